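"""AMOVA variance components, geographic distances and Mantel tests."""

import itertools
import math

import numpy as np
import pytest

from beandiv.amova import (amova, great_circle_km, ibd_test, mantel)
from beandiv.distances import DistanceMatrix, fst_matrix
from beandiv.io import MISSING
from beandiv.simulate import SimulationConfig, simulate_collection

from conftest import make_geno


def _amova_oracle(geno):
    """One-level AMOVA by explicit pairwise loops over gene copies."""
    copies = []   # (accession, per-locus allele or None)
    for k, ind in enumerate(geno.individuals):
        for slot in (0, 1):
            alleles = [int(a) if a != MISSING else None
                       for a in geno.alleles[k, :, slot]]
            copies.append((geno.accession_of[ind], alleles))

    def d2(x, y):
        return sum(1 for a, b in zip(x[1], y[1])
                   if a is not None and b is not None and a != b)

    N = len(copies)
    accs = sorted({c[0] for c in copies})
    ss_total = sum(d2(copies[i], copies[j])
                   for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    sizes = {}
    for acc in accs:
        sub = [c for c in copies if c[0] == acc]
        sizes[acc] = len(sub)
        ss_within += sum(d2(sub[i], sub[j])
                         for i in range(len(sub))
                         for j in range(i + 1, len(sub))) / len(sub)
    ss_among = ss_total - ss_within
    G = len(accs)
    ms_a = ss_among / (G - 1)
    ms_w = ss_within / (N - G)
    n_prime = (N - sum(s * s for s in sizes.values()) / N) / (G - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return sigma_a, sigma_w


class TestAmova:
    def test_fixed_differences_all_among(self):
        g = make_geno({
            "a_1": [(1, 1), (5, 5)], "a_2": [(1, 1), (5, 5)],
            "b_1": [(2, 2), (6, 6)], "b_2": [(2, 2), (6, 6)],
            "c_1": [(3, 3), (7, 7)], "c_2": [(3, 3), (7, 7)],
        })
        res = amova(g, nperm=0)
        assert res.pct_total[0] == pytest.approx(100.0)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_all_identical_undefined(self):
        g = make_geno({"a_1": [(1, 1)], "a_2": [(1, 1)],
                       "b_1": [(1, 1)], "b_2": [(1, 1)]})
        res = amova(g, nperm=0)
        assert all(v == 0 for v in res.variance)
        assert math.isnan(res.phi["phi_st"])

    def test_three_accession_toy_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        rows = {}
        for acc in ("a", "b", "c"):
            for i in range(4):
                rows[f"{acc}_{i+1}"] = [
                    tuple(rng.choice([1, 2, 3], size=2)) for _ in range(2)]
        g = make_geno(rows)
        res = amova(g, nperm=0)
        sa, sw = _amova_oracle(g)
        assert res.variance[0] == pytest.approx(sa, abs=1e-10)
        assert res.variance[1] == pytest.approx(sw, abs=1e-10)

    def test_df_arithmetic(self, small_sim):
        geno = small_sim.geno
        res = amova(geno, nperm=0)
        n_ind = geno.n_individuals
        n_acc = len(geno.accessions)
        assert res.df == [n_acc - 1, 2 * n_ind - n_acc]
        assert sum(res.df) == 2 * n_ind - 1
        assert sum(res.pct_total) == pytest.approx(100.0, abs=0.01)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        rows = {f"{acc}_{i+1}": [tuple(rng.choice([1, 2, 3], size=2))
                                 for _ in range(3)]
                for acc in ("a", "b", "c") for i in range(3)}
        g1 = make_geno(rows)
        renamed = {ind.replace("a_", "z_"): v for ind, v in rows.items()}
        order = sorted(renamed)
        g2 = make_geno({k: renamed[k] for k in order})
        r1, r2 = amova(g1, nperm=0), amova(g2, nperm=0)
        assert r1.variance == pytest.approx(r2.variance, abs=1e-12)

    def test_permutation_p_reproducible_and_bounded(self, small_sim):
        geno = small_sim.geno.subset(small_sim.geno.individuals[:60])
        r1 = amova(geno, nperm=99, seed=5)
        r2 = amova(geno, nperm=99, seed=5)
        p = r1.p_values["phi_st"]
        assert p == r2.p_values["phi_st"]
        assert p >= 1 / 100

    def test_two_level_design_components(self, small_sim):
        geno = small_sim.geno.subset(small_sim.geno.individuals[:80])
        accs = geno.accessions
        group_of = {a: ("G1" if i < len(accs) // 2 else "G2")
                    for i, a in enumerate(accs)}
        res = amova(geno, group_of, nperm=49, seed=3)
        assert len(res.strata) == 3
        assert sum(res.pct_total) == pytest.approx(100.0, abs=0.01)
        assert res.df[0] == 1
        assert res.df[1] == len(accs) - 2
        assert res.df[2] == 2 * geno.n_individuals - len(accs)

    def test_among_fraction_monotone_in_selfing(self):
        """% among accessions increases with selfing F (same seed)."""
        pcts = []
        for F in (0.0, 0.5, 0.95):
            cfg = SimulationConfig(n_accessions=20, selfing_F=F, seed=13)
            sim = simulate_collection(cfg, 13)
            pcts.append(amova(sim.geno, nperm=0).pct_total[0])
        assert pcts[0] < pcts[1] < pcts[2]


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_km((40.0, -8.0), (40.0, -8.0)) == 0.0

    def test_one_degree_meridian(self):
        assert great_circle_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            math.pi * 6371.0 / 180, abs=1e-3)  # 111.195 km

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            assert great_circle_km(a, b) == pytest.approx(
                great_circle_km(b, a), abs=1e-9)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            great_circle_km((95.0, 0.0), (0.0, 0.0))


def _mantel_exhaustive_p(A, B, alternative="greater"):
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
    hits = 0
    perms = list(itertools.permutations(range(n)))
    for perm in perms:
        bp = B[np.ix_(perm, perm)][iu]
        r = np.corrcoef(A[iu], bp)[0, 1]
        if alternative == "greater":
            hits += r >= r_obs - 1e-12
        else:
            hits += abs(r) >= abs(r_obs) - 1e-12
    return hits / len(perms)


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(1, 2, size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        res = mantel(A, A.copy(), nperm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_four_by_four_matches_exhaustive_enumeration(self):
        """Monte-Carlo p converges to the exact all-24-permutations p."""
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, size=(4, 4))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        B = rng.uniform(0, 1, size=(4, 4))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        exact = _mantel_exhaustive_p(A, B)
        res = mantel(A, B, nperm=20000, seed=1)
        # permutations are sampled with replacement, so compare as estimate
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_p_floor(self):
        x = np.arange(4.0)
        A = np.abs(x[:, None] - x[None, :])
        res = mantel(A, A.copy(), nperm=9, seed=0)
        assert res.p_value >= 1 / 10

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((2, 2)), np.zeros((2, 2)))


class TestIbd:
    def test_null_simulation_rarely_significant(self, small_sim):
        """Random coordinates vs genetics: |r| small, p rarely < 0.05."""
        accs = small_sim.geno.accessions[:15]
        sub = small_sim.geno.subset(
            [i for a in accs for i in small_sim.geno.members(a)])
        fst = fst_matrix(sub)
        rng = np.random.default_rng(17)
        hits = 0
        rs = []
        for _ in range(50):
            coords = {a: (rng.uniform(37, 42), rng.uniform(-9.5, -6.5))
                      for a in accs}
            res, _, _ = ibd_test(fst, coords, nperm=99,
                                 seed=int(rng.integers(2**31)))
            rs.append(res.r)
            hits += res.p_value <= 0.05
        assert hits <= 5  # ≥ 90 % of replicates non-significant
        assert np.median(np.abs(rs)) < 0.1

    def test_linearization_and_floor(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0, 0.5, -0.02], [0.5, 0, 0.25],
                         [-0.02, 0.25, 0]])
        fst = DistanceMatrix(ids, vals, metric="fst")
        coords = {"a": (40.0, -8.0), "b": (40.0, -8.0), "c": (41.0, -8.0)}
        res, lin, logkm = ibd_test(fst, coords, nperm=9, seed=0)
        # negative theta clamped to 0 before linearization
        assert lin.values[0, 2] == 0.0
        assert lin.values[0, 1] == pytest.approx(1.0)  # 0.5/(1-0.5)
        # co-located accessions floored at 1 km -> ln 1 = 0
        assert logkm.values[0, 1] == 0.0

    def test_excludes_accessions_without_coordinates(self):
        ids = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        V = rng.uniform(0.1, 0.3, (4, 4))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        fst = DistanceMatrix(ids, V, metric="fst")
        coords = {"a": (40, -8), "b": (41, -8), "c": (39, -7)}
        _, lin, _ = ibd_test(fst, coords, nperm=9, seed=0)
        assert lin.ids == ["a", "b", "c"]
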
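"""Distances and PCoA against hand values and independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beandiv.distances import (DistanceMatrix, chord_distance, chord_matrix,
                               dpsa, dpsa_matrix, fst_matrix, pairwise_fst,
                               pcoa)
from beandiv.io import MISSING

from conftest import make_geno


class TestChord:
    def test_identical_profiles_zero(self):
        f = {"L1": {1: 0.6, 2: 0.4}, "L2": {3: 1.0}}
        assert chord_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_different_alleles_one(self):
        assert chord_distance({"L1": {1: 1.0}}, {"L1": {2: 1.0}}) == \
            pytest.approx(1.0)

    def test_hand_value_half_split(self):
        d = chord_distance({"L1": {1: 1.0}}, {"L1": {1: 0.5, 2: 0.5}})
        assert d == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_gendist_dialect_scales_radicand(self):
        a, b = {"L1": {1: 1.0}}, {"L1": {1: 0.5, 2: 0.5}}
        assert chord_distance(a, b, "gendist") == pytest.approx(
            chord_distance(a, b) * 2 * np.sqrt(2) / np.pi)

    def test_no_shared_loci_errors(self):
        with pytest.raises(ValueError, match="shared"):
            chord_distance({"L1": {1: 1.0}}, {"L2": {1: 1.0}})

    @given(st.lists(st.tuples(st.floats(0.01, 1), st.floats(0.01, 1)),
                    min_size=1, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identity_and_symmetry(self, raw):
        fa = {f"L{i}": {1: p / (p + q), 2: q / (p + q)}
              for i, (p, q) in enumerate(raw)}
        fb = {f"L{i}": {1: q / (p + q), 2: p / (p + q)}
              for i, (p, q) in enumerate(raw)}
        # sqrt amplifies float error in Σ√(p·p): tolerance is sqrt(eps)-scale
        assert chord_distance(fa, fa) == pytest.approx(0.0, abs=1e-6)
        assert chord_distance(fa, fb) == pytest.approx(
            chord_distance(fb, fa), abs=1e-12)

    def test_matrix_agrees_with_scalar(self, toy_geno):
        from beandiv.diversity import allele_frequencies
        table = allele_frequencies(toy_geno)
        dm = chord_matrix(toy_geno)
        freqs = {g: {loc: table.frequencies(g, loc) for loc in table.loci
                     if table.frequencies(g, loc)} for g in table.groups}
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    assert dm.values[i, j] == pytest.approx(
                        chord_distance(freqs[a], freqs[b]), abs=1e-12)


def _dpsa_oracle(ga, gb):
    """Allele-multiset intersection per locus, brute force."""
    used = shared = 0
    for a, b in zip(ga, gb):
        if MISSING in a or MISSING in b:
            continue
        used += 1
        ma, mb = list(a), list(b)
        for x in list(ma):
            if x in mb:
                shared += 1
                mb.remove(x)
    return 1 - shared / (2 * used)


class TestDpsa:
    def test_identical_zero(self):
        g = make_geno({"a_1": [(1, 2), (3, 3)], "a_2": [(1, 2), (3, 3)]})
        assert dpsa(g, "a_1", "a_2") == pytest.approx(0.0)

    def test_half_shared(self):
        g = make_geno({"a_1": [(1, 2)], "a_2": [(1, 3)]})
        assert dpsa(g, "a_1", "a_2") == pytest.approx(0.5)

    def test_disjoint_one(self):
        g = make_geno({"a_1": [(1, 2)], "a_2": [(3, 4)]})
        assert dpsa(g, "a_1", "a_2") == pytest.approx(1.0)

    def test_missing_locus_skipped(self):
        g = make_geno({"a_1": [(1, 1), (-1, -1)], "a_2": [(1, 1), (5, 5)]})
        assert dpsa(g, "a_1", "a_2") == pytest.approx(0.0)

    def test_all_missing_errors(self):
        g = make_geno({"a_1": [(-1, -1)], "a_2": [(1, 1)]})
        with pytest.raises(ValueError, match="usable"):
            dpsa(g, "a_1", "a_2")

    def test_brute_force_oracle_all_small_genotypes(self):
        """min-count formula equals multiset intersection on ≤3-locus toys."""
        pool = [(1, 1), (1, 2), (2, 2), (2, 3)]
        for n_loci in (1, 2, 3):
            for ga in itertools.product(pool, repeat=n_loci):
                for gb in itertools.product(pool, repeat=n_loci):
                    g = make_geno({"x_1": list(ga), "x_2": list(gb)})
                    assert dpsa(g, "x_1", "x_2") == pytest.approx(
                        _dpsa_oracle(ga, gb), abs=1e-12)


def _wc_theta_oracle(geno, acc_a, acc_b):
    """Independent Weir–Cockerham θ: direct per-allele formula, r=2."""
    num = den = 0.0
    for l in range(geno.n_loci):
        samples = []
        for acc in (acc_a, acc_b):
            idx = geno.indices_of(acc)
            calls = geno.alleles[idx, l]
            calls = calls[calls[:, 0] != MISSING]
            samples.append(calls)
        if any(len(s) == 0 for s in samples):
            continue
        alleles = sorted({int(x) for s in samples for x in s.ravel()})
        if len(alleles) < 2:
            continue
        n1, n2 = len(samples[0]), len(samples[1])
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2))
        for A in alleles:
            p1 = (samples[0] == A).sum() / (2 * n1)
            p2 = (samples[1] == A).sum() / (2 * n2)
            h1 = ((samples[0][:, 0] == A) ^ (samples[0][:, 1] == A)).mean()
            h2 = ((samples[1][:, 0] == A) ^ (samples[1][:, 1] == A)).mean()
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
                               / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestPairwiseFst:
    def test_fixed_difference_theta_one(self):
        g = make_geno({"a_1": [(1, 1)], "a_2": [(1, 1)],
                       "b_1": [(2, 2)], "b_2": [(2, 2)]})
        assert pairwise_fst(g, "a", "b") == pytest.approx(1.0)

    def test_panmictic_theta_near_zero(self):
        rng = np.random.default_rng(4)
        rows = {}
        for acc in ("a", "b"):
            for i in range(60):
                rows[f"{acc}_{i+1}"] = [
                    tuple(rng.choice([1, 2, 3], size=2,
                                     p=[0.5, 0.3, 0.2]))
                    for _ in range(30)]
        g = make_geno(rows)
        assert abs(pairwise_fst(g, "a", "b")) < 0.02

    def test_matches_independent_formula_to_1e10(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            rows = {}
            for acc, probs in (("a", [0.7, 0.2, 0.1]), ("b", [0.2, 0.5, 0.3])):
                for i in range(6):
                    rows[f"{acc}_{i+1}"] = [
                        tuple(rng.choice([10, 12, 14], size=2, p=probs))
                        for _ in range(4)]
            g = make_geno(rows)
            theta = pairwise_fst(g, "a", "b")
            assert theta == pytest.approx(_wc_theta_oracle(g, "a", "b"),
                                          abs=1e-10)

    def test_monomorphic_undefined(self):
        g = make_geno({"a_1": [(1, 1)], "a_2": [(1, 1)],
                       "b_1": [(1, 1)], "b_2": [(1, 1)]})
        assert np.isnan(pairwise_fst(g, "a", "b"))

    def test_needs_two_individuals(self):
        g = make_geno({"a_1": [(1, 1)], "b_1": [(2, 2)], "b_2": [(2, 2)]})
        with pytest.raises(ValueError):
            pairwise_fst(g, "a", "b")


class TestDistanceMatrixInvariants:
    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1, 0], [0, 0.0]]))


class TestPcoa:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(list("abcd"), D))
        pos = res.eigenvalues[res.eigenvalues > 1e-8]
        assert res.proportion_explained[0] == pytest.approx(1.0)
        assert len(pos) == 1

    def test_zero_matrix_zero_coordinates(self):
        res = pcoa(DistanceMatrix(list("abc"), np.zeros((3, 3))))
        assert res.coordinates.shape[1] == 0 or \
            np.allclose(res.coordinates, 0)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(8)], D))
        got = res.coordinates[:, :2]
        D2 = np.sqrt(((got[:, None] - got[None, :]) ** 2).sum(-1))
        assert np.abs(D2 - D).max() < 1e-8

    def test_agrees_with_skbio(self):
        import skbio
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        ids = [f"p{i}" for i in range(6)]
        ours = pcoa(DistanceMatrix(ids, D))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D, ids))
        np.testing.assert_allclose(
            ours.eigenvalues[:3], np.asarray(ref.eigvals)[:3], atol=1e-8)


def test_fst_matrix_symmetric_zero_diag(small_sim):
    accs = small_sim.geno.accessions[:6]
    sub = small_sim.geno.subset(
        [i for a in accs for i in small_sim.geno.members(a)])
    dm = fst_matrix(sub)
    assert dm.metric == "fst"
    assert np.allclose(dm.values, dm.values.T, equal_nan=True)
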
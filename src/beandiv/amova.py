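"""Analysis of molecular variance and isolation by distance.

AMOVA operates on gene copies (two per diploid individual per locus) with
the squared inter-copy distance defined as the number of loci carrying
different alleles, partitioned into sums of squares per
Excoffier–Smouse–Quattro.  Two hierarchies are supported: a one-level
among/within-accessions design and a two-level groups/accessions/within
design.  Significance is by permutation: gene copies among accessions for
Φ_ST, copies among accessions within groups for Φ_SC, and whole
accessions among groups for Φ_CT.

Isolation by distance regresses F_ST/(1−F_ST) on ln(great-circle km)
between accession collecting sites (Rousset), tested by a Mantel
permutation of location assignments.  Co-located accessions are floored
at 1 km before the log; negative F_ST values are clamped to 0 before
linearisation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .io import MISSING, GenotypeMatrix

__all__ = [
    "AMOVAResult",
    "MantelResult",
    "amova",
    "great_circle_km",
    "mantel",
    "ibd_test",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class AMOVAResult:
    """AMOVA table: one row per stratum plus Φ-statistics."""

    hierarchy: str                       # "accessions" | "groups/accessions"
    strata: list[str]
    df: list[int]
    variance: list[float]
    pct_total: list[float]
    phi: dict[str, float]
    p_values: dict[str, float]
    nperm: int
    seed: int | None


@dataclass
class MantelResult:
    r: float
    p_value: float
    nperm: int
    seed: int | None


# ---------------------------------------------------------------------------
# internal: gene-copy encoding and pair sums


def _copy_codes(geno: GenotypeMatrix) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-locus integer allele codes for all 2N gene copies (−1 missing).

    Returns (codes_per_locus, copy_owner) where copy_owner[c] is the
    individual index owning copy c; copies are laid out individual-major.
    """
    n = geno.n_individuals
    codes = []
    for l in range(geno.n_loci):
        col = geno.alleles[:, l, :].reshape(-1)  # 2N copies
        alleles = np.unique(col[col != MISSING])
        lookup = {int(a): i for i, a in enumerate(alleles)}
        codes.append(np.array([lookup.get(int(v), -1) for v in col]))
    owner = np.repeat(np.arange(n), 2)
    return codes, owner


def _pair_mismatch_sum(codes: list[np.ndarray], members: np.ndarray) -> float:
    """Σ over copy pairs in ``members`` of the mismatch distance.

    Per locus this is C(m,2) − Σ_a C(c_a,2) over present copies.
    """
    total = 0.0
    for col in codes:
        sub = col[members]
        sub = sub[sub >= 0]
        m = sub.size
        if m < 2:
            continue
        counts = np.bincount(sub)
        total += m * (m - 1) / 2 - float((counts * (counts - 1) // 2).sum())
    return total


def _grouped_pair_sums(codes: list[np.ndarray], grp: np.ndarray,
                       n_groups: int) -> np.ndarray:
    """Per-group Σ of pairwise mismatch distances, vectorised over copies."""
    sums = np.zeros(n_groups)
    for col in codes:
        ok = col >= 0
        g, a = grp[ok], col[ok]
        n_alleles = int(a.max()) + 1 if a.size else 0
        if n_alleles == 0:
            continue
        counts = np.zeros((n_groups, n_alleles))
        np.add.at(counts, (g, a), 1.0)
        m = counts.sum(axis=1)
        sums += m * (m - 1) / 2 - (counts * (counts - 1) / 2).sum(axis=1)
    return sums


def _one_level_components(codes, grp, sizes, ss_total):
    """(sigma_within, sigma_among, ss_within, ss_among) for one grouping."""
    G = len(sizes)
    N = int(sizes.sum())
    pair_sums = _grouped_pair_sums(codes, grp, G)
    ss_within = float((pair_sums / sizes).sum())
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, N - G
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n_prime = (N - (sizes ** 2).sum() / N) / (G - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return sigma_w, sigma_a, ss_within, ss_among


def amova(geno: GenotypeMatrix,
          group_of: dict[str, str] | None = None,
          nperm: int = 999, seed: int | None = None) -> AMOVAResult:
    """AMOVA over gene copies with mismatch distances.

    ``group_of`` maps accession -> higher-level group; when given, the
    two-level groups/accessions/within design is fitted.  ``nperm = 0``
    reports components only (p-values missing).
    """
    accs = geno.accessions
    acc_idx = {a: i for i, a in enumerate(accs)}
    codes, owner = _copy_codes(geno)
    grp = np.array([acc_idx[geno.accession_of[geno.individuals[o]]]
                    for o in owner])
    G = len(accs)
    sizes = np.bincount(grp, minlength=G).astype(float)
    if (sizes < 2).any():
        raise ValueError("every accession needs at least 1 individual")
    N = int(sizes.sum())
    ss_total = _pair_mismatch_sum(codes, np.arange(N)) / N
    rng = np.random.default_rng(seed)

    if group_of is None:
        sw, sa, ssw, ssa = _one_level_components(codes, grp, sizes, ss_total)
        tot = sw + sa
        if tot <= 0:
            phi = {"phi_st": float("nan")}
            pvals = {"phi_st": float("nan")}
            return AMOVAResult("accessions", ["among accessions",
                                              "within accessions"],
                               [G - 1, N - G], [sa, sw],
                               [float("nan")] * 2, phi, pvals, nperm, seed)
        phi_st = sa / tot
        pct = [100 * sa / tot, 100 * sw / tot]
        p = float("nan")
        if nperm > 0:
            count = 0
            for _ in range(nperm):
                perm = rng.permutation(grp)
                psw, psa, *_ = _one_level_components(codes, perm, sizes,
                                                     ss_total)
                pt = psw + psa
                if pt > 0 and psa / pt >= phi_st - 1e-12:
                    count += 1
            p = (count + 1) / (nperm + 1)
        return AMOVAResult("accessions",
                           ["among accessions", "within accessions"],
                           [G - 1, N - G], [sa, sw], pct,
                           {"phi_st": phi_st}, {"phi_st": p}, nperm, seed)

    # ---- two-level design -------------------------------------------------
    groups = []
    for a in accs:
        if group_of[a] not in groups:
            groups.append(group_of[a])
    P = len(groups)
    grp_of_acc = np.array([groups.index(group_of[a]) for a in accs])
    top = grp_of_acc[grp]  # group index per gene copy

    def two_level(top_vec, acc_vec):
        acc_sizes = np.bincount(acc_vec, minlength=G).astype(float)
        grp_sizes = np.bincount(top_vec, minlength=P).astype(float)
        pair_acc = _grouped_pair_sums(codes, acc_vec, G)
        ss_wp = float((pair_acc / acc_sizes).sum())
        pair_grp = _grouped_pair_sums(codes, top_vec, P)
        ss_wg = float((pair_grp / grp_sizes).sum())
        ss_ap = ss_wg - ss_wp
        ss_ag = ss_total - ss_wg
        df_wp, df_ap, df_ag = N - G, G - P, P - 1
        ms_wp, ms_ap, ms_ag = ss_wp / df_wp, ss_ap / df_ap, ss_ag / df_ag
        # size coefficients for unequal sample sizes
        sum_sq_within = 0.0
        for gi in range(P):
            sel = acc_sizes[grp_of_acc == gi]
            sum_sq_within += (sel ** 2).sum() / sel.sum()
        n1 = (N - sum_sq_within) / (G - P)
        n2 = (sum_sq_within - (acc_sizes ** 2).sum() / N) / (P - 1)
        n3 = (N - (grp_sizes ** 2).sum() / N) / (P - 1)
        s_c = ms_wp
        s_b = (ms_ap - s_c) / n1
        s_a = (ms_ag - s_c - n2 * s_b) / n3
        return s_a, s_b, s_c

    s_a, s_b, s_c = two_level(top, grp)
    tot = s_a + s_b + s_c
    phi = {
        "phi_ct": s_a / tot,
        "phi_sc": s_b / (s_b + s_c),
        "phi_st": (s_a + s_b) / tot,
    }
    pct = [100 * s_a / tot, 100 * s_b / tot, 100 * s_c / tot]
    pvals = {k: float("nan") for k in phi}
    if nperm > 0:
        counts = {k: 0 for k in phi}
        for _ in range(nperm):
            # phi_st: copies among all accessions
            perm_acc = rng.permutation(grp)
            pa, pb, pc = two_level(grp_of_acc[perm_acc], perm_acc)
            if (pa + pb) / (pa + pb + pc) >= phi["phi_st"] - 1e-12:
                counts["phi_st"] += 1
            # phi_sc: copies among accessions within groups
            perm_within = grp.copy()
            for gi in range(P):
                mask = top == gi
                perm_within[mask] = rng.permutation(grp[mask])
            pa, pb, pc = two_level(top, perm_within)
            if pb / (pb + pc) >= phi["phi_sc"] - 1e-12:
                counts["phi_sc"] += 1
            # phi_ct: whole accessions among groups
            perm_groups = rng.permutation(grp_of_acc)
            pa, pb, pc = two_level(perm_groups[grp], grp)
            if pa / (pa + pb + pc) >= phi["phi_ct"] - 1e-12:
                counts["phi_ct"] += 1
        pvals = {k: (c + 1) / (nperm + 1) for k, c in counts.items()}
    return AMOVAResult("groups/accessions",
                       ["among groups", "among accessions within groups",
                        "within accessions"],
                       [P - 1, G - P, N - G], [s_a, s_b, s_c], pct,
                       phi, pvals, nperm, seed)


# ---------------------------------------------------------------------------
# geography and Mantel


def great_circle_km(coord_a: tuple[float, float],
                    coord_b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) decimal-degree points."""
    for lat, lon in (coord_a, coord_b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    la1, lo1, la2, lo2 = map(np.radians, (*coord_a, *coord_b))
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def mantel(A: np.ndarray, B: np.ndarray, nperm: int = 9999,
           seed: int | None = None,
           alternative: str = "greater") -> MantelResult:
    """Mantel test: Pearson r over off-diagonal pairs, permutation p.

    Permutations jointly shuffle rows/columns of ``B``.  The default
    alternative is one-sided "greater" (the usual convention for
    isolation by distance); "two-sided" compares |r|.
    """
    A, B = np.asarray(A, float), np.asarray(B, float)
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 entities")
    iu = np.triu_indices(n, k=1)
    a, b = A[iu], B[iu]
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        r = float(np.corrcoef(a, bp)[0, 1])
        if alternative == "two-sided":
            hit = abs(r) >= abs(r_obs) - 1e-12
        else:
            hit = r >= r_obs - 1e-12
        if hit:
            count += 1
    return MantelResult(r_obs, (count + 1) / (nperm + 1), nperm, seed)


def ibd_test(fst: DistanceMatrix, coords: dict[str, tuple[float, float]],
             nperm: int = 9999, seed: int | None = None,
             min_km: float = 1.0):
    """Rousset isolation by distance with a Mantel test.

    Builds F_ST/(1−F_ST) (negative θ clamped to 0 first) and ln(km)
    matrices over the accessions present in both inputs; distances below
    ``min_km`` are floored before the log.  Returns
    (MantelResult, linearized_fst_matrix, log_km_matrix).
    """
    ids = [i for i in fst.ids if i in coords]
    if len(ids) < 3:
        raise ValueError("need at least 3 accessions with coordinates")
    sub = fst.submatrix(ids)
    theta = np.clip(sub.values, 0.0, 0.999999)
    lin = theta / (1.0 - theta)
    np.fill_diagonal(lin, 0.0)
    n = len(ids)
    logkm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            km = max(great_circle_km(coords[ids[i]], coords[ids[j]]), min_km)
            logkm[i, j] = logkm[j, i] = np.log(km)
    res = mantel(lin, logkm, nperm=nperm, seed=seed)
    return (res,
            DistanceMatrix(ids, lin, metric="fst-linearized"),
            DistanceMatrix(ids, logkm, metric="log-km"))
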
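"""Genetic distances and principal coordinate analysis.

Three distances are provided, matching their classical definitions for
codominant multilocus data:

* Cavalli-Sforza & Edwards chord distance between allele-frequency
  profiles.  Default dialect: ``D = sqrt((1/L) Σ_l (1 − Σ_a sqrt(p q)))``,
  bounded in [0, 1].  The PHYLIP/GENDIST-style dialect multiplies the same
  radicand by 8/π² (i.e. the 2√2/π chord factor) and is selectable because
  published averages depend on the dialect used.
* Proportion-of-shared-alleles distance D_PSA between two diploid
  multilocus genotypes: ``1 − Σ_l min-shared / (2 L_used)``.
* Weir–Cockerham θ (pairwise F_ST) between two accessions, multilocus
  ratio-of-sums; slightly negative estimates are reported as computed.

PCoA is a plain Gower double-centering eigendecomposition; negative
eigenvalues are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import AlleleCountTable, allele_frequencies
from .io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "chord_distance",
    "chord_matrix",
    "dpsa",
    "dpsa_matrix",
    "pairwise_fst",
    "fst_matrix",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over named entities."""

    ids: list[str]
    values: np.ndarray
    metric: str = "generic"  # chord | dpsa | fst | fst-linearized | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix size does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-12,
                           equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ValueError("nonzero diagonal")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)],
                              self.metric)


# ---------------------------------------------------------------------------
# chord distance

_GENDIST_FACTOR = 8.0 / np.pi ** 2  # (2*sqrt(2)/pi)^2 applied to the radicand


def chord_distance(freqs_a: dict[str, dict[int, float]],
                   freqs_b: dict[str, dict[int, float]],
                   dialect: str = "default") -> float:
    """Chord distance between two per-locus allele-frequency profiles.

    ``freqs_*`` map locus -> {allele: frequency}.  Loci missing (empty)
    in either profile are skipped; at least one usable locus is required.
    """
    loci = [l for l in freqs_a if l in freqs_b and freqs_a[l] and freqs_b[l]]
    if not loci:
        raise ValueError("no shared loci with data")
    total = 0.0
    for l in loci:
        fa, fb = freqs_a[l], freqs_b[l]
        cos = sum(np.sqrt(fa[al] * fb[al]) for al in fa if al in fb)
        total += 1.0 - min(cos, 1.0)
    radicand = total / len(loci)
    if dialect == "gendist":
        radicand *= _GENDIST_FACTOR
    elif dialect != "default":
        raise ValueError(f"unknown chord dialect {dialect!r}")
    return float(np.sqrt(radicand))


def locus_frequency_matrices(table: AlleleCountTable
                             ) -> list[np.ndarray]:
    """Per-locus (groups × alleles) frequency matrices (rows sum to 1 or 0)."""
    out = []
    for loc in table.loci:
        alleles = sorted({a for grp in table.groups
                          for a in table.counts[grp][loc]})
        F = np.zeros((len(table.groups), len(alleles)))
        for i, grp in enumerate(table.groups):
            f = table.frequencies(grp, loc)
            for j, a in enumerate(alleles):
                F[i, j] = f.get(a, 0.0)
        out.append(F)
    return out


def chord_matrix_from_loci(freq_mats: list[np.ndarray], groups: list[str],
                           loci_idx: np.ndarray,
                           dialect: str = "default") -> DistanceMatrix:
    """Vectorised pairwise chord distances over a locus (re)sample."""
    G = len(groups)
    total = np.zeros((G, G))
    used = np.zeros((G, G))
    for l in loci_idx:
        F = freq_mats[l]
        has = F.sum(axis=1) > 0
        S = np.sqrt(F)
        cos = np.clip(S @ S.T, None, 1.0)
        ok = np.outer(has, has)
        total += np.where(ok, 1.0 - cos, 0.0)
        used += ok
    if (used == 0).any():
        raise ValueError("some pair shares no loci with data")
    radicand = total / used
    if dialect == "gendist":
        radicand *= _GENDIST_FACTOR
    elif dialect != "default":
        raise ValueError(f"unknown chord dialect {dialect!r}")
    D = np.sqrt(np.maximum(radicand, 0.0))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    return DistanceMatrix(list(groups), D, metric="chord")


def chord_matrix(geno: GenotypeMatrix, dialect: str = "default",
                 table: AlleleCountTable | None = None) -> DistanceMatrix:
    """Pairwise chord distances among accessions."""
    if table is None:
        table = allele_frequencies(geno)
    mats = locus_frequency_matrices(table)
    return chord_matrix_from_loci(mats, table.groups,
                                  np.arange(len(table.loci)), dialect)


# ---------------------------------------------------------------------------
# proportion of shared alleles


def dpsa(geno: GenotypeMatrix, ind_a: str, ind_b: str) -> float:
    """D_PSA between two individuals: 1 − shared/(2·L_used).

    ``shared`` at each locus is Σ_alleles min(count_a, count_b) over the
    two-allele genotypes; loci missing in either individual are skipped.
    """
    ia, ib = geno.individuals.index(ind_a), geno.individuals.index(ind_b)
    used = shared = 0
    for l in range(geno.n_loci):
        a, b = geno.alleles[ia, l], geno.alleles[ib, l]
        if a[0] == MISSING or b[0] == MISSING:
            continue
        used += 1
        for allele in set(a.tolist()):
            shared += min(int((a == allele).sum()), int((b == allele).sum()))
    if used == 0:
        raise ValueError(f"no usable loci between {ind_a!r} and {ind_b!r}")
    return 1.0 - shared / (2.0 * used)


def dpsa_matrix(geno: GenotypeMatrix,
                individuals: list[str] | None = None) -> DistanceMatrix:
    inds = individuals if individuals is not None else list(geno.individuals)
    D = np.zeros((len(inds), len(inds)))
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            D[i, j] = D[j, i] = dpsa(geno, inds[i], inds[j])
    return DistanceMatrix(list(inds), D, metric="dpsa")


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_components(geno: GenotypeMatrix, idx_by_pop: list[np.ndarray]
                   ) -> tuple[float, float]:
    """Sums of Weir–Cockerham a and a+b+c over all loci and alleles."""
    r = len(idx_by_pop)
    num = den = 0.0
    for l in range(geno.n_loci):
        pops = []
        for idx in idx_by_pop:
            calls = geno.alleles[idx, l]
            ok = calls[:, 0] != MISSING
            calls = calls[ok]
            if len(calls) == 0:
                continue
            pops.append(calls)
        if len(pops) < r:
            continue  # locus absent in some population
        alleles = sorted({int(a) for c in pops for a in c.ravel()})
        if len(alleles) < 2:
            continue
        n_i = np.array([len(c) for c in pops], dtype=float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i = np.array([float((c == allele).sum()) / (2 * len(c))
                            for c in pops])
            h_i = np.array([
                float(((c[:, 0] == allele) ^ (c[:, 1] == allele)).sum())
                / len(c) for c in pops])
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / n_c) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num, den


def pairwise_fst(geno: GenotypeMatrix, acc_a: str, acc_b: str) -> float:
    """Multilocus Weir–Cockerham θ between two accessions.

    Ratio-of-sums over loci and alleles; may be slightly negative.
    Returns NaN when every locus is monomorphic across both accessions.
    """
    ia, ib = geno.indices_of(acc_a), geno.indices_of(acc_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each accession needs >= 2 genotyped individuals")
    num, den = _wc_components(geno, [ia, ib])
    if den == 0.0:
        return float("nan")
    return num / den


def fst_matrix(geno: GenotypeMatrix,
               accessions: list[str] | None = None) -> DistanceMatrix:
    accs = accessions if accessions is not None else geno.accessions
    n = len(accs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            theta = pairwise_fst(geno, accs[i], accs[j])
            D[i, j] = D[j, i] = theta
    return DistanceMatrix(list(accs), D, metric="fst")


# ---------------------------------------------------------------------------
# principal coordinate analysis


@dataclass
class PCoAResult:
    coordinates: np.ndarray       # (n, n_axes), axes ordered by eigenvalue
    eigenvalues: np.ndarray       # all eigenvalues, descending (incl. < 0)
    proportion_explained: np.ndarray  # share of positive eigenvalue mass
    ids: list[str] = field(default_factory=list)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Gower double-centering PCoA.

    Coordinates are returned for axes with positive eigenvalues; negative
    eigenvalues stay in ``eigenvalues`` so non-Euclidean input is visible.
    """
    D = dm.values
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total_pos = vals[pos].sum()
    prop = np.where(pos, vals / total_pos, 0.0) if total_pos > 0 else vals * 0
    return PCoAResult(coords, vals, prop, list(dm.ids))
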
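"""Microsatellite diversity statistics per accession or group.

Implements the classical codominant-marker summaries: observed and
unbiased expected heterozygosity, effective number of alleles, PIC,
rarefied allelic richness, private-allele counts with Kalinowski's
rarefied private allelic richness, and Shannon diversity.

Counting conventions
--------------------
All statistics are computed from per-group, per-locus allele *copy*
counts.  A diploid individual contributes two gene copies per locus;
missing calls are excluded entirely.  Expected heterozygosity uses Nei's
small-sample correction ``(2n/(2n−1))(1 − Σ p²)`` with ``n`` diploid
individuals, appropriate for accession samples of ~10 plants.  Accession
averages are unweighted means over loci; loci with no data in a group
drop out of that group's averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix

__all__ = [
    "AlleleCountTable",
    "allele_frequencies",
    "heterozygosity",
    "effective_alleles",
    "pic",
    "rarefied_richness",
    "private_allelic_richness",
    "shannon_diversity",
    "diversity_summary",
]


@dataclass
class AlleleCountTable:
    """Per-(group, locus) allele copy counts.

    ``counts[group][locus]`` is a dict allele -> copy count; ``N`` per
    (group, locus) is the total non-missing copy count.
    """

    groups: list[str]
    loci: list[str]
    counts: dict[str, dict[str, dict[int, int]]]

    def n_copies(self, group: str, locus: str) -> int:
        return sum(self.counts[group][locus].values())

    def frequencies(self, group: str, locus: str) -> dict[int, float]:
        c = self.counts[group][locus]
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}


def allele_frequencies(geno: GenotypeMatrix,
                       grouping: dict[str, str] | None = None
                       ) -> AlleleCountTable:
    """Tally allele copies per (group, locus), excluding missing calls.

    ``grouping`` maps individual -> group; defaults to the accession
    grouping.  A group with zero non-missing copies at a locus simply has
    an empty count dict there (uninformative, not an error).
    """
    if grouping is None:
        grouping = dict(geno.accession_of)
    groups: list[str] = []
    for ind in geno.individuals:
        g = grouping[ind]
        if g not in groups:
            groups.append(g)
    counts: dict[str, dict[str, dict[int, int]]] = {
        g: {loc: {} for loc in geno.loci} for g in groups}
    for k, ind in enumerate(geno.individuals):
        g = grouping[ind]
        for l, loc in enumerate(geno.loci):
            for allele in geno.alleles[k, l]:
                if allele != MISSING:
                    d = counts[g][loc]
                    d[int(allele)] = d.get(int(allele), 0) + 1
    return AlleleCountTable(groups, list(geno.loci), counts)


# ---------------------------------------------------------------------------
# per-locus statistics


def heterozygosity(geno: GenotypeMatrix, group: str, locus: str,
                   grouping: dict[str, str] | None = None
                   ) -> tuple[float, float]:
    """(H_O, H_E) at one locus for one group.

    H_O is the fraction of non-missing genotypes with two distinct
    alleles.  H_E is Nei's unbiased gene diversity
    ``(2n/(2n−1))(1 − Σ p²)`` with n the number of genotyped individuals.
    Returns ``(nan, nan)`` when no individual is genotyped.
    """
    if grouping is None:
        grouping = dict(geno.accession_of)
    l = geno.loci.index(locus)
    het = tot = 0
    tally: dict[int, int] = {}
    for k, ind in enumerate(geno.individuals):
        if grouping[ind] != group:
            continue
        a, b = geno.alleles[k, l]
        if a == MISSING:
            continue
        tot += 1
        het += int(a != b)
        tally[int(a)] = tally.get(int(a), 0) + 1
        tally[int(b)] = tally.get(int(b), 0) + 1
    if tot == 0:
        return (float("nan"), float("nan"))
    n2 = 2 * tot
    p2 = sum((c / n2) ** 2 for c in tally.values())
    he = (n2 / (n2 - 1)) * (1.0 - p2) if n2 > 1 else float("nan")
    return (het / tot, he)


def effective_alleles(freqs: dict[int, float]) -> float:
    """Effective number of alleles at one locus: 1 / Σ p²."""
    if not freqs:
        return float("nan")
    return 1.0 / sum(p * p for p in freqs.values())


def pic(freqs: dict[int, float]) -> float:
    """Polymorphism information content: 1 − Σp² − Σ_{i<j} 2 p_i² p_j²."""
    p = np.array(list(freqs.values()), dtype=float)
    if p.size == 0:
        return float("nan")
    s2 = float(np.sum(p ** 2))
    # Σ_{i<j} 2 p_i² p_j² = (Σp²)² − Σp⁴
    cross = s2 * s2 - float(np.sum(p ** 4))
    return 1.0 - s2 - cross


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _prob_present(N: int, Ni: int, g: int) -> float:
    """P(allele with Ni of N copies appears in a size-g subsample)."""
    if g > N - Ni:
        return 1.0
    return 1.0 - float(np.exp(_log_comb(N - Ni, g) - _log_comb(N, g)))


def rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Allelic richness N_ar(g): expected allele count in g of N copies.

    ``N_ar = Σ_i [1 − C(N−N_i, g)/C(N, g)]`` (hypergeometric rarefaction).
    """
    N = sum(counts.values())
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > N:
        raise ValueError(f"g={g} exceeds available copies N={N}")
    return sum(_prob_present(N, Ni, g) for Ni in counts.values())


def private_allelic_richness(tables: dict[str, dict[int, int]],
                             focal: str, g: int) -> tuple[int, float]:
    """(N_pr, N_par(g)) for the focal group against all other groups.

    N_pr is the raw number of alleles present in the focal group and
    absent everywhere else.  N_par(g) is Kalinowski's rarefied private
    allelic richness: for every allele, the probability that it appears
    in a size-g subsample of the focal group times the probability it
    appears in no size-g subsample of any other group, summed over the
    focal group's alleles.
    """
    if focal not in tables or len(tables) < 2:
        raise ValueError("need the focal group plus at least one other")
    for grp, c in tables.items():
        if g > sum(c.values()):
            raise ValueError(f"g={g} exceeds copies in group {grp!r}")
    others = [c for grp, c in tables.items() if grp != focal]
    n_pr = 0
    n_par = 0.0
    fc = tables[focal]
    Nf = sum(fc.values())
    for allele, Ni in fc.items():
        if all(allele not in c for c in others):
            n_pr += 1
        p = _prob_present(Nf, Ni, g)
        for c in others:
            No = sum(c.values())
            p *= 1.0 - _prob_present(No, c.get(allele, 0), g)
        n_par += p
    return n_pr, n_par


def shannon_diversity(counts) -> float:
    """Shannon index H = −Σ p ln p over one categorical count vector."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict)
                   else counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts zero")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# accession-level summary (Table-1 style)


def diversity_summary(geno: GenotypeMatrix, g: int | None = None,
                      grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-group diversity table: N_a, N_ar(g), N_e, N_pr, N_par(g), H_O, H_E.

    Averages are unweighted over loci with data in the group; N_e is the
    harmonic mean over loci (the GenAlEx convention).  ``g`` (gene copies
    for rarefaction) defaults to the smallest non-missing copy count over
    all (group, locus) cells with data, the FSTAT convention.
    """
    if grouping is None:
        grouping = dict(geno.accession_of)
    table = allele_frequencies(geno, grouping)
    if g is None:
        mins = [table.n_copies(grp, loc) for grp in table.groups
                for loc in table.loci if table.n_copies(grp, loc) > 0]
        g = min(mins) if mins else 1
    rows = []
    for grp in table.groups:
        na, nar, ne_inv, ho, he, npr, npar = [], [], [], [], [], 0, 0.0
        for loc in table.loci:
            c = table.counts[grp][loc]
            N = sum(c.values())
            if N == 0:
                continue
            na.append(len(c))
            nar.append(rarefied_richness(c, min(g, N)))
            f = table.frequencies(grp, loc)
            ne_inv.append(1.0 / effective_alleles(f))
            o, e = heterozygosity(geno, grp, loc, grouping)
            ho.append(o)
            he.append(e)
            if len(table.groups) >= 2:
                per_locus = {gg: table.counts[gg][loc] for gg in table.groups
                             if sum(table.counts[gg][loc].values()) > 0}
                if grp in per_locus and len(per_locus) >= 2:
                    gl = min(min(sum(cc.values()) for cc in per_locus.values()),
                             g)
                    pr, par = private_allelic_richness(per_locus, grp, gl)
                    npr += pr
                    npar += par
        rows.append({
            "group": grp,
            "n_loci": len(na),
            "N_a": float(np.mean(na)),
            "N_ar": float(np.mean(nar)),
            "N_e": float(len(ne_inv) / np.sum(ne_inv)),
            "N_pr": npr,
            "N_par": npar / len(na) if na else float("nan"),
            "H_O": float(np.nanmean(ho)),
            "H_E": float(np.nanmean(he)),
            "g": g,
        })
    return pd.DataFrame(rows).set_index("group")
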
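"""Core-collection construction by the maximization (M) strategy.

A core collection is a minimal-redundancy subset of accessions chosen to
retain the collection's diversity.  Selection operates on one
representative individual per accession (the plant carrying the
accession's most frequent multilocus genotype) over a coverage universe
of (locus, allele) pairs plus (qualitative trait, state) pairs.

Two selectors are provided:

* ``mstrat_nested`` — the standard M strategy: stochastic greedy
  construction plus swap local search maximizing the covered item count,
  run as independent replicates per target size; among replicate optima
  with maximal coverage the subset with the highest Shannon diversity is
  kept, and successive sizes are nested (smaller cores forced into
  larger ones);
* ``powercore_select`` — the advanced coverage-complete strategy:
  deterministic greedy set cover followed by redundancy elimination,
  guaranteeing 100 % coverage of alleles and trait states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import allele_frequencies, heterozygosity, shannon_diversity
from .io import MISSING, GenotypeMatrix, TraitTable, QUALITATIVE_STATES

__all__ = [
    "CoverageUniverse",
    "CoreSubset",
    "representative_individual",
    "build_universe",
    "coverage",
    "shannon_index",
    "mstrat_nested",
    "powercore_select",
    "compare_core",
]

CORE_TRAITS = ["growth_habit", "seed_shape", "seed_coat_color",
               "seed_coat_pattern", "seed_size"]


def representative_individual(geno: GenotypeMatrix, accession: str) -> str:
    """The member carrying the accession's most frequent multilocus genotype.

    Genotypes are compared as complete strings of unordered allele pairs;
    ties (between genotype classes or carriers) resolve to the smallest
    individual id.
    """
    members = geno.members(accession)
    if not members:
        raise ValueError(f"accession {accession!r} has no members")
    profiles: dict[tuple, list[str]] = {}
    for ind in members:
        k = geno.individuals.index(ind)
        prof = tuple(tuple(sorted(geno.alleles[k, l]))
                     for l in range(geno.n_loci))
        if all(a == (MISSING, MISSING) for a in prof):
            continue
        profiles.setdefault(prof, []).append(ind)
    if not profiles:
        raise ValueError(f"accession {accession!r}: all genotypes missing")
    best_count = max(len(v) for v in profiles.values())
    carriers = [ind for v in profiles.values() if len(v) == best_count
                for ind in v]
    return min(carriers)


@dataclass
class CoverageUniverse:
    """Coverable items and per-accession boolean incidence."""

    allele_items: list[tuple]      # (locus, allele)
    trait_items: list[tuple]       # (trait, state)
    accessions: list[str]
    incidence: np.ndarray          # (n_accessions, n_items) bool

    @property
    def n_alleles(self) -> int:
        return len(self.allele_items)

    @property
    def n_traits(self) -> int:
        return len(self.trait_items)


def build_universe(geno: GenotypeMatrix, traits: TraitTable | None = None,
                   representative: dict[str, str] | None = None
                   ) -> CoverageUniverse:
    """Coverage universe from representative-individual genotypes + traits.

    Every item is carried by ≥ 1 accession by construction (items are
    enumerated from the data itself).
    """
    accs = geno.accessions
    if representative is None:
        representative = {a: representative_individual(geno, a)
                          for a in accs}
    carried: dict[str, set] = {a: set() for a in accs}
    allele_items: list[tuple] = []
    for a in accs:
        k = geno.individuals.index(representative[a])
        for l, loc in enumerate(geno.loci):
            for al in geno.alleles[k, l]:
                if al != MISSING:
                    item = (loc, int(al))
                    if item not in allele_items:
                        allele_items.append(item)
                    carried[a].add(item)
    trait_items: list[tuple] = []
    if traits is not None:
        for trait in CORE_TRAITS:
            if trait not in traits.data.columns:
                continue
            for a in accs:
                if a not in traits.data.index:
                    continue
                state = traits.data.loc[a, trait]
                if pd.isna(state):
                    continue
                item = (trait, state)
                if item not in trait_items:
                    trait_items.append(item)
                carried[a].add(item)
    items = allele_items + trait_items
    pos = {it: i for i, it in enumerate(items)}
    inc = np.zeros((len(accs), len(items)), dtype=bool)
    for i, a in enumerate(accs):
        for it in carried[a]:
            inc[i, pos[it]] = True
    return CoverageUniverse(allele_items, trait_items, list(accs), inc)


def coverage(universe: CoverageUniverse, members: list[str]
             ) -> tuple[float, float]:
    """(allele %, trait-state %) of universe items carried by the subset."""
    if universe.incidence.shape[1] == 0:
        raise ValueError("empty universe")
    idx = [universe.accessions.index(m) for m in members]
    if not idx:
        return (0.0, 0.0)
    cov = universe.incidence[idx].any(axis=0)
    na = universe.n_alleles
    apct = 100.0 * cov[:na].sum() / na if na else 100.0
    nt = universe.n_traits
    tpct = 100.0 * cov[na:].sum() / nt if nt else 100.0
    return float(apct), float(tpct)


def shannon_index(universe: CoverageUniverse, members: list[str],
                  geno: GenotypeMatrix, traits: TraitTable | None,
                  representative: dict[str, str]) -> float:
    """Mean per-variable Shannon H over loci and qualitative traits."""
    hs = []
    idx = [geno.individuals.index(representative[m]) for m in members]
    for l in range(geno.n_loci):
        counts: dict[int, int] = {}
        for k in idx:
            for al in geno.alleles[k, l]:
                if al != MISSING:
                    counts[int(al)] = counts.get(int(al), 0) + 1
        if counts:
            hs.append(shannon_diversity(counts))
    if traits is not None:
        sub = traits.data.loc[[m for m in members
                               if m in traits.data.index]]
        for trait in CORE_TRAITS:
            if trait in sub.columns:
                counts = sub[trait].value_counts().to_dict()
                if counts:
                    hs.append(shannon_diversity(counts))
    return float(np.mean(hs)) if hs else 0.0


@dataclass
class CoreSubset:
    members: list[str]
    size: int
    allele_coverage_pct: float
    trait_coverage_pct: float
    shannon: float
    strategy: str
    seed: int | None = None
    replicates: int | None = None
    summary: dict = field(default_factory=dict)


def _covered_count(universe: CoverageUniverse, idx: list[int]) -> int:
    return int(universe.incidence[idx].any(axis=0).sum())


def _greedy_fill(universe: CoverageUniverse, chosen: list[int], size: int,
                 rng: np.random.Generator) -> list[int]:
    chosen = list(chosen)
    cov = (universe.incidence[chosen].any(axis=0) if chosen
           else np.zeros(universe.incidence.shape[1], dtype=bool))
    pool = [i for i in range(len(universe.accessions)) if i not in chosen]
    while len(chosen) < size:
        gains = np.array([universe.incidence[i][~cov].sum() for i in pool])
        best = np.flatnonzero(gains == gains.max())
        pick = pool[int(rng.choice(best))]
        chosen.append(pick)
        cov |= universe.incidence[pick]
        pool.remove(pick)
    return chosen


def mstrat_nested(geno: GenotypeMatrix, traits: TraitTable | None,
                  sizes: list[int], replicates: int = 200,
                  iterations: int = 100, seed: int = 0,
                  universe: CoverageUniverse | None = None,
                  representative: dict[str, str] | None = None
                  ) -> list[CoreSubset]:
    """Nested M-strategy cores for strictly increasing target sizes.

    Per size: ``replicates`` independent restarts of stochastic greedy
    construction plus up to ``iterations`` random swap moves (a swap is
    accepted when it does not reduce the covered item count and either
    improves it or improves Shannon diversity).  Among replicate optima
    with maximal coverage the highest-Shannon subset is kept; each size
    is forced to contain the previous core.  Restart r uses seed+r, so
    results are reproducible under parallel execution.
    """
    if sizes != sorted(set(sizes)):
        raise ValueError("sizes must be strictly increasing")
    if representative is None:
        representative = {a: representative_individual(geno, a)
                          for a in geno.accessions}
    if universe is None:
        universe = build_universe(geno, traits, representative)
    accs = universe.accessions
    if sizes[-1] > len(accs):
        raise ValueError("size exceeds collection")
    forced: list[int] = []
    out: list[CoreSubset] = []
    for size in sizes:
        best: tuple[int, float, list[int]] | None = None
        for r in range(replicates):
            rng = np.random.default_rng(seed + r)
            chosen = _greedy_fill(universe, forced, size, rng)
            score = _covered_count(universe, chosen)
            sh = shannon_index(universe, [accs[i] for i in chosen],
                               geno, traits, representative)
            for _ in range(iterations):
                swappable = [i for i in chosen if i not in forced]
                outside = [i for i in range(len(accs)) if i not in chosen]
                if not swappable or not outside:
                    break
                drop = swappable[int(rng.integers(len(swappable)))]
                add = outside[int(rng.integers(len(outside)))]
                cand = [c for c in chosen if c != drop] + [add]
                cscore = _covered_count(universe, cand)
                if cscore < score:
                    continue
                csh = shannon_index(universe, [accs[i] for i in cand],
                                    geno, traits, representative)
                if cscore > score or csh > sh:
                    chosen, score, sh = cand, cscore, csh
            key = (score, sh, sorted(accs[i] for i in chosen))
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                    (key[0], key[1]) == (best[0], best[1])
                    and key[2] < sorted(accs[i] for i in best[2])):
                best = (score, sh, chosen)
        forced = sorted(best[2])
        members = sorted(accs[i] for i in forced)
        apct, tpct = coverage(universe, members)
        out.append(CoreSubset(members, size, apct, tpct, best[1],
                              strategy="mstrat", seed=seed,
                              replicates=replicates))
    return out


def powercore_select(geno: GenotypeMatrix, traits: TraitTable | None = None,
                     universe: CoverageUniverse | None = None,
                     representative: dict[str, str] | None = None
                     ) -> CoreSubset:
    """Deterministic coverage-complete core: greedy set cover, then prune.

    Greedy picks the accession covering the most still-uncovered items
    (ties by accession id); redundancy elimination then drops any member
    whose items remain covered without it (checked in id order).  The
    result always covers 100 % of alleles and trait states.
    """
    if representative is None:
        representative = {a: representative_individual(geno, a)
                          for a in geno.accessions}
    if universe is None:
        universe = build_universe(geno, traits, representative)
    accs = universe.accessions
    n_items = universe.incidence.shape[1]
    cov = np.zeros(n_items, dtype=bool)
    chosen: list[int] = []
    order = sorted(range(len(accs)), key=lambda i: accs[i])
    while not cov.all():
        gains = [(-int(universe.incidence[i][~cov].sum()), accs[i], i)
                 for i in order if i not in chosen]
        neg_gain, _, pick = min(gains)
        if neg_gain == 0:
            break  # unreachable: every item is carried by some accession
        chosen.append(pick)
        cov |= universe.incidence[pick]
    # redundancy elimination
    for i in sorted(chosen, key=lambda i: accs[i]):
        rest = [j for j in chosen if j != i]
        if rest and universe.incidence[rest].any(axis=0).all():
            chosen = rest
    members = sorted(accs[i] for i in chosen)
    apct, tpct = coverage(universe, members)
    sh = shannon_index(universe, members, geno, traits, representative)
    return CoreSubset(members, len(members), apct, tpct, sh,
                      strategy="powercore")


def compare_core(geno: GenotypeMatrix, core_members: list[str],
                 traits: TraitTable | None = None,
                 representative: dict[str, str] | None = None
                 ) -> pd.DataFrame:
    """Core vs. whole-collection diversity over representative individuals.

    Rows: per-locus allele count N_a, H_O, H_E for the core subset and
    the entire collection, with a paired Wilcoxon signed-rank test across
    loci (the caller applies Bonferroni across core sizes), plus trait
    state counts and Shannon diversity when traits are given.
    """
    accs = geno.accessions
    unknown = set(core_members) - set(accs)
    if unknown:
        raise ValueError(f"core members not in collection: {sorted(unknown)}")
    if len(core_members) < 2:
        raise ValueError("core must have >= 2 members")
    if representative is None:
        representative = {a: representative_individual(geno, a)
                          for a in accs}

    def per_locus(members: list[str]):
        sub = geno.subset([representative[m] for m in members])
        grouping = {i: "all" for i in sub.individuals}
        table = allele_frequencies(sub, grouping)
        na, ho, he = [], [], []
        for loc in sub.loci:
            na.append(len(table.counts["all"][loc]))
            o, e = heterozygosity(sub, "all", loc, grouping)
            ho.append(o)
            he.append(e)
        return np.array(na, float), np.array(ho), np.array(he)

    na_c, ho_c, he_c = per_locus(core_members)
    na_f, ho_f, he_f = per_locus(accs)
    rows = []
    for name, c, f in (("N_avg", na_c, na_f), ("H_O", ho_c, ho_f),
                       ("H_E", he_c, he_f)):
        diff = c - f
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(c, f, zero_method="zsplit").pvalue)
        rows.append({"statistic": name, "core": float(np.nanmean(c)),
                     "collection": float(np.nanmean(f)),
                     "wilcoxon_p": p})
    if traits is not None:
        uni = build_universe(geno, traits, representative)
        rows.append({"statistic": "N_s",
                     "core": coverage(uni, core_members)[1] / 100
                     * uni.n_traits,
                     "collection": float(uni.n_traits),
                     "wilcoxon_p": float("nan")})
        rows.append({"statistic": "H_Sh",
                     "core": shannon_index(uni, core_members, geno, traits,
                                           representative),
                     "collection": shannon_index(uni, accs, geno, traits,
                                                 representative),
                     "wilcoxon_p": float("nan")})
    return pd.DataFrame(rows).set_index("statistic")
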
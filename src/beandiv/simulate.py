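"""Synthetic germplasm collections with the structure the analysis assumes.

The generator emulates a landrace collection descended from a small
number of strongly differentiated ancestral gene pools (the common-bean
situation: Mesoamerican vs. Andean domestications), genotyped at
codominant SSR loci:

* per-pool allele frequencies drawn from a Dirichlet centred on a shared
  base frequency vector, with a single divergence knob δ ∈ (0, 1)
  (concentration (1−δ)/δ: δ→0 makes pools identical, δ→1 maximally
  divergent);
* accessions are seed lots founded by a handful of plants
  (``founders_per_accession``), which produces the low within-accession
  and high between-accession diversity the analysis exploits;
* heavy selfing: with probability F an individual's locus call is a
  duplicated single draw from the accession's founder allele pool
  (identical-by-state homozygote), otherwise two independent draws;
* about a third of accessions are admixed, their gene copies drawn from
  pools according to an accession-level membership vector q;
* a pool-linked phaseolin haplotype per individual, flipped with a small
  discordance rate ε;
* pool-dependent seed/plant traits: quantitative traits Normal around
  q-weighted pool means, qualitative states from q-mixed pool-specific
  categorical distributions;
* GPS coordinates uniform in a bounding box with no spatial genetic
  signal, so isolation by distance is a true null.

Everything is reproducible bit-identically from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (AccessionMetadata, GenotypeMatrix, PhaseolinCall,
                 QUALITATIVE_STATES, TraitTable)
from .morphology import seed_indices, seed_size_class

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "SimulatedCollection",
    "PHASEOLIN_REFERENCE",
    "POOL_HAPLOTYPES",
    "sample_pool_frequencies",
    "simulate_collection",
    "write_collection",
]

#: synthetic reference fragment patterns (bp) for the three haplotypes
PHASEOLIN_REFERENCE = {"P1": (280, 310), "P2": (265, 330), "P3": (250, 345)}

#: pool index -> diagnostic haplotype (Mesoamerican P1; Andean P3, P2)
POOL_HAPLOTYPES = ["P1", "P3", "P2"]

_POOL_TRAIT_MEANS = {
    # seed_length, seed_width, seed_height (mm), 100-seed weight (g),
    # seeds/pod, locules/pod — Mesoamerican small-seeded, Andean large
    0: (11.0, 6.0, 4.5, 22.0, 5.5, 6.5),
    1: (15.0, 8.0, 6.0, 48.0, 4.5, 5.0),
    2: (17.0, 7.5, 5.5, 44.0, 4.0, 4.5),
}

_POOL_QUALITATIVE = {
    # per-pool categorical weights over QUALITATIVE_STATES orderings
    "growth_habit": {0: [0.55, 0.45], 1: [0.7, 0.3], 2: [0.4, 0.6]},
    "seed_shape": {0: [0.05, 0.1, 0.65, 0.2], 1: [0.0, 0.1, 0.6, 0.3],
                   2: [0.0, 0.45, 0.4, 0.15]},
    "seed_coat_pattern": {
        0: [0.6, 0.0, 0.05, 0.3, 0.0, 0.0, 0.05],
        1: [0.55, 0.0, 0.0, 0.3, 0.0, 0.1, 0.05],
        2: [0.6, 0.05, 0.05, 0.25, 0.05, 0.0, 0.0],
    },
    # colors for plain-coat seeds only (8 named colors, no "patterned")
    "_plain_color": {
        0: [0.5, 0.0, 0.07, 0.14, 0.2, 0.0, 0.02, 0.07],
        1: [0.3, 0.08, 0.15, 0.0, 0.0, 0.38, 0.09, 0.0],
        2: [0.04, 0.0, 0.37, 0.11, 0.22, 0.22, 0.04, 0.0],
    },
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic collection."""

    n_pools: int = 2
    n_loci: int = 21
    alleles_per_locus: tuple[int, int] = (2, 12)
    delta: float = 0.6               # between-pool divergence in (0,1)
    n_accessions: int = 175
    individuals_per_accession: int = 10
    admixed_fraction: float = 0.33
    selfing_F: float = 0.95
    founders_per_accession: int = 4
    founder_weight_concentration: float = 0.2
    phaseolin_epsilon: float = 0.02
    bbox: tuple[float, float, float, float] = (37.0, 42.0, -9.5, -6.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        for name in ("admixed_fraction", "selfing_F", "phaseolin_epsilon"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pools < 1:
            raise ValueError("n_pools must be >= 1")
        if self.n_pools > len(POOL_HAPLOTYPES):
            raise ValueError("at most 3 pools have linked haplotypes")


@dataclass
class SimTruth:
    """Recoverable ground truth for every generated entity."""

    pool_frequencies: list[dict[str, dict[int, float]]]
    accession_q: dict[str, np.ndarray]
    individual_q: dict[str, np.ndarray]
    accession_kind: dict[str, str]       # "pure" | "admixed"
    accession_pool: dict[str, int | None]
    individual_haplotype: dict[str, str]
    config: SimulationConfig = None
    seed: int = 0


@dataclass
class SimulatedCollection:
    geno: GenotypeMatrix
    phaseolin: dict[str, PhaseolinCall]
    traits: TraitTable
    metadata: dict[str, AccessionMetadata]
    truth: SimTruth


def sample_pool_frequencies(config: SimulationConfig,
                            rng: np.random.Generator | int | None = None
                            ) -> list[dict[str, dict[int, float]]]:
    """Per-pool, per-locus allele frequencies on the simplex.

    Base frequencies per locus are symmetric-Dirichlet; each pool's
    frequencies are Dirichlet(base · (1−δ)/δ) so that expected
    between-pool differentiation grows monotonically with δ.
    """
    rng = np.random.default_rng(rng)
    lo, hi = config.alleles_per_locus
    conc = (1.0 - config.delta) / config.delta
    pools: list[dict[str, dict[int, float]]] = [
        {} for _ in range(config.n_pools)]
    for l in range(config.n_loci):
        locus = f"L{l + 1:02d}"
        n_alleles = int(rng.integers(lo, hi + 1))
        # allele codes mimic SSR fragment sizes in bp
        sizes = (100 + 10 * l + 2 * np.arange(n_alleles)).tolist()
        base = rng.dirichlet(np.ones(n_alleles))
        for k in range(config.n_pools):
            f = rng.dirichlet(np.maximum(base * conc, 1e-3))
            pools[k][locus] = {int(s): float(x) for s, x in zip(sizes, f)}
    return pools


def _draw_allele(rng, freqs: dict[int, float]) -> int:
    alleles = list(freqs)
    return int(alleles[rng.choice(len(alleles), p=np.array(
        [freqs[a] for a in alleles]) / sum(freqs.values()))])


def simulate_collection(config: SimulationConfig,
                        seed: int | None = None) -> SimulatedCollection:
    """Generate (genotypes, phaseolin calls, traits, metadata, truth)."""
    seed = config.seed if seed is None else seed
    # two aligned streams: structure (pools, founders, traits, geography)
    # and genotype sampling, so that changing e.g. selfing_F alone leaves
    # the collection's ancestral structure untouched
    ss = np.random.SeedSequence(seed)
    child_struct, child_geno = ss.spawn(2)
    rng = np.random.default_rng(child_struct)
    rng_g = np.random.default_rng(child_geno)
    pools = sample_pool_frequencies(config, rng)
    K = config.n_pools
    loci = list(pools[0])
    n_adm = int(round(config.admixed_fraction * config.n_accessions))
    kinds = np.array(["admixed"] * n_adm
                     + ["pure"] * (config.n_accessions - n_adm))
    rng.shuffle(kinds)

    individuals: list[str] = []
    accession_of: dict[str, str] = {}
    calls: list[np.ndarray] = []
    phaseolin: dict[str, PhaseolinCall] = {}
    metadata: dict[str, AccessionMetadata] = {}
    trait_rows = []
    truth = SimTruth([{loc: dict(f[loc]) for loc in loci} for f in pools],
                     {}, {}, {}, {}, {}, config, seed)

    la, lb, lo_a, lo_b = config.bbox
    for a in range(config.n_accessions):
        acc = f"acc{a + 1:03d}"
        kind = str(kinds[a])
        if kind == "pure" or K == 1:
            pool = int(rng.integers(K))
            q = np.zeros(K)
            q[pool] = 1.0
            truth.accession_pool[acc] = pool
        else:
            q = rng.dirichlet(np.full(K, 3.0))
            truth.accession_pool[acc] = None
        truth.accession_kind[acc] = kind

        # accession founder pool: a few fully inbred founder haplotypes
        # with skewed contribution weights — the bottleneck that produces
        # low within-accession and high between-accession diversity
        nf = config.founders_per_accession
        z_f = np.array([int(rng.choice(K, p=q)) for _ in range(nf)])
        haplos = [{loc: _draw_allele(rng, pools[z][loc]) for loc in loci}
                  for z in z_f]
        # pure seed lots descend mostly from one line (skewed weights);
        # admixed lots are genuine mixtures (even weights)
        conc = 1.0 if kind == "admixed" else \
            config.founder_weight_concentration
        w = rng.dirichlet(np.full(nf, conc))
        q_real = np.zeros(K)
        for j in range(nf):
            q_real[z_f[j]] += w[j]
        truth.accession_q[acc] = q_real if kind == "admixed" else q

        dominant = int(np.argmax(q_real)) if kind == "admixed" else \
            int(np.argmax(q))
        acc_haplo = POOL_HAPLOTYPES[dominant]
        # phaseolin travels with the seed lot: one haplotype per accession,
        # discordant with the dominant pool at rate epsilon
        if K > 1 and rng.random() < config.phaseolin_epsilon:
            others = [h for h in POOL_HAPLOTYPES[:K] if h != acc_haplo]
            acc_haplo = others[rng.integers(len(others))]
        for i in range(config.individuals_per_accession):
            ind = f"{acc}_{i + 1}"
            individuals.append(ind)
            accession_of[ind] = acc
            truth.individual_q[ind] = truth.accession_q[acc]
            row = np.zeros((len(loci), 2), dtype=np.int64)
            # fixed draw pattern (u, j1, j2) per cell keeps the stream
            # aligned across selfing_F values for the same seed
            us = rng_g.random(len(loci))
            j1s = rng_g.choice(nf, size=len(loci), p=w)
            j2s = rng_g.choice(nf, size=len(loci), p=w)
            for l, loc in enumerate(loci):
                a1 = haplos[int(j1s[l])][loc]
                if us[l] < config.selfing_F:
                    row[l] = (a1, a1)
                else:
                    row[l] = (a1, haplos[int(j2s[l])][loc])
            calls.append(row)
            truth.individual_haplotype[ind] = acc_haplo
            phaseolin[ind] = PhaseolinCall(ind, PHASEOLIN_REFERENCE[acc_haplo],
                                           acc_haplo)

        metadata[acc] = AccessionMetadata(
            acc, region="simulated",
            latitude=float(rng.uniform(la, lb)),
            longitude=float(rng.uniform(lo_a, lo_b)))
        trait_rows.append(_simulate_traits(rng, acc, q))

    geno = GenotypeMatrix(individuals, loci, accession_of,
                          np.array(calls, dtype=np.int64))
    traits = TraitTable(pd.DataFrame(trait_rows).set_index("accession"))
    return SimulatedCollection(geno, phaseolin, traits, metadata, truth)


def _simulate_traits(rng, acc: str, q: np.ndarray) -> dict:
    K = len(q)
    means = np.zeros(6)
    for k in range(K):
        means += q[k] * np.array(_POOL_TRAIT_MEANS[k])
    sds = 0.08 * means
    L, W, H, wt, spp, lpp = np.maximum(rng.normal(means, sds), 0.5)
    flat, flat_idx, elong = seed_indices(L, W, H)

    def pick(trait: str, states: list[str]) -> str:
        w = np.zeros(len(states))
        for k in range(K):
            w += q[k] * np.array(_POOL_QUALITATIVE[trait][k])
        return states[int(rng.choice(len(states), p=w / w.sum()))]

    pattern = pick("seed_coat_pattern",
                   QUALITATIVE_STATES["seed_coat_pattern"])
    if pattern == "absent":
        color = pick("_plain_color",
                     QUALITATIVE_STATES["seed_coat_color"][:8])
    else:
        color = "patterned"
    return {
        "accession": acc,
        "seed_length_mm": float(L), "seed_width_mm": float(W),
        "seed_height_mm": float(H), "weight_100seed_g": float(wt),
        "seeds_per_pod": float(spp), "locules_per_pod": float(lpp),
        "elongation": float(elong), "flatness": float(flat),
        "flatness_index": float(flat_idx),
        "growth_habit": pick("growth_habit",
                             QUALITATIVE_STATES["growth_habit"]),
        "seed_shape": pick("seed_shape", QUALITATIVE_STATES["seed_shape"]),
        "seed_coat_pattern": pattern,
        "seed_coat_color": color,
        "seed_size": seed_size_class(float(wt)),
    }


def write_collection(sim: SimulatedCollection, outdir: str | Path) -> None:
    """Emit the same files real data would use, plus truth.json."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_interchange(sim.geno, "wide", outdir / "genotypes.csv")
    gio.write_interchange(sim.geno, "structure", outdir / "genotypes.str")
    sim.traits.data.to_csv(outdir / "traits.csv")
    rows = [{"individual": c.individual,
             "fragments": ";".join(map(str, c.fragments)),
             "haplotype": c.haplotype}
            for c in sim.phaseolin.values()]
    pd.DataFrame(rows).to_csv(outdir / "phaseolin.csv", index=False)
    pd.DataFrame([
        {"accession": m.accession, "region": m.region,
         "latitude": m.latitude, "longitude": m.longitude}
        for m in sim.metadata.values()]).to_csv(outdir / "coords.csv",
                                                index=False)
    truth = {
        "seed": sim.truth.seed,
        "config": dataclasses.asdict(sim.truth.config),
        "accession_kind": sim.truth.accession_kind,
        "accession_pool": sim.truth.accession_pool,
        "accession_q": {a: list(map(float, q))
                        for a, q in sim.truth.accession_q.items()},
        "individual_haplotype": sim.truth.individual_haplotype,
        "pool_frequencies": [
            {loc: {str(a): f for a, f in d.items()}
             for loc, d in pool.items()}
            for pool in sim.truth.pool_frequencies],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
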
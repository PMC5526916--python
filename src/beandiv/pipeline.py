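"""End-to-end orchestration: diversity → tree → AMOVA → IBD →
classification → morphology → core selection, from a single config.

Every stage is independently invocable through its module; the pipeline
simply sequences them over shared inputs and writes one table per stage
plus a provenance log (seeds and decision flags in effect).  Any stage
failure aborts with the stage name; tables already written are kept.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import em_admixture, loglik_admixture
from .amova import amova, ibd_test
from .classify import classify_collection
from .core import (build_universe, compare_core, mstrat_nested,
                   powercore_select, representative_individual)
from .distances import chord_matrix, dpsa_matrix, fst_matrix, pcoa
from .diversity import diversity_summary
from .io import write_newick, write_phylip_distance
from .morphology import anova_tukey, lr_chisq, ContingencyTable, \
    quantitative_summary, stepwise_discriminant
from .simulate import (POOL_HAPLOTYPES, SimulationConfig, simulate_collection,
                       write_collection)
from .trees import bootstrap_consensus

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full simulated-collection analysis run."""

    outdir: str = "results/pipeline"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    rarefaction_g: int | None = None
    chord_dialect: str = "default"
    tau: float = 0.75
    bootstrap: int = 100
    amova_permutations: int = 199
    mantel_permutations: int = 999
    core_sizes: tuple[int, ...] = (10, 15, 20, 25, 30)
    core_replicates: int = 20
    core_iterations: int = 50
    skip_phaseolin: bool = False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a simulated collection; return a summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:  # keep partial outputs
                log.append({"stage": name, "status": "failed",
                            "error": str(exc)})
                _write_log(out, config, log)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.append({"stage": name, "status": "ok",
                        "seconds": round(time.time() - t0, 2)})
        return wrap

    sim = simulate_collection(config.sim, config.seed)
    geno, truth = sim.geno, sim.truth
    write_collection(sim, out / "inputs")
    log.append({"stage": "simulate", "status": "ok",
                "n_individuals": geno.n_individuals,
                "n_loci": geno.n_loci})

    @stage("diversity")
    def _():
        table = diversity_summary(geno, g=config.rarefaction_g)
        table.to_csv(out / "diversity_per_accession.csv")
        summary["mean_H_O"] = float(table["H_O"].mean())
        summary["mean_H_E"] = float(table["H_E"].mean())
        summary["mean_N_a"] = float(table["N_a"].mean())

    @stage("distances_tree")
    def _():
        dm = chord_matrix(geno, dialect=config.chord_dialect)
        write_phylip_distance(dm.ids, dm.values, out / "chord.phylip")
        summary["mean_chord"] = float(dm.offdiag().mean())
        tree = bootstrap_consensus(geno, B=config.bootstrap,
                                   seed=config.seed,
                                   dialect=config.chord_dialect)
        write_newick(tree.dendropy_tree, out / "nj_chord.nwk")

    @stage("amova")
    def _():
        res = amova(geno, nperm=config.amova_permutations, seed=config.seed)
        pd.DataFrame({"stratum": res.strata, "df": res.df,
                      "variance": res.variance,
                      "pct_total": res.pct_total}).to_csv(
            out / "amova.csv", index=False)
        summary["amova_pct_among"] = res.pct_total[0]
        summary["amova_phi_st"] = res.phi["phi_st"]
        summary["amova_p"] = res.p_values["phi_st"]

    @stage("ibd")
    def _():
        fst = fst_matrix(geno)
        coords = {a: (m.latitude, m.longitude)
                  for a, m in sim.metadata.items()}
        res, lin, logkm = ibd_test(fst, coords,
                                   nperm=config.mantel_permutations,
                                   seed=config.seed)
        summary["mantel_r"] = res.r
        summary["mantel_p"] = res.p_value
        write_phylip_distance(lin.ids, lin.values, out / "fst_lin.phylip")

    @stage("classification")
    def _():
        if config.skip_phaseolin:
            log.append({"stage": "classification",
                        "status": "skipped: no phaseolin calls"})
            return
        Q = em_admixture(geno, truth.pool_frequencies)
        lnP = loglik_admixture(geno, truth.pool_frequencies, Q)
        run = {"K": config.sim.n_pools, "lnP": lnP, "Q": Q}
        cmap = {k: POOL_HAPLOTYPES[k] for k in range(config.sim.n_pools)}
        records = classify_collection(run, geno.accession_of, sim.phaseolin,
                                      cmap, tau=config.tau)
        df = pd.DataFrame([{
            "accession": r.accession, "category": r.category,
            "subtype": r.subtype,
            "max_Q": float(np.max(r.accession_q)),
            "admixed_fraction": r.admixed_individual_fraction}
            for r in records]).set_index("accession")
        df.to_csv(out / "classification.csv")
        counts = df["category"].value_counts()
        summary["n_truetype"] = int(counts.get("TrueType", 0))
        summary["frac_offtype"] = float(
            1 - counts.get("TrueType", 0) / len(df))
        summary["_records"] = records

    @stage("morphology")
    def _():
        quant = sim.traits.data[
            [c for c in sim.traits.data.columns
             if sim.traits.data[c].dtype.kind == "f"]]
        corr, scores, loadings, pct = quantitative_summary(quant)
        corr.to_csv(out / "trait_correlations.csv")
        summary["pca_pc12_pct"] = float(pct[:2].sum())
        records = summary.pop("_records", None)
        if records is None:
            return
        group = {r.accession: (r.subtype or r.category) for r in records
                 if r.category == "TrueType"}
        members = [a for a in group if a in sim.traits.data.index]
        if len(set(group[a] for a in members)) < 2:
            return
        labels = pd.Series({a: group[a] for a in members})
        tab = pd.crosstab(labels,
                          sim.traits.data.loc[members, "seed_shape"])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            G, dfree, p = lr_chisq(ContingencyTable(
                list(tab.index), list(tab.columns), tab.to_numpy()))
            summary["seed_shape_G_p"] = p
        groups_w = {g: sim.traits.data.loc[[a for a in members
                                            if group[a] == g],
                                           "weight_100seed_g"].to_numpy()
                    for g in sorted(set(group[a] for a in members))}
        if all(len(v) >= 2 for v in groups_w.values()):
            F, p, letters = anova_tukey(groups_w)
            summary["weight_anova_p"] = p
        model = stepwise_discriminant(
            quant.loc[members], labels)
        summary["stepdisc_traits"] = model.selected
        summary["stepdisc_cv_error"] = model.cv_error

    @stage("core")
    def _():
        rep = {a: representative_individual(geno, a)
               for a in geno.accessions}
        uni = build_universe(geno, sim.traits, rep)
        cores = mstrat_nested(geno, sim.traits, list(config.core_sizes),
                              replicates=config.core_replicates,
                              iterations=config.core_iterations,
                              seed=config.seed, universe=uni,
                              representative=rep)
        full = powercore_select(geno, sim.traits, universe=uni,
                                representative=rep)
        rows = [{"strategy": c.strategy, "size": c.size,
                 "allele_pct": c.allele_coverage_pct,
                 "trait_pct": c.trait_coverage_pct,
                 "shannon": c.shannon,
                 "members": ";".join(c.members)}
                for c in cores + [full]]
        pd.DataFrame(rows).to_csv(out / "core_subsets.csv", index=False)
        compare_core(geno, full.members, sim.traits, rep).to_csv(
            out / "core_vs_collection.csv")
        summary["core_full_coverage_size"] = full.size
        summary["core_full_allele_pct"] = full.allele_coverage_pct

        rep_geno = geno.subset([rep[a] for a in geno.accessions])
        dm = dpsa_matrix(rep_geno)
        res = pcoa(dm)
        pd.DataFrame(res.coordinates[:, :2], index=res.ids,
                     columns=["PCo1", "PCo2"]).to_csv(out / "pcoa.csv")
        summary["pcoa_pc12_pct"] = float(
            100 * res.proportion_explained[:2].sum())

    _write_log(out, config, log)
    summary = {k: v for k, v in summary.items() if not k.startswith("_")}
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return summary


def _write_log(out: Path, config: PipelineConfig, log: list[dict]) -> None:
    (out / "provenance.json").write_text(json.dumps({
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "decisions": {
            "chord_dialect": config.chord_dialect,
            "tau_boundary": "inclusive (>=)",
            "mantel_floor_km": 1.0,
            "bootstrap_resamples": "loci",
        },
        "stages": log,
    }, indent=1, default=str))
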
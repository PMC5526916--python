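"""Admixture post-processing and true-type/offtype classification.

Given externally produced admixture Q-matrices (plus run
log-likelihoods), this module selects the cluster number by Evanno's ΔK,
averages individual memberships into accession-level Q vectors, applies
the 75 % assignment rule, calls phaseolin haplotypes from PCR fragment
patterns, and classifies each accession into one of four categories that
reconcile cluster membership with phaseolin haplotype:

1. TrueType(cluster) — accession max Q ≥ τ, a single phaseolin haplotype
   across the accession's called individuals, and that haplotype matches
   the assigned cluster;
2. NonCorresponding — accession max Q ≥ τ but the haplotype condition
   fails (multiple haplotypes and/or mismatch);
3. Composite — accession max Q < τ with fewer than half of its
   individuals admixed;
4. Hybrid — accession max Q < τ with at least half admixed.

τ defaults to 0.75 and the boundary is inclusive (max Q = τ assigns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PhaseolinCall, QRunSet

__all__ = [
    "EvannoTable",
    "ClassificationRecord",
    "evanno",
    "accession_memberships",
    "assign",
    "call_phaseolin",
    "classify_accession",
    "classify_collection",
    "HAPLOTYPE_PHASEOLIN_TYPE",
]

#: phaseolin haplotype -> seed-protein type(s) it diagnoses
HAPLOTYPE_PHASEOLIN_TYPE = {"P1": ("S",), "P2": ("H", "C"), "P3": ("T",)}


@dataclass
class EvannoTable:
    """Per-K log-likelihood curvature statistics."""

    table: pd.DataFrame  # index K; columns mean_lnP, sd_lnP, Lp, Lpp, deltaK

    @property
    def best_k(self) -> int:
        d = self.table["deltaK"].dropna()
        if d.empty:
            raise ValueError("deltaK undefined at every interior K")
        return int(d.idxmax())


def evanno(q_runs: QRunSet) -> EvannoTable:
    """Evanno ΔK table from replicate admixture runs.

    ΔK(K) = mean|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)), defined at interior
    K with positive run-to-run sd.  Requires ≥ 2 runs per K over a
    contiguous K range of length ≥ 3.
    """
    ks = q_runs.ks()
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    stats = {}
    for k in ks:
        lnps = np.array([r["lnP"] for r in q_runs.runs_at(k)])
        if lnps.size < 2:
            raise ValueError(f"need >= 2 runs at K={k}")
        stats[k] = (lnps.mean(), lnps.std(ddof=1))
    rows = []
    for k in ks:
        mean, sd = stats[k]
        lp = lpp = dk = np.nan
        if k > ks[0]:
            lp = mean - stats[k - 1][0]
        if ks[0] < k < ks[-1]:
            lpp = abs(stats[k + 1][0] - 2 * mean + stats[k - 1][0])
            if sd > 0:
                dk = lpp / sd
            else:
                warnings.warn(f"sd(lnP)=0 at K={k}: deltaK undefined")
        rows.append({"K": k, "mean_lnP": mean, "sd_lnP": sd,
                     "Lp": lp, "Lpp": lpp, "deltaK": dk})
    return EvannoTable(pd.DataFrame(rows).set_index("K"))


def accession_memberships(q_run: dict, accession_of: dict[str, str]
                          ) -> dict[str, np.ndarray]:
    """Accession-level Q: unweighted mean of member individuals' vectors."""
    by_acc: dict[str, list[np.ndarray]] = {}
    for ind, q in q_run["Q"].items():
        by_acc.setdefault(accession_of[ind], []).append(np.asarray(q, float))
    missing = set(accession_of.values()) - set(by_acc)
    if missing:
        raise ValueError(f"accessions absent from run: {sorted(missing)}")
    return {acc: np.mean(qs, axis=0) for acc, qs in by_acc.items()}


def assign(q: np.ndarray, tau: float = 0.75) -> int | str:
    """Cluster index if max membership ≥ τ, else ``"admixed"``."""
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must be in (0.5, 1]")
    q = np.asarray(q, float)
    k = int(np.argmax(q))
    return k if q[k] >= tau else "admixed"


def call_phaseolin(fragments, reference_profiles: dict[str, tuple],
                   tolerance_bp: int = 1) -> str:
    """Label a fragment pattern by its unique matching reference profile.

    A pattern matches a reference when the sorted fragment multisets have
    equal length and agree within ± ``tolerance_bp`` per fragment.
    Returns ``"other"`` when nothing matches; raises on ambiguity.
    """
    obs = sorted(fragments)
    hits = []
    for label, ref in reference_profiles.items():
        ref = sorted(ref)
        if len(ref) == len(obs) and all(
                abs(o - r) <= tolerance_bp for o, r in zip(obs, ref)):
            hits.append(label)
    if len(hits) > 1:
        raise ValueError(f"pattern {obs} matches multiple references: {hits}")
    return hits[0] if hits else "other"


@dataclass
class ClassificationRecord:
    accession: str
    accession_q: np.ndarray
    admixed_individual_fraction: float
    haplotypes: frozenset
    category: str          # TrueType | Composite | Hybrid | NonCorresponding
    cluster: int | None    # assigned cluster for TrueType/NonCorresponding
    subtype: str | None    # e.g. "AP1"
    flags: list[str] = field(default_factory=list)


def classify_accession(accession: str,
                       acc_q: np.ndarray,
                       individual_qs: list[np.ndarray],
                       phaseolin_calls: list[PhaseolinCall],
                       cluster_haplotype_map: dict[int, str],
                       cluster_names: dict[int, str] | None = None,
                       tau: float = 0.75) -> ClassificationRecord:
    """Apply the four-way true-type/offtype decision for one accession.

    ``cluster_haplotype_map`` pairs each cluster index with its expected
    phaseolin haplotype (e.g. {0: "P1", 1: "P3", 2: "P2"}).  Haplotype
    uniqueness is evaluated over individuals with successful calls;
    accessions with zero calls cannot be resolved and raise.
    """
    acc_q = np.asarray(acc_q, float)
    called = [c.haplotype for c in phaseolin_calls if c.haplotype != "other"]
    haplos = frozenset(called)
    flags: list[str] = []
    if not phaseolin_calls:
        raise ValueError(f"accession {accession!r}: no phaseolin calls; "
                         "classification needs at least one")
    if not called:
        flags.append("no-reference-haplotype-called")
    frac_admixed = float(np.mean(
        [assign(q, tau) == "admixed" for q in individual_qs]))
    status = assign(acc_q, tau)
    names = cluster_names or {k: chr(ord("A") + k)
                              for k in range(acc_q.size)}
    if status != "admixed":
        cluster = int(status)
        expected = cluster_haplotype_map.get(cluster)
        if len(haplos) == 1 and expected in haplos:
            hap = next(iter(haplos))
            return ClassificationRecord(
                accession, acc_q, frac_admixed, haplos, "TrueType",
                cluster, f"{names[cluster]}{hap}", flags)
        return ClassificationRecord(accession, acc_q, frac_admixed, haplos,
                                    "NonCorresponding", cluster, None, flags)
    if frac_admixed < 0.5:
        if frac_admixed == 0.0:
            flags.append("near-threshold-composite")  # all pure yet mean < tau
        return ClassificationRecord(accession, acc_q, frac_admixed, haplos,
                                    "Composite", None, None, flags)
    return ClassificationRecord(accession, acc_q, frac_admixed, haplos,
                                "Hybrid", None, None, flags)


def classify_collection(q_run: dict, accession_of: dict[str, str],
                        phaseolin_by_individual: dict[str, PhaseolinCall],
                        cluster_haplotype_map: dict[int, str],
                        tau: float = 0.75) -> list[ClassificationRecord]:
    """Classify every accession from one chosen (max-likelihood) run."""
    acc_q = accession_memberships(q_run, accession_of)
    by_acc: dict[str, list[str]] = {}
    for ind in q_run["Q"]:
        by_acc.setdefault(accession_of[ind], []).append(ind)
    out = []
    for acc, inds in by_acc.items():
        out.append(classify_accession(
            acc, acc_q[acc],
            [q_run["Q"][i] for i in inds],
            [phaseolin_by_individual[i] for i in inds
             if i in phaseolin_by_individual],
            cluster_haplotype_map, tau=tau))
    return out
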
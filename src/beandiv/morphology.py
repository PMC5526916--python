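"""Seed/plant morphology statistics across accession groups.

Covers the derived seed-shape indices, the 100-seed-weight size classes,
likelihood-ratio (G) contingency tests for qualitative traits, one-way
ANOVA with Tukey HSD letter displays, trait correlations with PCA, and
forward stepwise discriminant analysis with leave-one-out
cross-validation.

Size-class boundaries follow the common-bean convention: small < 25 g,
medium 25–40 g inclusive, large > 40 g per 100 seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "seed_indices",
    "seed_size_class",
    "ContingencyTable",
    "lr_chisq",
    "anova_tukey",
    "quantitative_summary",
    "DiscriminantModel",
    "stepwise_discriminant",
]


def seed_indices(L_mm: float, W_mm: float, H_mm: float
                 ) -> tuple[float, float, float]:
    """(flatness, flatness_index, elongation) = (H/W, (L+H)/2W, L/H)."""
    if min(L_mm, W_mm, H_mm) <= 0:
        raise ValueError("seed dimensions must be positive")
    return H_mm / W_mm, (L_mm + H_mm) / (2 * W_mm), L_mm / H_mm


def seed_size_class(weight_100seed_g: float) -> str:
    """small (< 25 g), medium (25–40 g inclusive) or large (> 40 g)."""
    if weight_100seed_g <= 0:
        raise ValueError("100-seed weight must be positive")
    if weight_100seed_g < 25:
        return "small"
    if weight_100seed_g <= 40:
        return "medium"
    return "large"


# ---------------------------------------------------------------------------
# likelihood-ratio chi-square


@dataclass
class ContingencyTable:
    rows: list[str]
    cols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def without_empty(self) -> "ContingencyTable":
        """Drop all-zero rows/columns (structural zeros), with a warning."""
        r = self.counts.sum(axis=1) > 0
        c = self.counts.sum(axis=0) > 0
        if not (r.all() and c.all()):
            warnings.warn("dropping all-zero rows/columns from table")
        return ContingencyTable(
            [x for x, k in zip(self.rows, r) if k],
            [x for x, k in zip(self.cols, c) if k],
            self.counts[np.ix_(r, c)])


def lr_chisq(table: ContingencyTable) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square (G-test) of independence.

    G = 2 Σ O ln(O/E) over cells with O > 0, E from the product of
    marginals; df = (r−1)(c−1).  All-zero rows/columns are dropped first.
    """
    t = table.without_empty()
    O = t.counts
    N = O.sum()
    if N == 0:
        raise ValueError("zero grand total")
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need at least 2 informative rows and columns")
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / N
    G = float(2.0 * xlogy(O, O / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return G, df, float(stats.chi2.sf(G, df))


# ---------------------------------------------------------------------------
# ANOVA + Tukey letters


def _letter_display(groups: list[str], means: dict[str, float],
                    different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups in one clique of the
    'not-significantly-different' graph share a letter."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            pair = tuple(sorted((a, b)))
            if pair not in different:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: (-np.mean([means[x] for x in c]),
                                    sorted(c)))
    letters: dict[str, str] = {x: "" for x in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for x in clique:
            letters[x] += ch
    return letters


def anova_tukey(values_by_group: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA plus Tukey HSD letter display at the given alpha.

    Returns (F, p, letters) where ``letters`` maps group -> letter string;
    groups sharing a letter do not differ at P ≤ alpha.  Degenerate
    (zero within-group variance everywhere) data yields NaN F/p with all
    groups flagged by ``letters`` computed from exact equality.
    """
    groups = list(values_by_group)
    if len(groups) < 2 or any(len(v) < 2 for v in values_by_group.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    if all(np.ptp(a) == 0 for a in arrays):
        warnings.warn("zero within-group variance everywhere: F degenerate")
        different = {tuple(sorted((a, b)))
                     for i, a in enumerate(groups) for b in groups[i + 1:]
                     if means[a] != means[b]}
        return float("nan"), float("nan"), _letter_display(groups, means,
                                                           different)
    F, p = stats.f_oneway(*arrays)
    data = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    different = set()
    for (a, b), rej in zip(
            [(tk.groupsunique[i], tk.groupsunique[j])
             for i in range(len(tk.groupsunique))
             for j in range(i + 1, len(tk.groupsunique))],
            tk.reject):
        if rej:
            different.add(tuple(sorted((str(a), str(b)))))
    return float(F), float(p), _letter_display(groups, means, different)


# ---------------------------------------------------------------------------
# correlations + PCA


def quantitative_summary(traits: pd.DataFrame):
    """Pearson correlations on raw traits and PCA on standardized traits.

    Complete-case analysis.  Returns (corr, scores, loadings,
    pct_variance); constant traits make their correlations NaN (flagged
    by a warning) and are dropped from the PCA.
    """
    df = traits.dropna()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    corr = df.corr(method="pearson")
    const = [c for c in df.columns if df[c].nunique() == 1]
    if const:
        warnings.warn(f"constant traits dropped from PCA: {const}")
    work = df.drop(columns=const)
    Z = (work - work.mean()) / work.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per axis
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = pd.DataFrame(U * S, index=work.index,
                          columns=[f"PC{i+1}" for i in range(len(S))])
    loadings = pd.DataFrame(Vt.T, index=work.columns, columns=scores.columns)
    var = S ** 2
    pct = 100 * var / var.sum()
    return corr, scores, loadings, pct


# ---------------------------------------------------------------------------
# stepwise discriminant analysis


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' Λ = det(W)/det(T) for the selected variable set."""
    T = np.cov(X, rowvar=False, ddof=0) * len(X)
    if X.shape[1] == 1:
        T = T.reshape(1, 1)
    W = np.zeros_like(T)
    for g in np.unique(y):
        sub = X[y == g]
        if len(sub) > 1:
            c = np.cov(sub, rowvar=False, ddof=0) * len(sub)
            W += c.reshape(T.shape)
    detT = np.linalg.det(T)
    if detT <= 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


@dataclass
class DiscriminantModel:
    selected: list[str]
    partial_r2: list[float]
    entry_F: list[float]
    entry_p: list[float]
    wilks_lambda: list[float]
    cv_error: float
    classifier: LinearDiscriminantAnalysis | None
    posterior_group: pd.Series | None


def stepwise_discriminant(traits: pd.DataFrame, groups: pd.Series,
                          entry_alpha: float = 0.15) -> DiscriminantModel:
    """Forward stepwise discriminant analysis with LOO cross-validation.

    At each step the candidate trait with the largest partial r²
    (1 − Λ(S∪{x})/Λ(S)) enters if its ANCOVA F-test p-value ≤
    ``entry_alpha`` (the SAS STEPDISC default 0.15).  The final variable
    set feeds a linear discriminant classifier with equal priors;
    ``cv_error`` is the leave-one-out misclassification rate and
    ``posterior_group`` the fitted model's per-record assignment.
    """
    df = traits.dropna()
    y = groups.loc[df.index].to_numpy()
    labels = np.unique(y)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n = len(df)
    selected: list[str] = []
    r2s, fs, ps, lambdas = [], [], [], []
    lam_current = 1.0
    remaining = list(df.columns)
    while remaining:
        best = None
        p_sel = len(selected)
        for cand in remaining:
            cols = selected + [cand]
            lam = _wilks_lambda(df[cols].to_numpy(), y)
            partial = lam / lam_current if lam_current > 0 else 1.0
            r2 = 1.0 - partial
            df2 = n - g - p_sel
            if df2 <= 0 or partial <= 0:
                continue
            F = (df2 / (g - 1)) * (1 - partial) / partial
            pval = float(stats.f.sf(F, g - 1, df2))
            if best is None or r2 > best[1]:
                best = (cand, r2, F, pval, lam)
        if best is None or best[3] > entry_alpha:
            break
        cand, r2, F, pval, lam = best
        selected.append(cand)
        remaining.remove(cand)
        r2s.append(r2)
        fs.append(F)
        ps.append(pval)
        lambdas.append(lam)
        lam_current = lam
    if not selected:
        warnings.warn("no trait passes the entry threshold: empty model")
        return DiscriminantModel([], [], [], [], [], float("nan"), None, None)
    X = df[selected].to_numpy()
    priors = np.full(g, 1.0 / g)
    # leave-one-out cross-validated error
    wrong = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < g:
            continue
        clf = LinearDiscriminantAnalysis(priors=priors)
        clf.fit(X[mask], y[mask])
        wrong += int(clf.predict(X[i:i + 1])[0] != y[i])
    clf = LinearDiscriminantAnalysis(priors=priors)
    clf.fit(X, y)
    posterior = pd.Series(clf.predict(X), index=df.index, name="group")
    return DiscriminantModel(selected, r2s, fs, ps, lambdas,
                             wrong / n, clf, posterior)
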
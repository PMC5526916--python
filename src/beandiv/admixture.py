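"""Supervised EM estimation of individual admixture proportions.

Plumbing, not inference machinery: the production analysis consumes
Q-matrices produced by an external model-based clustering sampler.  This
estimator exists so the classifier, pipeline and tests can be exercised
on simulated collections without external software — the ancestral pool
allele frequencies are taken as *known* (supervised), and only the
per-individual membership vector q is estimated.

Model: each of an individual's gene copies at locus l derives from pool
z ~ Categorical(q) and is allele a with probability p_z(l, a).  The EM
update is the classic responsibility average over the individual's
non-missing gene copies.
"""

from __future__ import annotations

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = ["em_admixture", "loglik_admixture"]


def _copy_prob_tensor(geno: GenotypeMatrix,
                      pool_freqs: list[dict[str, dict[int, float]]]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """P[k, i, c] for copy c of individual i under pool k, plus a mask."""
    K = len(pool_freqs)
    n, L = geno.n_individuals, geno.n_loci
    P = np.zeros((K, n, 2 * L))
    mask = np.zeros((n, 2 * L), dtype=bool)
    floor = 1e-6  # unseen alleles keep positive likelihood
    for l, locus in enumerate(geno.loci):
        for slot in (0, 1):
            col = geno.alleles[:, l, slot]
            ok = col != MISSING
            mask[:, 2 * l + slot] = ok
            for k in range(K):
                f = pool_freqs[k].get(locus, {})
                P[k, ok, 2 * l + slot] = np.array(
                    [max(f.get(int(a), 0.0), floor) for a in col[ok]])
    return P, mask


def em_admixture(geno: GenotypeMatrix,
                 pool_freqs: list[dict[str, dict[int, float]]],
                 n_iter: int = 200, tol: float = 1e-8
                 ) -> dict[str, np.ndarray]:
    """Estimate per-individual admixture q given known pool frequencies.

    ``pool_freqs[k]`` maps locus -> {allele: frequency} for pool k.
    Returns individual id -> simplex vector of length K.
    """
    K = len(pool_freqs)
    if K < 1:
        raise ValueError("need at least one pool")
    P, mask = _copy_prob_tensor(geno, pool_freqs)
    n = geno.n_individuals
    q = np.full((n, K), 1.0 / K)
    for _ in range(n_iter):
        # responsibilities r[k, i, c] ∝ q[i, k] * P[k, i, c]
        w = q.T[:, :, None] * P
        denom = w.sum(axis=0)
        denom[~mask] = 1.0
        r = w / denom
        r[:, ~mask] = 0.0
        new_q = r.sum(axis=2).T
        new_q /= new_q.sum(axis=1, keepdims=True)
        if np.abs(new_q - q).max() < tol:
            q = new_q
            break
        q = new_q
    return {ind: q[i].copy() for i, ind in enumerate(geno.individuals)}


def loglik_admixture(geno: GenotypeMatrix,
                     pool_freqs: list[dict[str, dict[int, float]]],
                     Q: dict[str, np.ndarray]) -> float:
    """Log-likelihood of the data under (pool_freqs, Q)."""
    P, mask = _copy_prob_tensor(geno, pool_freqs)
    q = np.array([Q[ind] for ind in geno.individuals])
    mix = np.einsum("ik,kic->ic", q, P)
    return float(np.log(mix[mask]).sum())
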
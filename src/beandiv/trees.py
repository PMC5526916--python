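"""Neighbor-joining trees with bootstrap-over-loci support.

NJ follows the Saitou–Nei agglomeration; on additive input distances the
tree path lengths reproduce the input exactly.  Determinism: ties in the
Q-matrix minimisation are broken by the lowest (row, col) index pair, and
negative branch lengths are clamped to 0 with the clamp count recorded on
the result.

Bootstrap support resamples loci with replacement (the SEQBOOT
convention for multilocus allele-frequency data), rebuilds the chord NJ
tree per replicate, and annotates each internal edge of the full-data
tree with the percentage of replicates whose tree contains the same leaf
bipartition (majority-rule style supports in [0, 100]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diversity import allele_frequencies
from .distances import (DistanceMatrix, chord_matrix_from_loci,
                        locus_frequency_matrices)
from .io import GenotypeMatrix

__all__ = ["Tree", "neighbor_joining", "bootstrap_consensus"]


@dataclass
class Tree:
    """Unrooted tree over leaf ids, wrapping a dendropy tree."""

    dendropy_tree: dendropy.Tree
    leaf_ids: list[str]
    n_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    def patristic(self, a: str, b: str) -> float:
        pdm = self.dendropy_tree.phylogenetic_distance_matrix()
        ns = self.dendropy_tree.taxon_namespace
        return pdm.patristic_distance(ns.get_taxon(a), ns.get_taxon(b))

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozenset)."""
        return _bipartitions(self.dendropy_tree, set(self.leaf_ids))

    def newick(self) -> str:
        return self.dendropy_tree.as_string(schema="newick",
                                            suppress_rooting=True)


def _bipartitions(tree: dendropy.Tree, all_leaves: set[str]) -> set[frozenset]:
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            other = frozenset(all_leaves - side)
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining on a distance matrix."""
    D = np.array(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 entities")

    ns = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    clamp_count = 0

    def clamp(x: float) -> float:
        nonlocal clamp_count
        if x < 0:
            clamp_count += 1
            return 0.0
        return x

    if n == 2:
        root = dendropy.Node()
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        nodes[0].edge.length = clamp(D[0, 1])
        nodes[1].edge.length = 0.0
        tree.seed_node = root
        tree.update_taxon_namespace()
        return Tree(tree, list(dm.ids), clamp_count)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # lowest flat index
        i, j = sorted(best)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = dendropy.Node()
        u.add_child(nodes[active[i]])
        u.add_child(nodes[active[j]])
        nodes[active[i]].edge.length = clamp(li)
        nodes[active[j]].edge.length = clamp(lj)
        # distances from the new node to every other active node
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k, ak in enumerate(active):
            D[-1, ak] = D[ak, -1] = new_d[k]
        D[-1, -1] = 0.0
        nodes.append(u)
        active = [a for t, a in enumerate(active) if t not in (i, j)]
        active.append(D.shape[0] - 1)

    # star-join the last three
    a, b, c = active
    root = dendropy.Node()
    for x in (a, b, c):
        root.add_child(nodes[x])
    nodes[a].edge.length = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    nodes[b].edge.length = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    nodes[c].edge.length = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    tree.seed_node = root
    tree.update_taxon_namespace()
    return Tree(tree, list(dm.ids), clamp_count)


def bootstrap_consensus(geno: GenotypeMatrix, B: int = 1000,
                        seed: int = 0, dialect: str = "default") -> Tree:
    """Chord-distance NJ tree with bootstrap-over-loci edge supports.

    Loci are resampled with replacement ``B`` times; each internal edge of
    the full-data tree carries the percentage of replicate trees sharing
    its bipartition, stored in ``supports`` and as internal node labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if geno.n_loci == 1:
        warnings.warn("single locus: bootstrap supports are degenerate")
    table = allele_frequencies(geno)
    mats = locus_frequency_matrices(table)
    groups = table.groups
    all_idx = np.arange(geno.n_loci)
    full = neighbor_joining(
        chord_matrix_from_loci(mats, groups, all_idx, dialect))
    target = {bp: 0 for bp in full.bipartitions()}
    rng = np.random.default_rng(seed)
    leaves = set(full.leaf_ids)
    for _ in range(B):
        pick = rng.integers(0, geno.n_loci, size=geno.n_loci)
        rep = neighbor_joining(
            chord_matrix_from_loci(mats, groups, pick, dialect))
        for bp in _bipartitions(rep.dendropy_tree, leaves):
            if bp in target:
                target[bp] += 1
    full.supports = {bp: 100.0 * c / B for bp, c in target.items()}
    # annotate internal nodes for Newick output
    for node in full.dendropy_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, frozenset(leaves - side),
                  key=lambda s: (len(s), sorted(s)))
        if key in full.supports:
            node.label = f"{full.supports[key]:.0f}"
    return full
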
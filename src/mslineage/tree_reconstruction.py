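"""Neighbor-joining lineage trees, median rooting and depth readout.

The distance matrix (ML division distances) includes the median pseudo-zygote
as a competing taxon labelled ``root_median``.  The unrooted Saitou-Nei tree
is then re-rooted at the attachment node of that pseudo-leaf, the pseudo-leaf
is removed, and each cell's *depth* (divisions since the zygote) is read off
as the branch-length sum from the root to its leaf.

Everything is deterministic: input labels are canonicalised upstream and
Q-matrix ties break by the lexicographically smallest label pair, so the same
matrix always yields the same tree.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .stepwise_model import ROOT_LABEL, DistanceMatrix


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree (trifurcating seed node).  Negative branch
    lengths that NJ can produce are preserved; they are clamped only at
    depth-readout time.  Ties in the Q criterion are broken by the smallest
    (lexicographic) pair of subtree labels, where an internal node inherits
    the smallest leaf label below it.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(dm.d, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.new_taxon(label=label))
        nodes.append(node)
        keys.append(label)
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        # subtraction order makes Q[i,j] and Q[j,i] differ in the last bit;
        # search the upper triangle only so ties are found reliably
        iu, ju = np.triu_indices(r, k=1)
        qvals = Q[iu, ju]
        qmin = qvals.min()
        best = None
        for a, b in zip(iu[qvals == qmin], ju[qvals == qmin]):
            pair = tuple(sorted((keys[active[a]], keys[active[b]])))
            if best is None or pair < best[0]:
                best = (pair, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    center = dendropy.Node()
    nodes[i].edge.length = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    nodes[j].edge.length = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    nodes[k].edge.length = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for c in (i, j, k):
        center.add_child(nodes[c])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_at_median(tree: dendropy.Tree) -> dendropy.Tree:
    """Re-root the tree at the attachment node of the ``root_median``
    pseudo-leaf and remove the pseudo-leaf itself.

    The pendant edge of the pseudo-leaf never contributes to any cell depth.
    The input tree is left untouched; a rooted copy is returned.
    """
    tree = tree.clone(depth=1)
    pseudo = tree.find_node_with_taxon_label(ROOT_LABEL)
    if pseudo is None:
        raise ValueError(f"tree has no leaf labelled {ROOT_LABEL!r}")
    anchor = pseudo.parent_node
    if anchor is None:
        raise ValueError("pseudo-root leaf cannot be the seed node")
    tree.reroot_at_node(anchor, update_bipartitions=False)
    anchor.remove_child(pseudo)
    tree.prune_leaves_without_taxa()
    anchor.edge.length = None
    tree.is_rooted = True
    return tree


def leaf_depths(
    tree: dendropy.Tree, clamp_negative: bool = True
) -> dict[str, float]:
    """Branch-length sum from the root to each leaf, per cell.

    Depths are division counts and must be non-negative, so NJ-produced
    negative branch lengths are clamped to zero before summation by default
    (the tree itself keeps the raw values).
    """
    if not tree.is_rooted:
        raise ValueError("leaf depths require a rooted tree")
    depths: dict[str, float] = {}
    acc: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        if clamp_negative:
            length = max(length, 0.0)
        acc[id(node)] = acc[id(node.parent_node)] + length
        if node.is_leaf() and node.taxon is not None:
            depths[node.taxon.label] = acc[id(node)]
    return depths


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a rooted lineage tree as Newick with 6-decimal branch lengths."""
    if not tree.is_rooted:
        raise ValueError("refusing to write an unrooted lineage tree")
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )
    Path(path).write_text(text)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )
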
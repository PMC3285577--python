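"""Clade enrichment of cell populations on reconstructed lineage trees.

Every internal branch defines a subtree (the leaf set on the side away from
the root).  A one-sided hypergeometric test asks whether that leaf set is
enriched for a given population; all branch tests enter one
Benjamini-Hochberg family (FDR 0.2 for data analyses, 0.05 for simulation
studies), and among nested significant subtrees only the most significant is
retained.  A population "clusters" on a tree when at least one branch
survives this procedure -- the signal used both for the oocyte-vs-bone-marrow
analyses and for bounding progenitor numbers by simulation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

FDR_DATA = 0.2
FDR_SIMULATION = 0.05


@dataclass
class EnrichmentRecord:
    """One internal branch's hypergeometric enrichment result."""

    branch_id: str
    population: str
    k: int  # population leaves inside the subtree
    n: int  # subtree leaves
    K: int  # population leaves in the whole tree
    N: int  # leaves in the whole tree
    p: float
    q_significant: bool = False
    pruned: bool = False
    leaf_ids: frozenset = frozenset()


def hypergeom_enrichment_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not 0 <= k <= min(n, K):
        raise ValueError(f"invalid counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def subtree_enrichment(
    tree: dendropy.Tree,
    labels: Mapping[str, str],
    population: str,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of ``population`` under every internal branch.

    ``labels`` maps leaf (cell) ids to population labels; every leaf must be
    labelled.  Branches subtending leaves (pendant edges) carry no clustering
    information beyond membership and are not tested.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in labels]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing[:5]}")
    N = len(leaves)
    K = sum(1 for l in leaves if labels[l] == population)
    if K == 0:
        warnings.warn(
            f"population {population!r} absent from tree", RuntimeWarning
        )
        return []
    records = []
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf() or node.parent_node is None:
            continue
        sub = frozenset(lf.taxon.label for lf in node.leaf_iter())
        n = len(sub)
        k = sum(1 for l in sub if labels[l] == population)
        records.append(
            EnrichmentRecord(
                branch_id=f"b{i:04d}",
                population=population,
                k=k,
                n=n,
                K=K,
                N=N,
                p=hypergeom_enrichment_p(k, n, K, N),
                leaf_ids=sub,
            )
        )
    return records


def fdr_select(
    records: Sequence[EnrichmentRecord], q: float = FDR_DATA
) -> list[EnrichmentRecord]:
    """Benjamini-Hochberg step-up selection over one family of branch tests.

    Returns copies with ``q_significant`` set; the input family is whatever
    the caller pooled (all populations of one tree by default).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if not records:
        return []
    reject, _, _, _ = multipletests(
        [r.p for r in records], alpha=q, method="fdr_bh"
    )
    return [
        dataclasses.replace(r, q_significant=bool(flag))
        for r, flag in zip(records, reject)
    ]


def prune_nested(
    records: Sequence[EnrichmentRecord],
    tree: Optional[dendropy.Tree] = None,
) -> list[EnrichmentRecord]:
    """Among nested significant subtrees keep only the most significant.

    Nesting is leaf-set containment (ancestor/descendant branches of one
    tree), assessed within each population.  The minimum-p record of every
    nested group keeps its significance; ties prefer the larger subtree.
    """
    out = [dataclasses.replace(r) for r in records]
    for population in {r.population for r in out}:
        sig = [r for r in out if r.population == population and r.q_significant]
        sig.sort(key=lambda r: (r.p, -r.n, r.branch_id))
        kept: list[EnrichmentRecord] = []
        for rec in sig:
            nested = any(
                rec.leaf_ids <= other.leaf_ids or other.leaf_ids <= rec.leaf_ids
                for other in kept
            )
            if nested:
                rec.q_significant = False
                rec.pruned = True
            else:
                kept.append(rec)
    return out


def clustering_detected(
    tree: dendropy.Tree,
    labels: Mapping[str, str],
    population: str,
    q: float = FDR_DATA,
) -> bool:
    """True when at least one branch remains significantly enriched for the
    population after FDR selection and nested-subtree pruning."""
    records = subtree_enrichment(tree, labels, population)
    records = prune_nested(fdr_select(records, q))
    return any(r.q_significant for r in records)


def ovary_mixing_report(
    tree: dendropy.Tree,
    side_labels: Mapping[str, str],
    q: float = FDR_DATA,
) -> dict:
    """Test whether oocytes from the two ovaries form side-specific clades.

    ``side_labels`` maps oocyte cell ids to ``left`` / ``right``; the tree is
    restricted to those leaves, both side labels are tested as populations in
    one pooled BH family, and detection of either side counts as clustering
    (coherent progenitor migration).  Absence of detection is the signature
    of spatially incoherent progenitor mixing.
    """
    sides = {"left", "right"}
    counts = {s: sum(1 for v in side_labels.values() if v == s) for s in sides}
    if min(counts.values()) < 3:
        warnings.warn(
            f"fewer than 3 oocytes on a side ({counts}); mixing report undefined",
            RuntimeWarning,
        )
        return {"detected": None, "records": [], "n_per_side": counts}
    induced = tree.extract_tree_with_taxa_labels(list(side_labels))
    induced.is_rooted = tree.is_rooted
    records: list[EnrichmentRecord] = []
    for side in sorted(sides):
        records.extend(subtree_enrichment(induced, side_labels, side))
    records = prune_nested(fdr_select(records, q))
    return {
        "detected": any(r.q_significant for r in records),
        "records": records,
        "n_per_side": counts,
    }


def records_to_frame(records: Sequence[EnrichmentRecord]):
    """Flatten records to a pandas DataFrame (TSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "branch_id": r.branch_id,
                "population": r.population,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "q_significant": r.q_significant,
                "pruned": r.pruned,
            }
            for r in records
        ]
    )
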
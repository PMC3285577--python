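"""End-to-end reconstruction: signatures -> root -> distances -> tree -> depths."""

from __future__ import annotations

from typing import Sequence

import dendropy

from .signature_io import CellSignature, RootSignature, compute_root_signature
from .stepwise_model import (
    MIN_OVERLAP_DEFAULT,
    StepwiseModel,
    build_distance_matrix,
)
from .tree_reconstruction import leaf_depths, neighbor_joining, root_at_median


def reconstruct_lineage_tree(
    cells: Sequence[CellSignature],
    model: StepwiseModel | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> tuple[dendropy.Tree, RootSignature]:
    """Reconstruct the rooted lineage tree of a set of cells.

    The median root signature competes in the NJ run as an extra taxon; the
    returned tree is re-rooted at its attachment point with the pseudo-leaf
    removed, so depths are measured from the putative zygote.
    """
    model = model or StepwiseModel()
    root = compute_root_signature(list(cells))
    dm = build_distance_matrix(cells, root, model, min_overlap=min_overlap)
    tree = root_at_median(neighbor_joining(dm))
    return tree, root


def estimate_depths(
    cells: Sequence[CellSignature],
    model: StepwiseModel | None = None,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    clamp_negative: bool = True,
) -> dict[str, float]:
    """Per-cell depth (divisions since the zygote) via the tree-ML pipeline."""
    tree, _ = reconstruct_lineage_tree(cells, model, min_overlap=min_overlap)
    return leaf_depths(tree, clamp_negative=clamp_negative)
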
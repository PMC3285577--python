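import numpy as np
import pytest

from mslineage.signature_io import CellSignature, Locus


@pytest.fixture
def panel3():
    return [
        Locus("L000", 2, 20, 40),
        Locus("L001", 1, 15, 55),
        Locus("L002", 2, 22, 44),
    ]


def make_cell(cell_id, devs, **meta):
    """Build a CellSignature from {(locus, parental): deviation}."""
    defaults = dict(mouse_id="M1", age_days=30, population="oocyte")
    defaults.update(meta)
    return CellSignature(cell_id=cell_id, deviations=dict(devs), **defaults)


@pytest.fixture
def make_signature():
    return make_cell


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix (independent oracle for NJ exactness)."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(label=f"t{i:02d}")) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        a.edge.length = float(rng.uniform(0.5, 5.0))
        b.edge.length = float(rng.uniform(0.5, 5.0))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tns)
    taxa = {t.label: t for t in tns}
    d = np.zeros((n_leaves, n_leaves))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[la], taxa[lb])
    return tree, labels, d
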
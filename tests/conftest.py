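import numpy as np
import pytest

import saturascreen as ss


@pytest.fixture
def jc():
    return ss.SubstitutionModel()


@pytest.fixture
def gtr():
    return ss.SubstitutionModel.gtr([0.3, 0.2, 0.3, 0.2], [1, 2, 1, 1, 3, 1])


@pytest.fixture
def four_taxon_chronogram():
    return ss.read_chronogram("((A:1,B:1):1.5,(C:2,D:2):0.5);")


@pytest.fixture
def small_chronogram():
    """A 12-taxon, root-age-390 chronogram (seeded)."""
    cfg = ss.SimulationConfig(n_taxa=12, root_age=390.0, seed=42)
    return ss.simulate_chronogram(cfg)


def random_chronogram(rng: np.random.Generator, n_taxa: int,
                      root_age: float = 10.0) -> "ss.Chronogram":
    """Random coalescent-style ultrametric tree for property tests."""
    import dendropy
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = []
    tns = dendropy.TaxonNamespace()
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = dendropy.Taxon(lab)
        tns.add_taxon(nd.taxon)
        nd._h = 0.0
        nodes.append(nd)
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(0.2, 1.0))
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent._h = h
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = h - child._h
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    scale = root_age / root._h
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return ss.Chronogram(tree)
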
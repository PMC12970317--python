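import dendropy
import numpy as np
import pytest

from otudelim import distance_matrix
from otudelim.synthdata import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One simulated 5-species dataset with truth (session-cached)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_dm(sim_default):
    alignment, truth = sim_default
    return distance_matrix(alignment)


def random_binary_tree(rng: np.random.Generator, n_leaves: int, min_len=0.001, max_len=1.0):
    """Random rooted binary tree by sequential random joins (test-side oracle
    input generator, independent of the package's tree builders)."""
    taxa = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=taxa.new_taxon(label=f"L{i:02d}")) for i in range(n_leaves)]
    for nd in nodes:
        nd.edge.length = float(rng.uniform(min_len, max_len))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(min_len, max_len))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    return tree


def tree_path_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Leaf-pair path lengths via root-to-leaf distances (test-side oracle)."""
    dists = {}
    for leaf in tree.leaf_node_iter():
        path = 0.0
        nd = leaf
        anc = []
        while nd is not None:
            anc.append((nd, path))
            if nd.edge.length is not None:
                path += nd.edge.length
            nd = nd.parent_node
        dists[leaf.taxon.label] = dict()
        dists[leaf.taxon.label]["anc"] = anc
    out = {}
    labels = sorted(dists)
    for i, a in enumerate(labels):
        anc_a = {id(nd): d for nd, d in dists[a]["anc"]}
        for b in labels[i + 1 :]:
            best = None
            for nd, d_b in dists[b]["anc"]:
                if id(nd) in anc_a:
                    best = anc_a[id(nd)] + d_b
                    break
            out[frozenset((a, b))] = best
    return out
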
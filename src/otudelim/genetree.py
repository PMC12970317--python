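"""Guide-tree construction: neighbor joining on the K2P matrix and midpoint
rooting.

An externally supplied ML tree is the preferred guide tree when available;
neighbor joining is the dependency-free default.  Joins pick the pair
minimising the standard Q-criterion, with ties broken by the smallest
(i, j) index pair so runs are deterministic.  Negative estimated branch
lengths are clamped to zero (count logged).  On an additive matrix NJ
reproduces the generating path lengths exactly, which the tests exploit.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix

log = logging.getLogger(__name__)


def two_taxon_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """The trivial rooted tree for exactly two taxa (half the distance each)."""
    if len(dm) != 2:
        raise ValueError("two_taxon_tree needs exactly 2 taxa")
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    half = float(dm.d[0, 1]) / 2.0
    for sid in dm.ids:
        node = dendropy.Node(taxon=taxa.new_taxon(label=sid))
        root.add_child(node)
        node.edge.length = half
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree."""
    n = len(dm)
    if n < 3:
        raise ValueError(
            "neighbor joining needs >= 3 taxa; join 2 taxa with a single edge"
        )
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for sid in dm.ids:
        taxon = taxa.new_taxon(label=sid)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among ties, scanning row-major upper triangle
        best = np.inf
        bi = bj = -1
        for i in range(m - 1):
            row = q[i, i + 1 :]
            j_rel = int(np.argmin(row))
            if row[j_rel] < best:
                best = row[j_rel]
                bi, bj = i, i + 1 + j_rel
        i, j = bi, bj
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        gi, gj = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = clamp(li)
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = clamp(lj)
        # distances from the new node to the remaining taxa
        rest = [g for k, g in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (d[gi, rest] + d[gj, rest] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        g_new = d.shape[0] - 1
        d[g_new, rest] = new_d
        d[rest, g_new] = new_d
        nodes.append(parent)
        active = rest + [g_new]

    # final three-point join
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for g, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[g])
        nodes[g].edge.length = clamp(length)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    if n_clamped:
        log.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def path_length_matrix(tree: dendropy.Tree, ids: tuple[str, ...]) -> np.ndarray:
    """Leaf-to-leaf path lengths ordered by ``ids`` (additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path."""
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    rooted = tree.clone(depth=1)
    if max(
        leaf.distance_from_root() for leaf in rooted.leaf_node_iter()
    ) <= 0.0:  # all-zero branch lengths: midpoint undefined, keep seed root
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=True)
    rooted.is_rooted = True
    if rooted.seed_node.edge.length is None:
        rooted.seed_node.edge.length = 0.0
    return rooted
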
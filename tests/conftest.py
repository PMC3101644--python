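"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from supertreesim import profile_sim, treekit
from supertreesim.treekit import PhyloTree, bipartition_set, read_newick


def random_tree(n: int, seed: int, *, lengths: bool = True) -> PhyloTree:
    """Random binary tree fixture (Yule topology, unit height)."""
    t = profile_sim.simulate_model_tree(n, seed=seed)
    if not lengths:
        return read_newick(t.to_newick(lengths=False))
    return t


@pytest.fixture
def quartet_tree():
    return read_newick("((a,b),(c,d));")


@pytest.fixture
def six_leaf_tree():
    return read_newick("(((a,b),c),((d,e),f));")


# ---------------------------------------------------------------------------
# independent oracles


def restriction_oracle_bipartitions(tree: PhyloTree, subset) -> frozenset:
    """Brute-force restriction of every bipartition to the subset."""
    out = set()
    for bip in bipartition_set(tree):
        r = bip.restricted(subset)
        if r is not None:
            out.add(r)
    return frozenset(out)


def induced_quartet_oracle(tree: PhyloTree, four):
    """Restrict-then-read oracle for quartet induction."""
    sub = treekit.restrict(tree, four)
    bips = bipartition_set(sub)
    if not bips:
        return None
    (bip,) = bips
    return treekit.QuartetTopology(sorted(bip.side1), sorted(bip.side2))


def networkx_leaf_distances(tree: PhyloTree):
    """Edge-count leaf distances via networkx shortest paths on the
    unrooted tree graph."""
    import networkx as nx

    adj, leaf_nodes = tree._unrooted_adjacency(weighted=False)
    g = nx.Graph()
    for u, nbrs in adj.items():
        for v, _ in nbrs:
            g.add_edge(id(u), id(v))
    labels = sorted(leaf_nodes)
    n = len(labels)
    D = np.zeros((n, n), dtype=int)
    for i, a in enumerate(labels):
        lengths = nx.single_source_shortest_path_length(g, id(leaf_nodes[a]))
        for j, b in enumerate(labels):
            D[i, j] = lengths[id(leaf_nodes[b])]
    return labels, D


def all_unrooted_topologies(taxa):
    """Every unrooted binary topology on the given taxa, by recursive
    leaf insertion (3 taxa: 1 tree; 6 taxa: 105 trees)."""
    taxa = list(taxa)

    def variants(node, leaf, is_root=False):
        """All ways to attach ``leaf`` on an edge of the subtree: either on
        the edge above this node or inside one of its children."""
        out = [] if is_root else [(node, leaf)]
        if isinstance(node, tuple):
            for k, child in enumerate(node):
                for v in variants(child, leaf):
                    out.append(node[:k] + (v,) + node[k + 1:])
        return out

    def build(remaining, struct):
        if not remaining:
            yield struct
            return
        leaf, rest = remaining[0], remaining[1:]
        for variant in variants(struct, leaf, is_root=True):
            yield from build(rest, variant)

    def to_newick(struct):
        if isinstance(struct, str):
            return struct
        return "(" + ",".join(to_newick(c) for c in struct) + ")"

    seen = {}
    base = (taxa[0], taxa[1], taxa[2])
    for struct in build(taxa[3:], base):
        t = read_newick(to_newick(struct) + ";")
        seen[treekit.topology_key(t)] = t
    return list(seen.values())


def fitch_bruteforce(tree: PhyloTree, column: dict) -> int:
    """Minimum state changes for one column by exhaustive assignment of
    0/1 to internal nodes (and to '?' leaves)."""
    dt = tree.dendropy_tree
    nodes = list(dt.preorder_node_iter())
    free = [
        nd for nd in nodes
        if not nd.is_leaf() or column.get(nd.taxon.label, "?") == "?"
    ]
    fixed = {
        nd: int(column[nd.taxon.label])
        for nd in nodes
        if nd.is_leaf() and column.get(nd.taxon.label, "?") != "?"
    }
    best = np.inf
    for bits in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(dict(zip(free, bits)))
        changes = sum(
            assign[nd] != assign[nd.parent_node]
            for nd in nodes
            if nd.parent_node is not None
        )
        best = min(best, changes)
    return int(best)
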
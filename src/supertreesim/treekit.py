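"""Core tree data structures and topological operations.

Trees are thin wrappers around :class:`dendropy.Tree`; all comparisons of
topology are bipartition-based and treat trees as unrooted.  Bipartitions are
represented explicitly as pairs of label sets so that they can be compared
across trees with different taxon namespaces.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "PhyloTree",
    "Bipartition",
    "QuartetTopology",
    "read_newick",
    "write_newick",
    "bipartition_set",
    "restrict",
    "induced_quartet",
    "topo_dist_matrix",
    "midpoint_root",
    "greedy_consensus",
    "topology_key",
    "same_topology",
]


class TreeError(ValueError):
    """Invalid tree input or operation."""


class NewickParseError(TreeError):
    """Malformed newick text."""


class Bipartition:
    """A split of a tree's leaf set induced by one internal edge.

    Canonical orientation: the side containing the lexicographically
    smallest label is stored first.
    """

    __slots__ = ("side1", "side2")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise TreeError("bipartition sides must be non-empty")
        if a & b:
            raise TreeError("bipartition sides must be disjoint")
        if min(a) < min(b):
            self.side1, self.side2 = a, b
        else:
            self.side1, self.side2 = b, a

    @property
    def leaf_set(self) -> frozenset:
        return self.side1 | self.side2

    def is_trivial(self) -> bool:
        return len(self.side1) < 2 or len(self.side2) < 2

    def restricted(self, subset: Iterable[str]) -> "Bipartition | None":
        """Induced bipartition on ``subset``; None if a side shrinks below 2."""
        s = frozenset(subset)
        a, b = self.side1 & s, self.side2 & s
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Two splits of the same leaf set are compatible iff some pair of
        opposite sides is disjoint."""
        return (
            not (self.side1 & other.side1)
            or not (self.side1 & other.side2)
            or not (self.side2 & other.side1)
            or not (self.side2 & other.side2)
        )

    def canonical_str(self) -> str:
        return (
            " ".join(sorted(self.side1)) + " | " + " ".join(sorted(self.side2))
        )

    def __eq__(self, other):
        return (
            isinstance(other, Bipartition)
            and self.side1 == other.side1
            and self.side2 == other.side2
        )

    def __hash__(self):
        return hash((self.side1, self.side2))

    def __repr__(self):
        return f"Bipartition({self.canonical_str()})"


class QuartetTopology:
    """A resolved four-leaf split ``ab|cd`` in canonical form.

    Canonical form: each pair sorted, pairs ordered by their smallest
    element, so every topology has a unique representation.
    """

    __slots__ = ("a", "b", "c", "d")

    def __init__(self, pair1: Sequence[str], pair2: Sequence[str]):
        p1 = tuple(sorted(pair1))
        p2 = tuple(sorted(pair2))
        if len(p1) != 2 or len(p2) != 2:
            raise TreeError("quartet pairs must each have two labels")
        if len({*p1, *p2}) != 4:
            raise TreeError("quartet labels must be distinct")
        if p1[0] > p2[0]:
            p1, p2 = p2, p1
        self.a, self.b = p1
        self.c, self.d = p2

    @property
    def labels(self) -> frozenset:
        return frozenset((self.a, self.b, self.c, self.d))

    def as_tuple(self):
        return (self.a, self.b, self.c, self.d)

    def __eq__(self, other):
        return (
            isinstance(other, QuartetTopology)
            and self.as_tuple() == other.as_tuple()
        )

    def __hash__(self):
        return hash(self.as_tuple())

    def __repr__(self):
        return f"{self.a},{self.b}|{self.c},{self.d}"


class PhyloTree:
    """Leaf-labelled phylogenetic tree (rooted or unrooted, possibly
    multifurcating) with optional branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed newick: {exc}") from exc
        return cls(tree)

    def _validate(self):
        labels = [
            lf.taxon.label if lf.taxon is not None else None
            for lf in self._tree.leaf_node_iter()
        ]
        if any(not lb for lb in labels):
            raise TreeError("empty or missing leaf label")
        if len(labels) != len(set(labels)):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaves(self) -> frozenset:
        return frozenset(
            lf.taxon.label for lf in self._tree.leaf_node_iter()
        )

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    def has_branch_lengths(self) -> bool:
        return all(
            e.length is not None
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self, *, lengths: bool = True) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not lengths,
        )
        return s.strip()

    def __repr__(self):
        return f"PhyloTree({self.n_leaves} leaves)"

    # -- unrooted adjacency view --------------------------------------

    def _unrooted_adjacency(self, weighted: bool = False):
        """Adjacency mapping of the unrooted version of the tree.

        A degree-2 root is suppressed (its two incident edges merged, with
        lengths summed when ``weighted``).  Returns ``(adj, leaf_nodes)``
        where ``adj`` maps node -> list of (neighbor, edge length) and
        ``leaf_nodes`` maps label -> node.
        """
        adj: dict = {}
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            w = (edge.length if edge.length is not None else 1.0) if weighted else 1.0
            adj.setdefault(edge.tail_node, []).append((edge.head_node, w))
            adj.setdefault(edge.head_node, []).append((edge.tail_node, w))
        root = self._tree.seed_node
        if root in adj and len(adj[root]) == 2:
            (u, wu), (v, wv) = adj.pop(root)
            merged = (wu + wv) if weighted else 1.0
            adj[u] = [(n, w) for (n, w) in adj[u] if n is not root] + [(v, merged)]
            adj[v] = [(n, w) for (n, w) in adj[v] if n is not root] + [(u, merged)]
        leaf_nodes = {
            lf.taxon.label: lf for lf in self._tree.leaf_node_iter()
        }
        return adj, leaf_nodes


# ---------------------------------------------------------------------------
# newick I/O


def read_newick(text: str) -> PhyloTree:
    """Parse a single newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, *, lengths: bool = True) -> str:
    return tree.to_newick(lengths=lengths)


def read_newick_list(text: str) -> list[PhyloTree]:
    """Parse a multi-tree file: one newick per non-empty line."""
    return [read_newick(line) for line in text.splitlines() if line.strip()]


def write_newick_list(trees: Iterable[PhyloTree], *, lengths: bool = True) -> str:
    return "\n".join(t.to_newick(lengths=lengths) for t in trees) + "\n"


# ---------------------------------------------------------------------------
# bipartitions


def bipartition_set(tree: PhyloTree) -> frozenset:
    """The set of non-trivial bipartitions, one per internal edge.

    Rooted trees are treated as their unrooted versions, so the two edges
    incident to a degree-2 root contribute a single bipartition.
    """
    all_leaves = tree.leaves
    out = set()
    for edge in tree.dendropy_tree.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node.is_leaf():
            continue
        below = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            out.add(Bipartition(below, above))
    return frozenset(out)


def topology_key(tree: PhyloTree) -> tuple:
    """Hashable unrooted-topology identifier (leaf set + bipartitions)."""
    return (tree.leaves, bipartition_set(tree))


def same_topology(t1: PhyloTree, t2: PhyloTree) -> bool:
    return topology_key(t1) == topology_key(t2)


# ---------------------------------------------------------------------------
# restriction and quartet induction


def restrict(tree: PhyloTree, subset: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``subset`` with degree-2 nodes suppressed.

    Branch lengths, when present, are summed across suppressed nodes.
    """
    subset = frozenset(subset)
    missing = subset - tree.leaves
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    if len(subset) < 3:
        raise TreeError("restriction subset must have >= 3 labels")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=subset, suppress_unifurcations=True
    )
    return PhyloTree(sub)


def _pairwise_path_lengths(tree: PhyloTree, labels: Sequence[str], weighted: bool):
    """Path lengths between the given leaves, on the unrooted tree."""
    adj, leaf_nodes = tree._unrooted_adjacency(weighted=weighted)
    missing = [lb for lb in labels if lb not in leaf_nodes]
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    targets = {leaf_nodes[lb]: i for i, lb in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n), dtype=float if weighted else np.int64)
    for i, lb in enumerate(labels):
        # single-source traversal; a tree has unique paths so this is exact
        start = leaf_nodes[lb]
        dist = {start: 0.0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, w in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for node, j in targets.items():
            D[i, j] = dist[node]
    return D


def induced_quartet(tree: PhyloTree, labels) -> QuartetTopology | None:
    """The quartet topology displayed on four leaves, or None if unresolved.

    Uses the four-point condition on topological distances: the pairing
    with the strictly smallest sum of within-pair distances is the
    displayed split; three equal sums mean the restriction is a star.
    """
    labels = sorted(labels)
    if len(labels) != 4 or len(set(labels)) != 4:
        raise TreeError("need four distinct labels")
    D = _pairwise_path_lengths(tree, labels, weighted=False)
    a, b, c, d = range(4)
    sums = [
        (D[a, b] + D[c, d], ((labels[a], labels[b]), (labels[c], labels[d]))),
        (D[a, c] + D[b, d], ((labels[a], labels[c]), (labels[b], labels[d]))),
        (D[a, d] + D[b, c], ((labels[a], labels[d]), (labels[b], labels[c]))),
    ]
    sums.sort(key=lambda sp: sp[0])
    if sums[0][0] == sums[1][0]:
        return None
    return QuartetTopology(*sums[0][1])


# ---------------------------------------------------------------------------
# distances


def topo_dist_matrix(tree: PhyloTree):
    """Pairwise leaf-to-leaf edge-count distances on the unrooted tree.

    Returns ``(labels, D)`` with labels sorted and ``D`` a symmetric
    integer matrix with zero diagonal.
    """
    labels = sorted(tree.leaves)
    if len(labels) < 2:
        raise TreeError("need >= 2 leaves")
    return labels, _pairwise_path_lengths(tree, labels, weighted=False)


def weighted_dist_matrix(tree: PhyloTree):
    """Pairwise leaf-to-leaf weighted (branch-length) distances."""
    labels = sorted(tree.leaves)
    return labels, _pairwise_path_lengths(tree, labels, weighted=True)


# ---------------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest weighted leaf-to-leaf path.

    Ties between equal-length longest paths are broken by the
    lexicographically smallest leaf pair.  Requires branch lengths; pass a
    tree with explicit unit lengths to midpoint-root by edge counts.
    """
    if not tree.has_branch_lengths():
        raise TreeError(
            "midpoint rooting requires branch lengths; assign unit lengths "
            "explicitly to root by edge counts"
        )
    work = tree.dendropy_tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) == 2:
        work.deroot()
    wrapped = PhyloTree(work)
    labels, D = weighted_dist_matrix(wrapped)
    # longest path, lexicographic tie-break on the (sorted) leaf pair
    best = None
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            key = (-D[i, j], li, labels[j])
            if best is None or key < best[0]:
                best = (key, li, labels[j])
    _, la, lb = best
    half = D[labels.index(la), labels.index(lb)] / 2.0

    # walk the path from la toward lb accumulating branch lengths
    adj, leaf_nodes = wrapped._unrooted_adjacency(weighted=True)
    start, goal = leaf_nodes[la], leaf_nodes[lb]
    parent = {start: None}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v, w in adj.get(u, ()):
            if v not in parent:
                parent[v] = (u, w)
                queue.append(v)
    path = []
    node = goal
    while parent[node] is not None:
        prev, w = parent[node]
        path.append((prev, node, w))
        node = prev
    path.reverse()  # edges from la to lb

    acc = 0.0
    eps = 1e-12
    for (u, v, w) in path:
        if acc + w >= half - eps:
            offset = half - acc
            if offset <= eps:
                work.reroot_at_node(u, update_bipartitions=False)
            elif offset >= w - eps:
                work.reroot_at_node(v, update_bipartitions=False)
            else:
                edge = _edge_between(u, v)
                if edge.head_node is v:
                    l_head, l_tail = w - offset, offset
                else:
                    l_head, l_tail = offset, w - offset
                work.reroot_at_edge(
                    edge, length1=l_tail, length2=l_head,
                    update_bipartitions=False,
                )
            break
        acc += w
    work.is_rooted = True
    return PhyloTree(work)


def _edge_between(u, v):
    if v.parent_node is u:
        return v.edge
    if u.parent_node is v:
        return u.edge
    raise TreeError("nodes are not adjacent")


# ---------------------------------------------------------------------------
# greedy consensus


def greedy_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Greedy (majority-rule extended) consensus of trees on one leaf set.

    Bipartitions are sorted by frequency (ties broken by canonical
    lexicographic form, then first appearance) and accepted when compatible
    with all previously accepted splits.  The result therefore contains
    every bipartition occurring in more than half the input trees.
    """
    if not trees:
        raise TreeError("need >= 1 trees")
    leaf_set = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaf_set:
            raise TreeError("greedy consensus requires identical leaf sets")

    counts: dict = {}
    first_seen: dict = {}
    for idx, t in enumerate(trees):
        for bip in bipartition_set(t):
            counts[bip] = counts.get(bip, 0) + 1
            first_seen.setdefault(bip, idx)
    ordered = sorted(
        counts,
        key=lambda b: (-counts[b], b.canonical_str(), first_seen[b]),
    )
    accepted: list = []
    for bip in ordered:
        if all(bip.is_compatible_with(acc) for acc in accepted):
            accepted.append(bip)
    return tree_from_bipartitions(leaf_set, accepted)


def tree_from_bipartitions(
    leaf_set: Iterable[str], bipartitions: Sequence[Bipartition]
) -> PhyloTree:
    """Build the (unrooted) tree displaying a pairwise-compatible set of
    bipartitions of ``leaf_set``."""
    leaf_set = frozenset(leaf_set)
    ref = min(leaf_set)
    # rooted-at-ref view: each split maps to the cluster not containing ref
    clusters = []
    for bip in bipartitions:
        if bip.leaf_set != leaf_set:
            raise TreeError("bipartition not on the given leaf set")
        clusters.append(bip.side2 if ref in bip.side1 else bip.side1)
    clusters = sorted(set(clusters), key=lambda c: (-len(c), sorted(c)))

    children: dict = {None: []}  # parent cluster -> list of child clusters

    def place(cluster, parent):
        for child in children.get(parent, []):
            if cluster < child:
                place(cluster, child)
                return
        sub = [c for c in children[parent] if c < cluster]
        children[parent] = [c for c in children[parent] if not c < cluster]
        children[parent].append(cluster)
        children[cluster] = sub

    for c in clusters:
        place(c, None)

    def newick_of(cluster) -> str:
        direct = children.get(cluster, [])
        covered = set().union(*direct) if direct else set()
        here = (cluster if cluster is not None else leaf_set) - covered
        parts = [newick_of(c) for c in direct] + sorted(here)
        return "(" + ",".join(parts) + ")"

    return read_newick(newick_of(None) + ";")
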
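"""Quartet encodings of source trees.

A source tree can be handed to a quartet amalgamation heuristic in three
ways: *all* induced four-taxon trees; or a random sample of them where a
quartet of topological diameter ``d`` (the largest leaf-to-leaf edge-count
distance among its four leaves) is kept with probability ``d**-3``
("geometric" rule) or ``1.5**-d`` ("exponential" rule), topped up with the
Topologically Short Quartets (TSQs) so that every internal edge keeps local
signal.  Sparse encodings are what make quartet amalgamation feasible for
larger source trees.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np

from .treekit import (
    PhyloTree,
    QuartetTopology,
    TreeError,
    topo_dist_matrix,
)

__all__ = [
    "QuartetSet",
    "quartet_diameter",
    "all_quartets",
    "tsq_trees",
    "sampled_encoding",
    "encode_tree",
    "encode_profile",
    "write_quartet_file",
    "read_quartet_file",
]

logger = logging.getLogger(__name__)

SAMPLING_RULES = ("geo", "exp")
STRATEGIES = ("all", "geo+tsq", "exp+tsq")


class QuartetSet:
    """Weighted multiset of resolved quartet topologies over a taxon universe.

    Conflicting topologies on the same four labels may coexist (they arise
    from different source trees); weights count contributing source trees.
    """

    def __init__(self, taxa: Iterable[str] = (), weights: Mapping[QuartetTopology, int] | None = None):
        self.taxa = set(taxa)
        self.weights: dict[QuartetTopology, int] = {}
        if weights:
            for q, w in weights.items():
                self.add(q, w)

    def add(self, q: QuartetTopology, weight: int = 1) -> None:
        if weight < 1:
            raise ValueError("quartet weight must be >= 1")
        self.weights[q] = self.weights.get(q, 0) + weight
        self.taxa.update(q.labels)

    def update(self, other: "QuartetSet") -> None:
        for q, w in other.weights.items():
            self.add(q, w)
        self.taxa.update(other.taxa)

    def topologies(self) -> set[QuartetTopology]:
        return set(self.weights)

    def total_weight(self) -> int:
        return sum(self.weights.values())

    def conflicts(self) -> int:
        """Number of four-label subsets carrying more than one topology."""
        seen: dict[frozenset, int] = {}
        for q in self.weights:
            seen[q.labels] = seen.get(q.labels, 0) + 1
        return sum(1 for v in seen.values() if v > 1)

    def deduplicated(self) -> "QuartetSet":
        """Plain-set view: every weight collapsed to 1."""
        return QuartetSet(self.taxa, {q: 1 for q in self.weights})

    def __len__(self):
        return len(self.weights)

    def __contains__(self, q: QuartetTopology):
        return q in self.weights

    def __iter__(self):
        return iter(self.weights)

    def __repr__(self):
        return f"QuartetSet({len(self)} topologies, |taxa|={len(self.taxa)})"


# ---------------------------------------------------------------------------
# vectorized per-tree machinery


def _quartet_arrays(t: PhyloTree):
    """All 4-subsets of leaves as index arrays plus topology/diameter info.

    Returns ``(labels, quartets, pairing, diam)`` where ``quartets`` is an
    (m, 4) array of sorted leaf indices, ``pairing`` in {0,1,2,-1} selects
    which of ab|cd, ac|bd, ad|bc is displayed (-1: unresolved), and
    ``diam`` is the topological diameter of each 4-subset.
    """
    labels, D = topo_dist_matrix(t)
    n = len(labels)
    if n < 4:
        raise TreeError("need >= 4 leaves")
    quartets = np.array(
        list(itertools.combinations(range(n), 4)), dtype=np.int64
    )
    a, b, c, d = (quartets[:, k] for k in range(4))
    sums = np.stack(
        [D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]], axis=1
    )
    order = np.sort(sums, axis=1)
    resolved = order[:, 0] < order[:, 1]
    pairing = np.where(resolved, np.argmin(sums, axis=1), -1)
    pairs = np.stack(
        [D[a, b], D[a, c], D[a, d], D[b, c], D[b, d], D[c, d]], axis=1
    )
    diam = pairs.max(axis=1)
    return labels, quartets, pairing, diam


_PAIRINGS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


def _topology(labels, quartet_row, pairing) -> QuartetTopology:
    i, j, k, l = _PAIRINGS[pairing]
    q = quartet_row
    return QuartetTopology(
        (labels[q[i]], labels[q[j]]), (labels[q[k]], labels[q[l]])
    )


def quartet_diameter(t: PhyloTree, q: Iterable[str]) -> int:
    """Topological diameter of four leaves: the maximum edge-count
    distance among the six leaf pairs."""
    q = sorted(set(q))
    if len(q) != 4:
        raise TreeError("need four distinct labels")
    missing = set(q) - t.leaves
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    from .treekit import _pairwise_path_lengths

    D = _pairwise_path_lengths(t, q, weighted=False)
    return int(D.max())


def all_quartets(t: PhyloTree) -> QuartetSet:
    """Every resolved induced four-taxon tree, weight 1 each.

    For a binary tree this is exactly C(n, 4) topologies; unresolved
    4-subsets of multifurcating trees are omitted (count logged).
    """
    labels, quartets, pairing, _ = _quartet_arrays(t)
    qs = QuartetSet(labels)
    omitted = 0
    for row, p in zip(quartets, pairing):
        if p < 0:
            omitted += 1
            continue
        qs.add(_topology(labels, row, p))
    if omitted:
        logger.info("all_quartets: omitted %d unresolved 4-subsets", omitted)
    return qs


# ---------------------------------------------------------------------------
# topologically short quartets


def tsq_trees(t: PhyloTree) -> QuartetSet:
    """Topologically Short Quartets of every internal edge.

    For each internal edge, each of the subtrees hanging off its two
    endpoints contributes its topologically nearest leaf (all of them on
    ties, distance = edge count to the nearer endpoint); the TSQs of the
    edge take one leaf per subtree, pairing same-side subtrees.  Around a
    polytomy every pair of same-side subtrees is used.
    """
    from collections import deque

    adj, leaf_nodes = t._unrooted_adjacency(weighted=False)
    node_label = {v: k for k, v in leaf_nodes.items()}

    def nearest_leaves(start, banned):
        """Closest leaves in the subtree entered via ``start`` (never
        crossing back through ``banned``), all tied ones."""
        best: list[str] = []
        best_d = None
        seen = {banned, start}
        queue = deque([(start, 0)])
        while queue:
            u, dist = queue.popleft()
            if u in node_label:
                if best_d is None or dist < best_d:
                    best, best_d = [node_label[u]], dist
                elif dist == best_d:
                    best.append(node_label[u])
                continue
            if best_d is not None and dist >= best_d:
                continue
            for v, _ in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    queue.append((v, dist + 1))
        return best

    qs = QuartetSet(t.leaves)
    internal_edges = [
        (u, v)
        for u in adj
        for v, _ in adj[u]
        if u not in node_label and v not in node_label and id(u) < id(v)
    ]
    for u, v in internal_edges:
        u_subs = [nearest_leaves(w, u) for w, _ in adj[u] if w is not v]
        v_subs = [nearest_leaves(w, v) for w, _ in adj[v] if w is not u]
        if len(u_subs) > 2 or len(v_subs) > 2:
            logger.info("tsq_trees: polytomy adjacent to an internal edge")
        for s1, s2 in itertools.combinations(u_subs, 2):
            for s3, s4 in itertools.combinations(v_subs, 2):
                for x1, x2, x3, x4 in itertools.product(s1, s2, s3, s4):
                    if len({x1, x2, x3, x4}) == 4:
                        qs.add(QuartetTopology((x1, x2), (x3, x4)))
    # within one tree's encoding every quartet carries weight 1
    return qs.deduplicated()


# ---------------------------------------------------------------------------
# sampled encodings


def inclusion_probability(rule: str, d):
    """Per-quartet inclusion probability for diameter ``d``:
    ``d**-3`` (geo) or ``1.5**-d`` (exp)."""
    if rule == "geo":
        return np.asarray(d, dtype=float) ** -3.0
    if rule == "exp":
        return 1.5 ** -np.asarray(d, dtype=float)
    raise ValueError(f"unknown sampling rule {rule!r}; choose from {SAMPLING_RULES}")


def sampled_encoding(t: PhyloTree, rule: str, seed: int) -> QuartetSet:
    """Diameter-weighted Bernoulli sample of the induced quartets, plus the
    TSQ trees.  Deterministic for a given seed."""
    labels, quartets, pairing, diam = _quartet_arrays(t)
    prob = inclusion_probability(rule, diam)
    rng = np.random.default_rng(seed)
    keep = (rng.random(len(quartets)) < prob) & (pairing >= 0)
    qs = tsq_trees(t)
    for row, p in zip(quartets[keep], pairing[keep]):
        topo = _topology(labels, row, p)
        if topo not in qs:
            qs.add(topo)
    return qs


def encode_tree(t: PhyloTree, strategy: str, seed: int = 0) -> QuartetSet:
    """Encode one source tree under a named strategy."""
    if strategy == "all":
        return all_quartets(t)
    if strategy == "geo+tsq":
        return sampled_encoding(t, "geo", seed)
    if strategy == "exp+tsq":
        return sampled_encoding(t, "exp", seed)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def encode_profile(profile, strategy: str, seed: int = 0, *, deduplicate: bool = False) -> QuartetSet:
    """Combine per-source-tree encodings into one weighted quartet
    collection (weight = number of contributing source trees).

    ``profile`` is a :class:`~supertreesim.profile_sim.SourceTreeProfile`
    or any iterable of trees.  With ``deduplicate`` the combined set keeps
    plain-set semantics (every weight 1).
    """
    trees = list(getattr(profile, "trees", profile))
    if not trees:
        raise ValueError("empty profile")
    ss = np.random.SeedSequence(seed)
    combined = QuartetSet()
    for t, child in zip(trees, ss.spawn(len(trees))):
        t = getattr(t, "tree", t)  # accept SourceTree records
        combined.taxa.update(t.leaves)
        if t.n_leaves < 4:
            continue
        combined.update(
            encode_tree(t, strategy, int(child.generate_state(1)[0] % 2**31))
        )
    if deduplicate:
        combined = combined.deduplicated()
    return combined


# ---------------------------------------------------------------------------
# quartet file format: "a,b|c,d<TAB>weight", weight omitted means 1


def write_quartet_file(qs: QuartetSet) -> str:
    """Canonical byte-stable text rendering (sorted lines)."""
    lines = [f"{q.a},{q.b}|{q.c},{q.d}\t{w}" for q, w in qs.weights.items()]
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


def read_quartet_file(text: str) -> QuartetSet:
    qs = QuartetSet()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) > 2:
            raise ValueError(f"line {lineno}: too many fields")
        weight = 1
        if len(parts) == 2:
            weight = int(parts[1])
        try:
            p1, p2 = parts[0].split("|")
            a, b = p1.split(",")
            c, d = p2.split(",")
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed quartet record") from exc
        qs.add(QuartetTopology((a, b), (c, d)), weight)
    return qs
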
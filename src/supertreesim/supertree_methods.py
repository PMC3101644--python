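"""Supertree construction: MRP/gMRP and max-cut style quartet amalgamation.

Two pathways are provided.

*MRP* (matrix representation with parsimony): every internal edge of every
source tree becomes one partial binary character (0/1 by side, ``?`` for
taxa absent from that tree); the matrix is analyzed with a parsimony
ratchet (random-addition starting trees, nearest-neighbor-interchange hill
climbing, alternating reweighted and original matrices) and the greedy
consensus of all best-found trees is the gMRP supertree.

*Quartet amalgamation*: a weighted quartet collection is assembled into a
tree by recursive graph partitioning.  Each quartet ``ab|cd`` deposits
"good" edges {a,b},{c,d} (which a cut should not separate) and "bad" edges
across the pairs (which a cut should separate); a randomized hill-climbing
search seeks a cut maximizing cut bad weight minus ``lambda_good`` times
cut good weight, and the method recurses on each side.  This follows the
published *contract* of quartet max-cut heuristics (polynomial time, no
optimality guarantee for Maximum Quartet Consistency); the internal cut
machinery is this package's own ("QMC-style", not a clone of any binary).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np

from .treekit import (
    PhyloTree,
    TreeError,
    bipartition_set,
    greedy_consensus,
    read_newick,
)
from .quartet_enc import QuartetSet

__all__ = [
    "CharacterMatrix",
    "mrp_encode",
    "fitch_length",
    "ratchet_search",
    "RatchetResult",
    "gmrp",
    "maxcut_amalgamate",
    "satisfied_quartet_weight",
]

logger = logging.getLogger(__name__)

UNKNOWN = 2  # matrix code for '?'


# ---------------------------------------------------------------------------
# MRP encoding


class CharacterMatrix:
    """Taxa x partial binary characters over {0, 1, ?}.

    ``data`` holds 0/1/2 (2 = ``?``); ``provenance[j]`` records the source
    tree index and bipartition behind column ``j``.
    """

    def __init__(self, taxa: Sequence[str], data: np.ndarray, provenance=None):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxon list")
        self.provenance = provenance or [None] * self.data.shape[1]
        for j in range(self.n_columns):
            col = self.data[:, j]
            if not ((col == 0).any() and (col == 1).any()):
                raise ValueError(f"column {j} lacks a 0 or a 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def uncovered_taxa(self) -> list[str]:
        """Taxa whose row is entirely '?' (present in no encoded tree)."""
        return [
            t
            for i, t in enumerate(self.taxa)
            if self.n_columns == 0 or (self.data[i] == UNKNOWN).all()
        ]

    def to_phylip(self) -> str:
        rows = [f" {self.n_taxa} {self.n_columns}"]
        sym = np.array(["0", "1", "?"])
        for i, t in enumerate(self.taxa):
            rows.append(f"{t}  " + "".join(sym[self.data[i]]))
        return "\n".join(rows) + "\n"

    def to_nexus(self) -> str:
        sym = np.array(["0", "1", "?"])
        body = "\n".join(
            f"    {t}  " + "".join(sym[self.data[i]])
            for i, t in enumerate(self.taxa)
        )
        return (
            "#NEXUS\nbegin data;\n"
            f"  dimensions ntax={self.n_taxa} nchar={self.n_columns};\n"
            "  format datatype=standard symbols=\"01\" missing=?;\n"
            "  matrix\n" + body + "\n  ;\nend;\n"
        )


def mrp_encode(profile) -> CharacterMatrix:
    """Encode a source-tree profile as partial binary characters.

    One column per internal edge of each source tree: taxa on the side
    containing the tree's lexicographically smallest leaf get 0, the other
    side 1, taxa absent from the tree '?'.  Source trees with fewer than 4
    leaves contribute no columns (logged).
    """
    trees = list(getattr(profile, "trees", profile))
    if not trees:
        raise ValueError("empty profile")
    records = [getattr(t, "tree", t) for t in trees]
    universe = sorted(set().union(*(t.leaves for t in records)))
    index = {t: i for i, t in enumerate(universe)}
    columns, provenance = [], []
    for ti, tree in enumerate(records):
        if tree.n_leaves < 4:
            logger.info("mrp_encode: source tree %d has < 4 leaves, skipped", ti)
            continue
        anchor = min(tree.leaves)
        for bip in sorted(bipartition_set(tree), key=lambda b: b.canonical_str()):
            col = np.full(len(universe), UNKNOWN, dtype=np.int8)
            zero_side = bip.side1 if anchor in bip.side1 else bip.side2
            one_side = bip.side2 if anchor in bip.side1 else bip.side1
            for t in zero_side:
                col[index[t]] = 0
            for t in one_side:
                col[index[t]] = 1
            columns.append(col)
            provenance.append((ti, bip))
    if columns:
        data = np.stack(columns, axis=1)
    else:
        data = np.zeros((len(universe), 0), dtype=np.int8)
    matrix = CharacterMatrix(universe, data, provenance)
    uncovered = matrix.uncovered_taxa()
    if uncovered:
        logger.warning("taxa in no source tree column: %s", uncovered)
    return matrix


# ---------------------------------------------------------------------------
# Fitch parsimony on a compact search representation
#
# Search trees are rooted on a pendant edge: the root has two children and
# every other internal node is binary; Fitch length is rooting-invariant.

_STATE_BITS = np.array([1, 2, 3], dtype=np.uint8)  # 0 -> {0}, 1 -> {1}, ? -> {0,1}


class _SearchTree:
    """Mutable rooted-binary scaffold over taxon indices 0..n-1."""

    __slots__ = ("n", "kids", "parent", "root")

    def __init__(self, n: int):
        self.n = n
        size = 2 * n - 1
        self.kids = np.full((size, 2), -1, dtype=np.int64)
        self.parent = np.full(size, -1, dtype=np.int64)
        self.root = -1

    def postorder_internal(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if self.kids[node, 0] >= 0:
                order.append(node)
                stack.extend(self.kids[node])
        order.reverse()
        return order

    def copy(self) -> "_SearchTree":
        other = _SearchTree(self.n)
        other.kids = self.kids.copy()
        other.parent = self.parent.copy()
        other.root = self.root
        return other

    def to_newick(self, labels: Sequence[str]) -> str:
        def rec(node: int) -> str:
            if self.kids[node, 0] < 0:
                return labels[node]
            return "(" + ",".join(rec(int(c)) for c in self.kids[node]) + ")"

        return rec(self.root) + ";"

    def to_tree(self, labels: Sequence[str]) -> PhyloTree:
        return read_newick(self.to_newick(labels))

    def topology_id(self) -> frozenset:
        """Unrooted topology key: one bitmask per non-trivial bipartition,
        normalized to the side not containing taxon 0."""
        masks: dict[int, int] = {}
        full = (1 << self.n) - 1
        for node in self.postorder_internal():
            c0, c1 = (int(c) for c in self.kids[node])
            m0 = masks.get(c0, 1 << c0)
            m1 = masks.get(c1, 1 << c1)
            masks[node] = m0 | m1
        out = []
        for node, mask in masks.items():
            if node == self.root:
                continue
            side = mask if not (mask & 1) else full ^ mask
            if bin(side).count("1") >= 2 and bin(full ^ side).count("1") >= 2:
                out.append(side)
        return frozenset(out)


def _fitch_score(tree: _SearchTree, leaf_bits: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Fitch length over all columns at once."""
    size = tree.kids.shape[0]
    ncols = leaf_bits.shape[1]
    bits = np.zeros((size, ncols), dtype=np.uint8)
    bits[: tree.n] = leaf_bits
    changes = np.zeros(ncols, dtype=np.int64)
    for node in tree.postorder_internal():
        c0, c1 = tree.kids[node]
        m0, m1 = bits[c0], bits[c1]
        inter = m0 & m1
        empty = inter == 0
        changes += empty
        bits[node] = np.where(empty, m0 | m1, inter)
    return float(changes @ weights)


def _leaf_bits(matrix: CharacterMatrix) -> np.ndarray:
    return _STATE_BITS[matrix.data]


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Fitch small-parsimony length of a binary tree on a matrix.

    '?' entries carry state set {0, 1} (free assignment); taxa of the tree
    absent from the matrix are treated as all-'?'.
    """
    extra = set(matrix.taxa) - tree.leaves
    if extra:
        raise TreeError(f"matrix taxa not in tree: {sorted(extra)}")
    labels = sorted(tree.leaves)
    st = _search_tree_from(tree, labels)
    n = len(labels)
    bits = np.full((n, matrix.n_columns), 3, dtype=np.uint8)
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    lb = _leaf_bits(matrix)
    for i, lab in enumerate(labels):
        if lab in row_of:
            bits[i] = lb[row_of[lab]]
    return int(_fitch_score(st, bits, np.ones(matrix.n_columns)))


def _search_tree_from(tree: PhyloTree, labels: Sequence[str]) -> _SearchTree:
    """Convert a binary (possibly basal-trifurcating) tree."""
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    st = _SearchTree(n)
    counter = itertools.count(n)

    def link(me: int, child: int) -> None:
        slot = 0 if st.kids[me, 0] < 0 else 1
        st.kids[me, slot] = child
        st.parent[child] = me

    def build(node) -> int:
        children = node.child_nodes()
        if not children:
            return idx[node.taxon.label]
        if len(children) == 2:
            me = next(counter)
            for ch in children:
                link(me, build(ch))
            return me
        if len(children) == 3:
            # unrooted basal trifurcation: root on the first child's edge
            me, inner = next(counter), next(counter)
            link(me, build(children[0]))
            link(inner, build(children[1]))
            link(inner, build(children[2]))
            link(me, inner)
            return me
        raise TreeError("fitch_length requires a binary tree")

    st.root = build(tree.dendropy_tree.seed_node)
    return st


# ---------------------------------------------------------------------------
# ratchet search


def _nni_moves(st: _SearchTree):
    """NNI rearrangements, one per (internal edge, swap choice):
    quadruples (parent, child, sibling_slot, child_slot).

    The edge between the root's two children counts as one internal edge
    when both are internal nodes (enumerated from the first child only)."""
    moves = []
    for c in range(st.n, 2 * st.n - 1):
        p = st.parent[c]
        if p < 0 or st.kids[c, 0] < 0:
            continue
        c_slot = 0 if st.kids[p, 0] == c else 1
        if p == st.root:
            sibling = st.kids[p, 1 - c_slot]
            if c_slot != 0 or st.kids[sibling, 0] < 0:
                continue
        for k_slot in (0, 1):
            moves.append((p, c, 1 - c_slot, k_slot))
    return moves


def _apply_nni(st: _SearchTree, move) -> None:
    p, c, w_slot, k_slot = move
    w = st.kids[p, w_slot]
    x = st.kids[c, k_slot]
    st.kids[p, w_slot] = x
    st.kids[c, k_slot] = w
    st.parent[x] = p
    st.parent[w] = c


def _hill_climb(st, leaf_bits, weights, *, max_rounds: int = 200) -> float:
    score = _fitch_score(st, leaf_bits, weights)
    for _ in range(max_rounds):
        best_gain, best_move = 0.0, None
        for move in _nni_moves(st):
            _apply_nni(st, move)
            s = _fitch_score(st, leaf_bits, weights)
            _apply_nni(st, move)  # NNI is an involution
            if score - s > best_gain:
                best_gain, best_move = score - s, move
        if best_move is None:
            break
        _apply_nni(st, best_move)
        score -= best_gain
    return score


def _parsimony_reinsertion_pass(st: _SearchTree, leaf_bits, weights, score: float) -> float:
    """Prune each subtree and regraft it on its best edge by Fitch length
    (a subtree-prune-regraft sweep; much stronger than NNI alone on
    matrices rich in missing data)."""
    n = st.n
    for v in range(2 * n - 1):
        joint = int(st.parent[v])
        if joint < 0 or joint == st.root or v == st.root:
            continue
        inside = _subtree_nodes(st, v)
        _remove_leaf(st, v, joint)
        best_s, best_target = np.inf, None
        for target in range(2 * n - 1):
            if target in inside or target in (joint, st.root):
                continue
            if st.parent[target] < 0 and target != st.root:
                continue
            _insert_leaf(st, v, target, joint)
            s = _fitch_score(st, leaf_bits, weights)
            _remove_leaf(st, v, joint)
            if s < best_s:
                best_s, best_target = s, target
        _insert_leaf(st, v, best_target, joint)
        score = min(score, best_s)
    return score


def _full_climb(st: _SearchTree, leaf_bits, weights, *, max_cycles: int = 3) -> float:
    """Alternate NNI climbing and reinsertion sweeps until neither helps."""
    score = _hill_climb(st, leaf_bits, weights)
    for _ in range(max_cycles):
        before = score
        score = _parsimony_reinsertion_pass(st, leaf_bits, weights, score)
        score = _hill_climb(st, leaf_bits, weights)
        if score >= before - 1e-9:
            break
    return score


def _random_addition_tree(
    n: int, leaf_bits, weights, rng, *, edge_sample: int | None = None
) -> _SearchTree:
    """Greedy random-addition starting tree: taxa in random order, each
    placed on the best of the current edges (optionally a sample)."""
    order = [int(x) for x in rng.permutation(n)]
    st = _SearchTree(n)
    next_internal = n
    a, b, c = order[:3]
    inner, root = next_internal, next_internal + 1
    next_internal += 2
    st.kids[inner] = (b, c)
    st.parent[b] = st.parent[c] = inner
    st.kids[root] = (a, inner)
    st.parent[a] = st.parent[inner] = root
    st.root = root

    for leaf in order[3:]:
        attached = [x for x in range(2 * n - 1) if st.parent[x] >= 0]
        if edge_sample is not None and len(attached) > edge_sample:
            attached = [
                attached[i]
                for i in rng.choice(len(attached), size=edge_sample, replace=False)
            ]
        joint = next_internal
        best = None
        for target in attached:
            _insert_leaf(st, leaf, target, joint)
            s = _fitch_score(st, leaf_bits, weights)
            _remove_leaf(st, leaf, joint)
            if best is None or s < best[0]:
                best = (s, target)
        _insert_leaf(st, leaf, best[1], joint)
        next_internal += 1
    return st


def _insert_leaf(st: _SearchTree, leaf: int, target: int, joint: int) -> None:
    """Attach ``leaf`` on the edge above ``target`` via new node ``joint``."""
    p = st.parent[target]
    slot = 0 if st.kids[p, 0] == target else 1
    st.kids[joint] = (target, leaf)
    st.parent[target] = st.parent[leaf] = joint
    st.kids[p, slot] = joint
    st.parent[joint] = p


def _remove_leaf(st: _SearchTree, leaf: int, joint: int) -> None:
    p = st.parent[joint]
    target = st.kids[joint, 0] if st.kids[joint, 1] == leaf else st.kids[joint, 1]
    slot = 0 if st.kids[p, 0] == joint else 1
    st.kids[p, slot] = target
    st.parent[target] = p
    st.parent[leaf] = -1
    st.kids[joint] = (-1, -1)
    st.parent[joint] = -1


@dataclasses.dataclass
class RatchetResult:
    """Best-found trees (all tied at ``score``) of a ratchet run."""

    trees: list
    score: float
    capped: bool = False


def ratchet_search(
    matrix: CharacterMatrix,
    iterations: int = 25,
    perturbation: float = 0.25,
    starts: int = 5,
    seed: int = 0,
    *,
    max_trees: int = 50,
) -> RatchetResult:
    """Parsimony ratchet over partial binary characters.

    Per start: a random-addition tree is NNI hill-climbed to a local
    optimum; each ratchet iteration upweights a random ``perturbation``
    fraction of columns x2, climbs, restores the original weights and
    climbs again, keeping the best.  Returns all distinct topologies at
    the best score found (capped at ``max_trees``, logged when hit).
    """
    n = matrix.n_taxa
    if n < 4:
        raise ValueError("need >= 4 taxa")
    labels = matrix.taxa
    if matrix.n_columns == 0:
        star = read_newick("(" + ",".join(sorted(labels)) + ");")
        return RatchetResult([star], 0.0)
    leaf_bits = _leaf_bits(matrix)
    weights = np.ones(matrix.n_columns)
    rng = np.random.default_rng(seed)

    best_score = np.inf
    best: dict = {}
    capped = False

    def offer(st: _SearchTree, score: float):
        nonlocal best_score, best, capped
        if score < best_score - 1e-9:
            best_score = score
            best = {}
        if abs(score - best_score) <= 1e-9:
            key = st.topology_id()
            if key not in best:
                if len(best) < max_trees:
                    best[key] = st.copy()
                else:
                    capped = True

    for _start in range(starts):
        st = _random_addition_tree(n, leaf_bits, weights, rng)
        score = _full_climb(st, leaf_bits, weights)
        offer(st, score)
        for _it in range(iterations):
            w2 = weights.copy()
            w2[rng.random(matrix.n_columns) < perturbation] *= 2.0
            work = st.copy()
            _hill_climb(work, leaf_bits, w2)
            s = _full_climb(work, leaf_bits, weights)
            offer(work, s)
            if s <= score:
                st, score = work, s
    if capped:
        logger.info("ratchet: best-tree set capped at %d", max_trees)
    return RatchetResult(
        [st.to_tree(labels) for st in best.values()], float(best_score), capped
    )


def gmrp(
    profile,
    iterations: int = 25,
    perturbation: float = 0.25,
    starts: int = 5,
    seed: int = 0,
    *,
    max_trees: int = 50,
) -> PhyloTree:
    """The gMRP supertree: greedy consensus of all best-score trees found
    by the parsimony ratchet on the MRP encoding of the profile."""
    matrix = mrp_encode(profile)
    result = ratchet_search(
        matrix, iterations, perturbation, starts, seed, max_trees=max_trees
    )
    return greedy_consensus(result.trees)


# ---------------------------------------------------------------------------
# max-cut style quartet amalgamation


def satisfied_quartet_weight(tree: PhyloTree, quartets: QuartetSet) -> int:
    """Total weight of quartets displayed by the tree."""
    from .treekit import induced_quartet

    total = 0
    for q, w in quartets.weights.items():
        if q.labels <= tree.leaves and induced_quartet(tree, q.labels) == q:
            total += w
    return total


def maxcut_amalgamate(
    quartets: QuartetSet,
    taxa,
    *,
    lambda_good: float = 2.0,
    restarts: int = 8,
    refine_kicks: int = 6,
    spr: bool = True,
    seed: int = 0,
) -> PhyloTree:
    """Assemble a supertree from weighted quartets by recursive partitioning.

    At each level a bipartition of the current taxa is sought by seeded
    randomized hill climbing (single-taxon flips, restarts, plus a warm
    start from a relaxed good/bad edge-graph max cut).  A cut is scored
    per quartet: a quartet split 2-2 with both pairs intact earns its
    weight (its topology is realized by the cut); a quartet whose pair is
    broken by the cut loses ``lambda_good`` times its weight (it becomes
    undisplayable); 3-1 and 0-4 splits are neutral (deferred).  The method
    then recurses on each side: quartets with exactly three taxa on one
    side keep their signal there with the off-side taxon replaced by a
    representative of the rest of the tree, an intact pair straddling the
    cut persists as a two-taxon cohesion constraint, and incoherently
    straddling quartets are dropped (counted and logged).  Output leaf set
    always equals ``taxa``; with fewer than 4 taxa (or no quartets) a star
    is returned.
    """
    taxa = sorted(taxa)
    stray = set(quartets.taxa) - set(taxa)
    if stray:
        raise TreeError(f"quartet taxa outside the given taxon set: {sorted(stray)}")
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa")
    index = {t: i for i, t in enumerate(taxa)}
    rows = np.array(
        [
            [index[q.a], index[q.b], index[q.c], index[q.d]]
            for q in quartets.weights
        ],
        dtype=np.int64,
    ).reshape(-1, 4)
    wts = np.array(list(quartets.weights.values()), dtype=float)
    if len(rows) == 0:
        logger.info("maxcut: empty quartet set, returning a star tree")
        star = read_newick("(" + ",".join(taxa) + ");")
        star.dropped_quartets = 0
        return star
    rng = np.random.default_rng(seed)
    dropped = [0]

    members = np.arange(len(taxa))
    side = _cut_members(members, rows, wts, lambda_good, restarts, rng)
    left, right = members[side], members[~side]
    sub_l = _solve_rooted(
        left, *_project(rows, wts, left, dropped), lambda_good, restarts, rng, dropped, taxa
    )
    sub_r = _solve_rooted(
        right, *_project(rows, wts, right, dropped), lambda_good, restarts, rng, dropped, taxa
    )
    if dropped[0]:
        logger.info("maxcut: dropped %d incoherently straddling quartets", dropped[0])
    tree = read_newick(f"({sub_l},{sub_r});")
    if len(taxa) >= 4 and len(rows):
        # polish against the MQC objective from two starts: the
        # divide-and-conquer tree and a quartet-separation NJ tree
        candidates = [_search_tree_from(tree, taxa)]
        try:
            candidates.append(
                _search_tree_from(_quartet_separation_nj(rows, wts, taxa), taxa)
            )
        except Exception:  # NJ start is a best-effort accelerator only
            logger.exception("maxcut: NJ warm start failed; continuing")
        scored = []
        for st in candidates:
            s = _mqc_nni_climb(st, rows, wts, _satisfied_weight_rows(st, rows, wts))
            scored.append((s, st))
        st = max(scored, key=lambda p: p[0])[1]
        _mqc_refine(st, rows, wts, rng, kicks=refine_kicks, spr=spr)
        tree = st.to_tree(taxa)
    tree.dropped_quartets = dropped[0]
    return tree


REP = -1  # placeholder index for "the rest of the tree" in deferred quartets


def _project(rows, wts, side_members, dropped):
    """Quartets available inside one side: fully-contained rows unchanged;
    rows with exactly 3 members inside keep them with the outside taxon
    (or an existing representative) mapped to REP; rows whose two inside
    members form one of the quartet's pairs persist as a two-taxon
    cohesion constraint (both off-side slots mapped to REP).  Straddling
    quartets whose inside members span both pairs are dropped (counted).

    REP slots are normalized to the tail positions: a single REP sits at
    slot 3, a double REP at slots 2 and 3 (pairs swapped as needed)."""
    if not len(rows):
        return rows, wts
    inside = np.isin(rows, side_members)
    cnt = inside.sum(axis=1)
    keep4 = cnt == 4
    keep3 = cnt == 3
    pair_in = (inside[:, 0] & inside[:, 1]) | (inside[:, 2] & inside[:, 3])
    keep2 = (cnt == 2) & pair_in
    dropped[0] += int(((cnt == 2) & ~pair_in & (rows >= 0).all(axis=1)).sum())

    r3 = rows[keep3].copy()
    r3[~inside[keep3]] = REP
    # move the REP-containing pair last, REP to slot 3
    swap_pair = (r3[:, 0] == REP) | (r3[:, 1] == REP)
    r3[swap_pair] = r3[swap_pair][:, [2, 3, 0, 1]]
    swap_in_pair = r3[:, 2] == REP
    r3[swap_in_pair] = r3[swap_in_pair][:, [0, 1, 3, 2]]

    r2 = rows[keep2].copy()
    r2[~inside[keep2]] = REP
    swap_pair = r2[:, 0] == REP
    r2[swap_pair] = r2[swap_pair][:, [2, 3, 0, 1]]

    out_rows = np.concatenate([rows[keep4], r3, r2])
    out_wts = np.concatenate([wts[keep4], wts[keep3], wts[keep2]])
    return out_rows, out_wts


def _localize(members, rows):
    """Map global taxon ids to 0..n-1 and REP to the sentinel index n."""
    n = len(members)
    lookup = {int(g): i for i, g in enumerate(members)}
    lookup[REP] = n
    out = np.empty_like(rows)
    for g, i in lookup.items():
        out[rows == g] = i
    return out


def _qc_score(lrows, wts, lam, sval, idx):
    """Quartet-consistency score of a cut on the selected rows.

    ``sval`` maps local vertex -> side (0/1), sentinel -> 2 (REP).
    Consistent 2-2 splits score +w, pair-breaking splits -lam*w,
    deferred (3-1, 0-4) splits 0.
    """
    r = lrows[idx]
    w = wts[idx]
    va, vb, vc, vd = sval[r[:, 0]], sval[r[:, 1]], sval[r[:, 2]], sval[r[:, 3]]
    two_rep = vc == 2
    one_rep = (vd == 2) & ~two_rep
    full = vd != 2
    p1_split = va != vb
    cons_full = full & ~p1_split & (vc == vd) & (va != vc)
    wrong_full = full & p1_split & (vc != vd) & ((va + vb + vc + vd) == 2)
    cons_rep = one_rep & ~p1_split & (vc != va)
    wrong_rep = (one_rep | two_rep) & p1_split
    cons = cons_full | cons_rep
    wrong = wrong_full | wrong_rep
    return float(w @ cons) - lam * float(w @ wrong)


def _cut_members(members, rows, wts, lam, restarts, rng) -> np.ndarray:
    n = len(members)
    lrows = _localize(members, rows) if len(rows) else rows
    side = _best_cut_quartets(n, lrows, wts, lam, rng, restarts)
    if side is None or side.all() or not side.any():
        logger.info("maxcut: degenerate cut, falling back to a balanced split")
        side = np.zeros(n, dtype=bool)
        side[rng.permutation(n)[: max(1, n // 2)]] = True
    return side


def _best_cut_quartets(n, lrows, wts, lam, rng, restarts):
    """Hill-climbing search for the best quartet-consistency cut."""
    if not len(lrows):
        return None
    sval = np.empty(n + 1, dtype=np.int8)
    sval[n] = 2
    rows_of = [np.nonzero((lrows == v).any(axis=1))[0] for v in range(n)]
    everything = np.arange(len(lrows))

    starts: list = [None] * max(1, restarts)
    warm = _best_cut(_graph_weights_local(n, lrows, wts, lam), rng, 4)
    if warm is not None and warm.any() and not warm.all():
        starts[0] = warm

    best_val, best_side = -np.inf, None
    for st in starts:
        sbool = st.copy() if st is not None else rng.random(n) < 0.5
        if sbool.all() or not sbool.any():
            sbool[int(rng.integers(n))] ^= True
        sval[:n] = sbool
        improved = True
        while improved:
            improved = False
            for v in rng.permutation(n):
                v = int(v)
                count = int(sbool.sum())
                if (sbool[v] and count == 1) or (not sbool[v] and count == n - 1):
                    continue  # flip would empty a side
                idx = rows_of[v]
                before = _qc_score(lrows, wts, lam, sval, idx)
                sbool[v] = not sbool[v]
                sval[v] = sbool[v]
                after = _qc_score(lrows, wts, lam, sval, idx)
                if after > before + 1e-12:
                    improved = True
                else:
                    sbool[v] = not sbool[v]
                    sval[v] = sbool[v]
        val = _qc_score(lrows, wts, lam, sval, everything)
        if val > best_val:
            best_val, best_side = val, sbool.copy()
    return best_side


def _solve_rooted(members, rows, wts, lam, restarts, rng, dropped, taxa) -> str:
    """Rooted resolution of one side; the returned subtree's root is its
    attachment point to the rest of the tree (signalled by REP)."""
    if len(members) == 1:
        return taxa[int(members[0])]
    if len(members) == 2:
        return "(" + ",".join(taxa[int(i)] for i in members) + ")"
    side = _cut_members(members, rows, wts, lam, restarts, rng)
    left, right = members[side], members[~side]
    sub_l = _solve_rooted(
        left, *_project(rows, wts, left, dropped), lam, restarts, rng, dropped, taxa
    )
    sub_r = _solve_rooted(
        right, *_project(rows, wts, right, dropped), lam, restarts, rng, dropped, taxa
    )
    return f"({sub_l},{sub_r})"


def _graph_weights_local(n, lrows, wts, lam) -> np.ndarray:
    """Relaxed pairwise weight matrix used to warm-start the cut search:
    per quartet, +w on cross-pair ("bad") edges, -lam*w on within-pair
    ("good") edges; the REP sentinel contributes nothing."""
    W = np.zeros((n + 1, n + 1))
    a, b, c, d = lrows[:, 0], lrows[:, 1], lrows[:, 2], lrows[:, 3]
    for (i, j) in ((a, c), (a, d), (b, c), (b, d)):
        np.add.at(W, (i, j), wts)
        np.add.at(W, (j, i), wts)
    for (i, j) in ((a, b), (c, d)):
        np.add.at(W, (i, j), -lam * wts)
        np.add.at(W, (j, i), -lam * wts)
    return W[:n, :n]


def _best_cut(W: np.ndarray, rng, restarts: int):
    """Randomized hill climbing for a maximum cut of weight matrix W;
    single-vertex flips, both sides kept non-empty."""
    n = W.shape[0]
    best_val, best_side = -np.inf, None
    for _ in range(max(1, restarts)):
        s = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if abs(s.sum()) == n:  # one side empty: flip a random vertex
            s[rng.integers(n)] *= -1
        Ws = W @ s
        while True:
            gains = s * Ws  # cut-value increase from flipping each vertex
            counts = (s > 0).sum()
            pick = -1
            for i in np.argsort(gains)[::-1]:
                if gains[i] <= 1e-12:
                    break
                if (s[i] > 0 and counts == 1) or (s[i] < 0 and counts == n - 1):
                    continue  # flip would empty a side
                pick = int(i)
                break
            if pick < 0:
                break
            Ws = Ws - 2 * s[pick] * W[:, pick]
            s[pick] = -s[pick]
        val = (W.sum() - s @ W @ s) / 4.0
        if val > best_val:
            best_val, best_side = val, s > 0
    return best_side


# ---------------------------------------------------------------------------
# MQC polishing


def _st_leaf_dists(st: _SearchTree) -> np.ndarray:
    """Edge-count leaf-to-leaf distances of the unrooted tree.

    d(i, j) = number of edges separating i from j = sum over (unrooted)
    edges of the indicator that the edge's leaf-side mask splits the pair;
    the two rooted edges at the degree-2 root form one unrooted edge, so
    only one of them is counted.
    """
    n = st.n
    size = 2 * n - 1
    below = np.zeros((size, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for node in st.postorder_internal():
        c0, c1 = st.kids[node]
        below[node] = below[c0] | below[c1]
    skip = int(st.kids[st.root, 1])  # twin of the other root edge
    D = np.zeros((n, n), dtype=np.int64)
    for node in range(size):
        if node == st.root or st.parent[node] < 0 or node == skip:
            continue
        m = below[node]
        D += m[:, None] ^ m[None, :]
    return D


def _satisfied_weight_rows(st: _SearchTree, rows, wts) -> float:
    """Total weight of quartet rows displayed by the search tree."""
    D = _st_leaf_dists(st)
    a, b, c, d = rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3]
    s1 = D[a, b] + D[c, d]
    s2 = D[a, c] + D[b, d]
    s3 = D[a, d] + D[b, c]
    return float(wts @ ((s1 < s2) & (s1 < s3)))


def _mqc_nni_climb(st: _SearchTree, rows, wts, score: float, max_rounds: int = 100) -> float:
    """Steepest-ascent NNI climb on total satisfied quartet weight."""
    for _ in range(max_rounds):
        best_gain, best_move = 0.0, None
        for move in _nni_moves(st):
            _apply_nni(st, move)
            s = _satisfied_weight_rows(st, rows, wts)
            _apply_nni(st, move)
            if s - score > best_gain:
                best_gain, best_move = s - score, move
        if best_move is None:
            break
        _apply_nni(st, best_move)
        score += best_gain
    return score


def _subtree_nodes(st: _SearchTree, v: int) -> set:
    out, stack = set(), [v]
    while stack:
        u = stack.pop()
        out.add(u)
        if st.kids[u, 0] >= 0:
            stack.extend(int(c) for c in st.kids[u])
    return out

def _mqc_reinsertion_pass(
    st: _SearchTree, rows, wts, score: float, *, spr: bool = True
) -> float:
    """Prune-and-regraft pass on satisfied quartet weight: every leaf
    (and, with ``spr``, every internal subtree) is detached and regrafted
    on its best edge."""
    n = st.n
    prunable = range(2 * n - 1) if spr else range(n)
    for v in prunable:
        joint = int(st.parent[v])
        if joint < 0 or joint == st.root or v == st.root:
            continue
        inside = _subtree_nodes(st, v)
        _remove_leaf(st, v, joint)
        best_s, best_target = -np.inf, None
        for target in range(2 * n - 1):
            if target in inside or target in (joint, st.root):
                continue
            if st.parent[target] < 0 and target != st.root:
                continue
            _insert_leaf(st, v, target, joint)
            s = _satisfied_weight_rows(st, rows, wts)
            _remove_leaf(st, v, joint)
            if s > best_s:
                best_s, best_target = s, target
        _insert_leaf(st, v, best_target, joint)
        score = max(score, best_s)
    return score


def _mqc_refine(
    st: _SearchTree,
    rows,
    wts,
    rng=None,
    *,
    max_cycles: int = 3,
    kicks: int = 6,
    kick_size: int = 3,
    spr: bool = True,
) -> float:
    """Iterated local search on total satisfied quartet weight.

    Alternates NNI climbing with leaf-reinsertion passes until neither
    improves, then escapes plateaus with random multi-NNI kicks followed
    by re-climbing, keeping the best tree seen.  Mutates ``st`` to the
    best configuration and returns its score.
    """
    rng = rng or np.random.default_rng(0)

    def climb(tree, score):
        for _ in range(max_cycles):
            before = score
            score = _mqc_nni_climb(tree, rows, wts, score)
            score = _mqc_reinsertion_pass(tree, rows, wts, score, spr=spr)
            if score <= before + 1e-12:
                break
        return score

    best_score = climb(st, _satisfied_weight_rows(st, rows, wts))
    best = st.copy()
    total = float(wts.sum())
    for _ in range(kicks):
        if best_score >= total - 1e-9:
            break  # every quartet satisfied; nothing left to gain
        work = best.copy()
        for _ in range(kick_size):
            moves = _nni_moves(work)
            _apply_nni(work, moves[int(rng.integers(len(moves)))])
        s = _mqc_nni_climb(work, rows, wts, _satisfied_weight_rows(work, rows, wts))
        if s > best_score:
            s = climb(work, s)
            best_score, best = s, work.copy()
    st.kids[:] = best.kids
    st.parent[:] = best.parent
    st.root = best.root
    return best_score


def _quartet_separation_nj(rows, wts, taxa) -> PhyloTree:
    """Warm-start tree: neighbor joining on the fraction of quartets that
    place each taxon pair on opposite sides."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(taxa)
    sep = np.zeros((n, n))
    tog = np.zeros((n, n))
    a, b, c, d = rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3]
    for (i, j) in ((a, c), (a, d), (b, c), (b, d)):
        np.add.at(sep, (i, j), wts)
        np.add.at(sep, (j, i), wts)
    for (i, j) in ((a, b), (c, d)):
        np.add.at(tog, (i, j), wts)
        np.add.at(tog, (j, i), wts)
    total = sep + tog
    D = np.where(total > 0, sep / np.maximum(total, 1e-9), 1.0)
    np.fill_diagonal(D, 0.0)
    tree = nj(DistanceMatrix(D, list(taxa)))
    return read_newick(str(tree))
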
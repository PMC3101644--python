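"""Frozen tiny scenarios used by the test suite and for quick demos.

Everything is generated programmatically from fixed seeds — no data files
ship with the package.
"""

from __future__ import annotations

from .profile_sim import ModelCondition, build_profile
from .quartet_enc import QuartetSet
from .treekit import QuartetTopology, read_newick


def perfect_recovery_profile(seed: int = 11):
    """Mixed 16-taxon profile, 100% scaffold density, true-source-tree
    mode with no gene loss: every source tree is a faithful restriction of
    the model tree, so a correct supertree method must return the model
    tree exactly."""
    cond = ModelCondition(
        n=16,
        scaffold_density=1.0,
        profile_type="mixed",
        estimator="true",
        loss_rate=0.0,
        sites_per_gene=50,
        n_replicates=1,
    )
    return build_profile(cond, seed=seed)


def sparse_all_scaffold_profile(seed: int = 23):
    """All-scaffold 16-taxon profile at 25% density with the built-in
    estimator: little overlap, noisy source trees."""
    cond = ModelCondition(
        n=16,
        scaffold_density=0.25,
        profile_type="all-scaffold",
        sites_per_gene=200,
        n_replicates=1,
    )
    return build_profile(cond, seed=seed)


def conflicting_quartet_toy() -> QuartetSet:
    """Two topologies on the same four taxa with unequal weights; the
    majority topology ab|cd should win in any sensible amalgamation."""
    qs = QuartetSet(list("abcdef"))
    qs.add(QuartetTopology(("a", "b"), ("c", "d")), 2)
    qs.add(QuartetTopology(("a", "c"), ("b", "d")), 1)
    qs.add(QuartetTopology(("c", "d"), ("e", "f")), 1)
    qs.add(QuartetTopology(("a", "b"), ("e", "f")), 1)
    return qs


def unresolved_supertree_scenario():
    """A conservative (highly unresolved) supertree next to a resolved
    truth: a star tree has FP 0 by convention but FN 1, the pattern of
    veto-style supertree methods."""
    truth = read_newick("(((a,b),c),((d,e),f));")
    star = read_newick("(a,b,c,d,e,f);")
    return truth, star
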
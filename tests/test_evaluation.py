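"""Error rates, Sum-distances, Spearman, experiment orchestration."""

import math

import numpy as np
import pandas as pd
import pytest

from supertreesim import evaluation as ev
from supertreesim import profile_sim as ps
from supertreesim import supertree_methods as sm
from supertreesim.profile_sim import ModelCondition, SourceTree, SourceTreeProfile
from supertreesim.treekit import (
    TreeError,
    bipartition_set,
    read_newick,
    restrict,
)

from conftest import random_tree


class TestErrorRates:
    def test_identical_trees(self, six_leaf_tree):
        assert ev.error_rates(six_leaf_tree, six_leaf_tree) == (0.0, 0.0, 0.0)

    def test_star_estimate_convention(self):
        truth = read_newick("(((a,b),c),((d,e),f));")
        star = read_newick("(a,b,c,d,e,f);")
        fn, fp, rf = ev.error_rates(star, truth)
        assert (fn, fp, rf) == (1.0, 0.0, 0.5)

    def test_single_nni_on_five_leaves(self):
        # ((a,b),c,(d,e)) vs ((a,c),b,(d,e)): each has 2 bipartitions, the
        # de|abc split is shared, the other differs -> FN = FP = 1/2
        t0 = read_newick("((a,b),c,(d,e));")
        t1 = read_newick("((a,c),b,(d,e));")
        fn, fp, rf = ev.error_rates(t1, t0)
        assert (fn, fp, rf) == (0.5, 0.5, 0.5)

    def test_role_swap_symmetry(self):
        a, b = random_tree(10, 1), random_tree(10, 2)
        fn_ab, fp_ab, rf_ab = ev.error_rates(a, b)
        fn_ba, fp_ba, rf_ba = ev.error_rates(b, a)
        assert fn_ab == fp_ba and fp_ab == fn_ba and rf_ab == rf_ba

    def test_binary_pair_has_equal_rates(self):
        a, b = random_tree(12, 3), random_tree(12, 4)
        fn, fp, rf = ev.error_rates(a, b)
        assert fn == fp == rf  # equal bipartition counts for binary trees

    def test_leafset_mismatch(self):
        with pytest.raises(TreeError):
            ev.error_rates(read_newick("((a,b),(c,d));"),
                           read_newick("((a,b),(c,e));"))


def _true_profile(model_tree, subsets):
    trees = [
        SourceTree(restrict(model_tree, s), "clade", f"t{i}")
        for i, s in enumerate(subsets)
    ]
    return SourceTreeProfile(trees, model_tree)


class TestSumDistance:
    def test_zero_for_true_restrictions(self):
        t = random_tree(10, 5)
        leaves = sorted(t.leaves)
        prof = _true_profile(t, [leaves[:6], leaves[3:], leaves[::2]])
        assert ev.sum_distance(t, prof, "FN") == 0.0
        assert ev.sum_distance(t, prof, "RF") == 0.0

    def test_single_full_tree_equals_error_rate(self):
        t0, t1 = random_tree(9, 6), random_tree(9, 7)
        prof = _true_profile(t0, [sorted(t0.leaves)])
        fn, fp, _ = ev.error_rates(t1, t0)
        assert ev.sum_distance(t1, prof, "FN") == pytest.approx(fn)
        assert ev.sum_distance(t1, prof, "FP") == pytest.approx(fp)

    def test_unnormalized_rf_identity_for_binary_pairs(self):
        # for binary T and t on one leaf set: RF = 2 FN = 2 FP (raw counts)
        T, t = random_tree(10, 8), random_tree(10, 9)
        bT, bt = bipartition_set(T), bipartition_set(t)
        fn_raw = len(bt - bT)
        fp_raw = len(bT - bt)
        rf_raw = len(bt ^ bT)
        assert rf_raw == 2 * fn_raw == 2 * fp_raw

    def test_missing_taxa_rejected(self):
        t = random_tree(8, 1)
        prof = _true_profile(t, [sorted(t.leaves)])
        small = restrict(t, sorted(t.leaves)[:6])
        with pytest.raises(TreeError):
            ev.sum_distance(small, prof, "FN")

    def test_mean_of_ratios_mode(self):
        t0 = read_newick("(((a,b),c),((d,e),f));")
        t1 = read_newick("(((a,c),b),((d,e),f));")
        prof = _true_profile(t0, [list("abcdef"), list("abcde")])
        pooled = ev.sum_distance(t1, prof, "FN")
        averaged = ev.sum_distance(t1, prof, "FN", per_tree_mean=True)
        assert 0 < pooled < 1 and 0 < averaged < 1


class TestSpearman:
    def test_perfect_and_reversed(self):
        assert ev.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert ev.spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_closed_form_three_elements(self):
        # 1 - 6 * sum(d^2) / (n(n^2-1)) with d = (1,1,0) -> 1 - 12/24 = 0.5
        assert ev.spearman_rho([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_zero_variance_is_flagged_nan(self):
        assert math.isnan(ev.spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_bad_input(self):
        with pytest.raises(ValueError):
            ev.spearman_rho([1], [2])


def _tiny_conditions(reps=2):
    return [
        ModelCondition(
            n=12, scaffold_density=d, profile_type="mixed", n_replicates=reps,
            sites_per_gene=60, clade_size_min=4, estimator="true",
        )
        for d in (0.5, 1.0)
    ]


class TestRunExperiment:
    def test_row_count_and_determinism(self):
        conds = _tiny_conditions()
        res1 = ev.run_experiment(conds, ["gmrp", "qmc-exp-tsq"], seed=3,
                                 method_params={"gmrp": {"iterations": 1, "starts": 1}})
        assert len(res1) == 2 * 2 * 2  # conditions x replicates x methods
        res2 = ev.run_experiment(conds, ["gmrp", "qmc-exp-tsq"], seed=3,
                                 method_params={"gmrp": {"iterations": 1, "starts": 1}})
        pd.testing.assert_frame_equal(res1, res2)

    def test_failing_method_excludes_whole_replicate(self):
        def broken(profile, seed, **kw):
            raise RuntimeError("boom")

        ev.register_method("always-fails", broken)
        try:
            res = ev.run_experiment(
                _tiny_conditions(reps=1), ["qmc-exp-tsq", "always-fails"], seed=1
            )
        finally:
            del ev.METHOD_REGISTRY["always-fails"]
        assert res["failed"].all()
        assert ev.condition_means(res).empty

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ev.run_experiment(_tiny_conditions(), ["nope"], seed=0)

    def test_condition_means_match_recomputation(self):
        res = ev.run_experiment(_tiny_conditions(), ["qmc-exp-tsq"], seed=5)
        means = ev.condition_means(res)
        for _, row in means.iterrows():
            sub = res[(res["condition"] == row["condition"])
                      & (res["method"] == row["method"]) & (~res["failed"])]
            assert row["fn_mean"] == pytest.approx(sub["fn"].mean())
            assert row["n_replicates"] == len(sub)


class TestCorrelationStudy:
    @staticmethod
    def _table(rows):
        df = pd.DataFrame(
            rows,
            columns=["condition", "replicate", "method", "fn", "fp", "rf",
                     "sum_fn", "sum_fp", "sum_rf"],
        )
        df["failed"] = False
        return df

    def test_identical_methods_give_empty_cells(self):
        rows = [
            ("c", r, m, 0.5, 0.5, 0.5, 0.2, 0.2, 0.2)
            for r in range(3)
            for m in ("m1", "m2", "m3")
        ]
        out = ev.correlation_study(self._table(rows))
        assert (out["n"] == 0).all()
        assert out["mean"].isna().all()

    def test_perfectly_aligned_ranks(self):
        rows = []
        for r in range(4):
            for k, m in enumerate(("m1", "m2", "m3")):
                v = 0.1 * (k + 1) + 0.01 * r
                rows.append(("c", r, m, v, v, v, v, v, v))
        out = ev.correlation_study(self._table(rows))
        assert out["mean"].eq(1.0).all()
        assert out["low"].eq(1.0).all() and out["high"].eq(1.0).all()

    def test_hand_computed_two_replicates(self):
        # replicate 0: sum_fn ranks = fn ranks -> rho 1
        # replicate 1: sum_fn reversed vs fn -> rho -1 ; mean 0, range (-1, 1)
        rows = [
            ("c", 0, "m1", 0.1, 0.1, 0.1, 0.2, 0.2, 0.2),
            ("c", 0, "m2", 0.2, 0.2, 0.2, 0.3, 0.3, 0.3),
            ("c", 0, "m3", 0.3, 0.3, 0.3, 0.4, 0.4, 0.4),
            ("c", 1, "m1", 0.1, 0.1, 0.1, 0.4, 0.4, 0.4),
            ("c", 1, "m2", 0.2, 0.2, 0.2, 0.3, 0.3, 0.3),
            ("c", 1, "m3", 0.3, 0.3, 0.3, 0.2, 0.2, 0.2),
        ]
        out = ev.correlation_study(self._table(rows))
        cell = out[(out["criterion"] == "SumFN") & (out["error"] == "FN")].iloc[0]
        assert cell["mean"] == pytest.approx(0.0)
        assert (cell["low"], cell["high"]) == (-1.0, 1.0)
        assert cell["n"] == 2

    def test_rho_always_within_bounds(self):
        res = ev.run_experiment(
            _tiny_conditions(), ["gmrp", "qmc-exp-tsq", "qmc-geo-tsq"], seed=2,
            method_params={"gmrp": {"iterations": 1, "starts": 1}},
        )
        out = ev.correlation_study(res)
        vals = out[["mean", "low", "high"]].values
        finite = vals[~np.isnan(vals)]
        assert ((finite >= -1) & (finite <= 1)).all()


class TestDegradationTrend:
    def test_random_nni_degradation_increases_fn(self):
        """Walking away from the true tree by random NNI moves should
        increase expected FN (trend over seeds, not per-seed monotone)."""

        def degraded_fn(t0, moves, seed):
            labels = sorted(t0.leaves)
            st = sm._search_tree_from(t0, labels)
            rng = np.random.default_rng(seed)
            for _ in range(moves):
                opts = sm._nni_moves(st)
                sm._apply_nni(st, opts[int(rng.integers(len(opts)))])
            fn, _, _ = ev.error_rates(st.to_tree(labels), t0)
            return fn

        t0 = random_tree(16, 0, lengths=False)
        few = np.mean([degraded_fn(t0, 2, s) for s in range(10)])
        many = np.mean([degraded_fn(t0, 20, s) for s in range(10)])
        assert many > few
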
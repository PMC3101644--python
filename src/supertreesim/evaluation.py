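"""Evaluation: topological error, distance to source trees, experiments.

Error of an estimated supertree ``T`` against the true (model) tree ``T0``
is measured on bipartition sets: the false negative (FN) rate is the
fraction of true-tree bipartitions missing from ``T``, the false positive
(FP) rate the fraction of ``T``'s bipartitions absent from ``T0``, and the
Robinson-Foulds (RF) rate their mean.  Distance of a supertree to its
source-tree profile restricts ``T`` to each source tree's taxa and
aggregates the same quantities over the profile (Sum-FN/FP/RF).  The
correlation study asks how well the rank order of supertree methods by
distance-to-source-trees predicts their rank order by true error, via
Spearman rank correlations per replicate.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .treekit import PhyloTree, TreeError, bipartition_set, restrict
from .profile_sim import ModelCondition, SourceTreeProfile, build_profile

__all__ = [
    "ErrorReport",
    "error_rates",
    "sum_distance",
    "spearman_rho",
    "run_experiment",
    "condition_means",
    "correlation_study",
    "METHOD_REGISTRY",
    "register_method",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "condition", "n", "density", "profile_type", "replicate", "method",
    "fn", "fp", "rf", "sum_fn", "sum_fp", "sum_rf", "failed",
]


@dataclasses.dataclass
class ErrorReport:
    """All six rates for one (method, replicate) cell."""

    method: str
    replicate: int
    condition: str
    fn: float
    fp: float
    rf: float
    sum_fn: float
    sum_fp: float
    sum_rf: float
    failed: bool = False


# ---------------------------------------------------------------------------
# topological error


def error_rates(T: PhyloTree, T0: PhyloTree) -> tuple[float, float, float]:
    """(FN, FP, RF) rates of an estimated tree against the true tree.

    FN is normalized by the number of true-tree bipartitions, FP by the
    number of estimated-tree bipartitions (0 when the estimate has no
    internal edges), RF is the average of the two.
    """
    if T.leaves != T0.leaves:
        raise TreeError("error_rates requires identical leaf sets")
    bt, be = bipartition_set(T0), bipartition_set(T)
    if not bt:
        raise TreeError("true tree has no internal edges")
    fn = len(bt - be) / len(bt)
    fp = len(be - bt) / len(be) if be else 0.0
    return fn, fp, (fn + fp) / 2.0


def sum_distance(T: PhyloTree, profile: SourceTreeProfile, kind: str = "FN",
                 *, per_tree_mean: bool = False) -> float:
    """Normalized total topological distance of a supertree to its profile.

    For each source tree ``t`` the supertree is restricted to ``t``'s taxa;
    Sum-FN aggregates the number of edges of ``t`` missing from the
    restriction over the total number of source-tree edges (ratio of sums;
    ``per_tree_mean`` switches to the mean of per-tree ratios).  Sum-FP
    uses the restricted supertree's edges as reference, and Sum-RF is the
    mean of Sum-FN and Sum-FP.
    """
    kind = kind.upper()
    if kind == "RF":
        return (
            sum_distance(T, profile, "FN", per_tree_mean=per_tree_mean)
            + sum_distance(T, profile, "FP", per_tree_mean=per_tree_mean)
        ) / 2.0
    if kind not in ("FN", "FP"):
        raise ValueError("kind must be FN, FP or RF")
    num, den = 0, 0
    ratios = []
    for st in profile:
        missing = st.taxa - T.leaves
        if missing:
            raise TreeError(
                f"source-tree taxa missing from supertree: {sorted(missing)}"
            )
        if len(st.taxa) < 4:
            continue
        rt = restrict(T, st.taxa)
        bs, br = bipartition_set(st.tree), bipartition_set(rt)
        if kind == "FN":
            d, m = len(bs - br), len(bs)
        else:
            d, m = len(br - bs), len(br)
        num += d
        den += m
        if m:
            ratios.append(d / m)
    if per_tree_mean:
        return float(np.mean(ratios)) if ratios else 0.0
    return num / den if den else 0.0


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties.

    Returns NaN (flagged by the caller) when either vector has zero
    variance, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman: zero variance, correlation undefined")
        return math.nan
    return float(scipy.stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# method registry and experiment orchestration


def _make_qmc(strategy: str):
    def run(profile: SourceTreeProfile, seed: int, **params) -> PhyloTree:
        from .quartet_enc import encode_profile
        from .supertree_methods import maxcut_amalgamate

        enc = encode_profile(profile, strategy, seed)
        return maxcut_amalgamate(enc, profile.taxa_union, seed=seed, **params)

    return run


def _run_gmrp(profile: SourceTreeProfile, seed: int, **params) -> PhyloTree:
    from .supertree_methods import gmrp

    return gmrp(profile, seed=seed, **params)


#: method name -> callable(profile, seed, **params) -> PhyloTree
METHOD_REGISTRY = {
    "gmrp": _run_gmrp,
    "qmc-all": _make_qmc("all"),
    "qmc-geo-tsq": _make_qmc("geo+tsq"),
    "qmc-exp-tsq": _make_qmc("exp+tsq"),
}


def register_method(name: str, fn) -> None:
    METHOD_REGISTRY[name] = fn


def run_supertree_method(name: str, profile: SourceTreeProfile, seed: int,
                         **params) -> PhyloTree:
    try:
        fn = METHOD_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; registered: {sorted(METHOD_REGISTRY)}"
        ) from None
    return fn(profile, seed, **params)


def evaluate_supertree(T: PhyloTree, model_tree: PhyloTree,
                       profile: SourceTreeProfile) -> dict:
    """All six rates of one supertree; the model tree is restricted to the
    supertree's taxa (taxa sampled by no dataset cannot be scored)."""
    truth = restrict(model_tree, T.leaves)
    fn, fp, rf = error_rates(T, truth)
    return {
        "fn": fn,
        "fp": fp,
        "rf": rf,
        "sum_fn": sum_distance(T, profile, "FN"),
        "sum_fp": sum_distance(T, profile, "FP"),
        "sum_rf": sum_distance(T, profile, "RF"),
    }


def run_experiment(
    conditions: Sequence[ModelCondition],
    methods: Sequence[str],
    seed: int = 0,
    method_params: dict | None = None,
) -> pd.DataFrame:
    """Full benchmark: per condition x replicate, simulate a profile, run
    every method, and score it.

    A replicate in which any requested method fails is flagged
    (``failed``) for all methods and excluded from condition means, so
    that means always compare methods on a common set of replicates.
    Deterministic for a given master seed.
    """
    method_params = method_params or {}
    for m in methods:
        if m not in METHOD_REGISTRY:
            raise ValueError(f"unknown method {m!r}")
    rows = []
    master = np.random.SeedSequence(seed)
    cond_seeds = master.spawn(len(conditions))
    for cond, cseed in zip(conditions, cond_seeds):
        rep_seeds = cseed.spawn(cond.n_replicates)
        for rep, rseed in enumerate(rep_seeds):
            rep_seed = int(rseed.generate_state(1)[0] % 2**31)
            model_tree, profile = build_profile(cond, seed=rep_seed)
            rep_rows = []
            any_failed = False
            for method in methods:
                try:
                    T = run_supertree_method(
                        method, profile, rep_seed, **method_params.get(method, {})
                    )
                    scores = evaluate_supertree(T, model_tree, profile)
                except Exception:
                    logger.exception(
                        "method %s failed on %s replicate %d",
                        method, cond.condition_id, rep,
                    )
                    any_failed = True
                    scores = dict.fromkeys(
                        ("fn", "fp", "rf", "sum_fn", "sum_fp", "sum_rf"), math.nan
                    )
                rep_rows.append(
                    {
                        "condition": cond.condition_id,
                        "n": cond.n,
                        "density": cond.scaffold_density,
                        "profile_type": cond.profile_type,
                        "replicate": rep,
                        "method": method,
                        **scores,
                        "failed": False,
                    }
                )
            if any_failed:
                for r in rep_rows:
                    r["failed"] = True
            rows.extend(rep_rows)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def condition_means(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error per condition x method over complete-case
    replicates (replicates with any failure are excluded throughout)."""
    ok = results[~results["failed"]]
    metrics = ["fn", "fp", "rf", "sum_fn", "sum_fp", "sum_rf"]
    grouped = ok.groupby(["condition", "method"], sort=True)
    out = grouped[metrics].agg(["mean", "sem"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out["n_replicates"] = grouped.size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# rank-correlation study


CRITERIA = {"SumFN": "sum_fn", "SumFP": "sum_fp", "SumRF": "sum_rf"}
ERRORS = {"FN": "fn", "FP": "fp", "RF": "rf"}


def correlation_study(results: pd.DataFrame) -> pd.DataFrame:
    """Does distance-to-source-trees predict true error?

    Within each replicate, methods are ranked by each Sum-criterion and by
    each true-error metric, and the Spearman correlation of the two
    rankings is computed.  The summary reports mean and range of the
    per-replicate correlations for every condition x criterion x error
    cell; undefined correlations (all methods tied) are flagged and
    excluded from the summary statistics.
    """
    ok = results[~results["failed"]]
    records = []
    for condition, cond_df in ok.groupby("condition", sort=True):
        cells: dict = {(c, e): [] for c in CRITERIA for e in ERRORS}
        n_und = 0
        for _, rep_df in cond_df.groupby("replicate"):
            if rep_df["method"].nunique() < 2:
                continue
            for cname, ccol in CRITERIA.items():
                for ename, ecol in ERRORS.items():
                    rho = spearman_rho(rep_df[ccol].values, rep_df[ecol].values)
                    if math.isnan(rho):
                        n_und += 1
                    else:
                        cells[(cname, ename)].append(rho)
        if n_und:
            logger.info(
                "correlation_study: %d undefined correlations in %s",
                n_und, condition,
            )
        for (cname, ename), rhos in cells.items():
            records.append(
                {
                    "condition": condition,
                    "criterion": cname,
                    "error": ename,
                    "mean": float(np.mean(rhos)) if rhos else math.nan,
                    "low": float(np.min(rhos)) if rhos else math.nan,
                    "high": float(np.max(rhos)) if rhos else math.nan,
                    "n": len(rhos),
                }
            )
    return pd.DataFrame(
        records,
        columns=["condition", "criterion", "error", "mean", "low", "high", "n"],
    )
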
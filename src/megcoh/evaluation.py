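"""ROC/AUC detection scoring and statistical comparison across weights.

Detection of simulated sources on a map is scored by sweeping an activation
threshold α over every distinct map value:

    TPF(α) = TP(α) / n_truth,
    FPF(α) = FP(α) / (n_evaluable − n_truth),

with TP(α) the truth vertices at or above α and FP(α) the remaining
evaluable vertices at or above α.  The AUC is the trapezoidal area under the
(FPF, TPF) curve, which for this exact sweep equals the normalized
Mann–Whitney U statistic (ties credited one half).

For seed-based coherence maps the reference patch is excluded from both the
truth set and the false-positive pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    IncompleteDesignError,
    ParameterError,
    UndefinedROCError,
)
from .spectral import SpectralMap

__all__ = [
    "ROCResult",
    "roc_auc",
    "compare_auc_paired",
    "aggregate_optimal_lambda",
    "STUDY_TABLE_COLUMNS",
]

# fixed StudyTable CSV header
STUDY_TABLE_COLUMNS = [
    "config_id",
    "snr_db",
    "patch_area_cm2",
    "coupling",
    "reg_weight",
    "analysis",
    "auc",
    "achieved_coherence",
    "seed",
]


@dataclass
class ROCResult:
    """Exact ROC curve and its area.

    ``thresholds`` are stored in decreasing order, so (fpf, tpf) runs from
    (0, 0) at α = +inf to (1, 1) at α = −inf.
    """

    thresholds: np.ndarray
    tpf: np.ndarray
    fpf: np.ndarray
    auc: float
    n_truth: int
    n_total: int


def _map_values(smap) -> np.ndarray:
    if isinstance(smap, SpectralMap):
        return smap.values
    return np.asarray(smap, dtype=float)


def roc_auc(smap, truth_vertices: Iterable[int], excluded: Iterable[int] = ()) -> ROCResult:
    """Score a per-vertex map against ground-truth vertices.

    ``excluded`` vertices (the coherence reference patch) are removed from
    both the truth set and the false-positive pool before the sweep.
    """
    values = _map_values(smap)
    n = values.shape[0]
    excluded = {int(v) for v in excluded}
    if isinstance(smap, SpectralMap):
        excluded |= set(smap.excluded_vertices)
    truth = {int(v) for v in truth_vertices} - excluded
    if not truth:
        raise UndefinedROCError("no ground-truth vertices left after exclusion")
    if not truth <= set(range(n)):
        raise ParameterError("truth vertices out of range")
    evaluable = np.ones(n, dtype=bool)
    if excluded:
        evaluable[np.asarray(sorted(excluded), int)] = False
    vals = values[evaluable]
    if not np.all(np.isfinite(vals)):
        raise ParameterError("map contains non-finite values on evaluable vertices")
    is_truth = np.zeros(n, dtype=bool)
    is_truth[np.asarray(sorted(truth), int)] = True
    labels = is_truth[evaluable]
    n_truth = int(labels.sum())
    n_total = int(evaluable.sum())
    n_false = n_total - n_truth
    if n_false == 0:
        raise UndefinedROCError("no non-truth vertices to score false positives")

    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    sorted_truth = labels[order].astype(float)
    # group ties: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(sorted_vals) != 0)
    block_ends = np.r_[distinct, n_total - 1]
    cum_tp = np.cumsum(sorted_truth)[block_ends]
    cum_all = block_ends + 1.0
    tpf = np.r_[0.0, cum_tp / n_truth]
    fpf = np.r_[0.0, (cum_all - cum_tp) / n_false]
    thresholds = np.r_[np.inf, sorted_vals[block_ends]]
    auc = float(np.trapezoid(tpf, fpf))
    return ROCResult(thresholds, tpf, fpf, auc, n_truth, n_total)


def compare_auc_paired(auc_a: Sequence[float], auc_b: Sequence[float]) -> tuple[float, float]:
    """Paired two-tailed t-test on per-configuration AUC values.

    Returns (t statistic, two-sided p).  Inputs must be paired by
    configuration and contain at least 3 pairs.
    """
    a = np.asarray(auc_a, float)
    b = np.asarray(auc_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("AUC vectors must be equal-length 1-D sequences")
    if a.size < 3:
        raise ParameterError("need at least 3 paired configurations")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateTestError("zero-variance differences; t-test degenerate")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def aggregate_optimal_lambda(
    table: pd.DataFrame,
    analysis: str,
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean AUC per regularization weight within each group, plus the argmax.

    Returns one row per (group, weight) with columns ``mean_auc``,
    ``is_optimal``, ``tie`` and ``at_grid_edge``.  Ties break toward the
    larger weight.  Raises :class:`IncompleteDesignError` if any group lacks
    part of the weight grid.
    """
    if analysis not in ("power", "coherence"):
        raise ParameterError("analysis must be 'power' or 'coherence'")
    sub = table[table["analysis"] == analysis]
    if sub.empty:
        raise IncompleteDesignError(f"no rows for analysis {analysis!r}")
    group_by = list(group_by)
    grid = np.sort(sub["reg_weight"].unique())

    def summarize(df: pd.DataFrame, key) -> pd.DataFrame:
        mean_auc = df.groupby("reg_weight")["auc"].mean().sort_index()
        missing = sorted(set(grid) - set(mean_auc.index))
        if missing:
            raise IncompleteDesignError(
                f"group {key!r} is missing weights {missing}"
            )
        best = mean_auc.max()
        optima = mean_auc.index[np.isclose(mean_auc.values, best)]
        chosen = optima.max()  # tie-break toward larger weight
        out = mean_auc.reset_index().rename(columns={"auc": "mean_auc"})
        out["is_optimal"] = out["reg_weight"] == chosen
        out["tie"] = len(optima) > 1
        out["at_grid_edge"] = out["is_optimal"] & (
            (chosen == grid[0]) | (chosen == grid[-1])
        )
        for col, val in zip(group_by, key if isinstance(key, tuple) else (key,)):
            out.insert(0, col, val)
        return out

    if not group_by:
        return summarize(sub, ())
    pieces = [summarize(df, key) for key, df in sub.groupby(group_by)]
    return pd.concat(pieces, ignore_index=True)
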
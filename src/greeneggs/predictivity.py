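"""Cutoff-sweep classifier evaluation and per-endpoint relative risk.

The assay calls a compound positive when its normalized score (log fold
ratio over DMSO) is at or above a cutoff.  Sweeping the cutoff over every
observed score value yields step-function sensitivity, specificity and
balanced accuracy against the mammalian labels; the best cutoff maximizes
balanced accuracy.  For each individual multigenerational endpoint, the
relative risk of endpoint positivity among assay-positives over
assay-negatives is maximized over cutoffs in a fixed range, with a Katz
log-method 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionTable",
    "SweepResult",
    "RRResult",
    "confusion_at_cutoff",
    "sweep",
    "relative_risk",
    "max_rr_in_range",
    "endpoint_rr_table",
]

ScoreLike = Union[Mapping[str, float], pd.Series]
LabelLike = Union[Mapping[str, bool], pd.Series, pd.DataFrame]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of assay call vs mammalian label at one cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


@dataclass(frozen=True)
class SweepResult:
    """Metrics along the full cutoff grid for one time point."""

    table: pd.DataFrame  # cutoff, tp, fp, fn, tn, sensitivity, specificity, balanced_accuracy
    best_cutoff: float
    best_balanced_accuracy: float
    time_point: Optional[str] = None

    @property
    def cutoffs(self) -> np.ndarray:
        return self.table["cutoff"].to_numpy()


@dataclass(frozen=True)
class RRResult:
    """Maximum relative risk for one endpoint within a cutoff range."""

    endpoint: Optional[str]
    time_point: Optional[str]
    best_cutoff: float
    relative_risk: float
    ci_low: float
    ci_high: float
    cutoff_range: Tuple[float, float]
    confusion: Optional[ConfusionTable] = None


def _align(scores: ScoreLike, labels: LabelLike) -> tuple[np.ndarray, np.ndarray]:
    """Pair scores with boolean labels, dropping excluded compounds."""
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    if isinstance(labels, pd.DataFrame):
        from .toxref_labels import binary_labels

        lab = binary_labels(labels)
        excluded = set(labels.loc[labels["excluded"].astype(bool), "compound"])
    else:
        lab = pd.Series(labels, dtype=bool) if not isinstance(labels, pd.Series) else labels.astype(bool)
        excluded = set()
    s = s[~s.index.isin(excluded)]
    unlabeled = [c for c in s.index if c not in lab.index]
    if unlabeled:
        raise ValueError(
            f"scored compounds without a label (and not excluded): {sorted(unlabeled)}"
        )
    lab = lab.loc[s.index]
    return s.to_numpy(), lab.to_numpy()


def confusion_at_cutoff(
    scores: ScoreLike, labels: LabelLike, cutoff: float
) -> ConfusionTable:
    """Count the 2x2 table with the assay calling positive at ``score >= cutoff``."""
    s, y = _align(scores, labels)
    pred = s >= cutoff
    return ConfusionTable(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


def sweep(
    scores: ScoreLike, labels: LabelLike, time_point: Optional[str] = None
) -> SweepResult:
    """Evaluate the classifier at every observed score plus a supremum sentinel.

    The grid runs from the lowest observed score (everything called positive)
    to one point above the highest (everything called negative); metrics are
    step functions of the cutoff, so the grid is exhaustive.  The best cutoff
    is the smallest one attaining the maximum balanced accuracy.
    """
    s, y = _align(scores, labels)
    if y.all() or not y.any():
        raise ValueError(
            "degenerate labels: need at least one positive and one negative "
            "compound for balanced accuracy"
        )
    grid = np.unique(s)
    grid = np.append(grid, grid[-1] + 1.0)  # sentinel: all-negative point
    rows = []
    for c in grid:
        t = ConfusionTable(
            tp=int(np.sum((s >= c) & y)),
            fp=int(np.sum((s >= c) & ~y)),
            fn=int(np.sum((s < c) & y)),
            tn=int(np.sum((s < c) & ~y)),
        )
        rows.append(
            {
                "cutoff": float(c),
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
                "sensitivity": t.sensitivity,
                "specificity": t.specificity,
                "balanced_accuracy": t.balanced_accuracy,
            }
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["balanced_accuracy"].to_numpy().argmax())  # first max: smallest cutoff
    return SweepResult(
        table=table,
        best_cutoff=float(table.loc[best_idx, "cutoff"]),
        best_balanced_accuracy=float(table.loc[best_idx, "balanced_accuracy"]),
        time_point=time_point,
    )


def relative_risk(
    table: ConfusionTable, z: float = 1.96, continuity: float = 0.5
) -> tuple[float, float, float]:
    """Relative risk of label positivity in assay-positives vs assay-negatives.

    rr = [tp/(tp+fp)] / [fn/(fn+tn)], with a Katz log-method CI:
    exp(ln rr +/- z * sqrt(1/tp - 1/(tp+fp) + 1/fn - 1/(fn+tn))).
    When any cell is zero, ``continuity`` is added to all four cells before
    both the point estimate and the interval.

    Returns ``(rr, ci_low, ci_high)``.
    """
    if table.tp + table.fp == 0:
        raise ValueError("relative risk undefined: no assay-positive compounds")
    if table.fn + table.tn == 0:
        raise ValueError("relative risk undefined: no assay-negative compounds")
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    if min(a, b, c, d) == 0:
        if continuity <= 0:
            raise ValueError("zero cell with no continuity correction")
        a, b, c, d = (x + continuity for x in (a, b, c, d))
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    lo = rr * math.exp(-z * se)
    hi = rr * math.exp(z * se)
    return rr, lo, hi


def max_rr_in_range(
    scores: ScoreLike,
    endpoint_labels: LabelLike,
    cutoff_range: Tuple[float, float] = (1.0, 2.0),
    z: float = 1.96,
    continuity: float = 0.5,
    min_positives: int = 2,
    endpoint: Optional[str] = None,
    time_point: Optional[str] = None,
) -> RRResult:
    """Maximize relative risk over grid cutoffs within ``cutoff_range``.

    The grid is the observed unique scores restricted to the closed range;
    ties in the maximum are broken toward the smaller cutoff.  The endpoint
    must have at least ``min_positives`` positive compounds.
    """
    s, y = _align(scores, endpoint_labels)
    n_pos = int(y.sum())
    if n_pos < min_positives:
        raise ValueError(
            f"endpoint has {n_pos} positive compounds; need >= {min_positives}"
        )
    lo, hi = cutoff_range
    grid = np.unique(s)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise ValueError(f"no observed score inside cutoff range [{lo}, {hi}]")
    best = None
    for c in grid:
        t = confusion_at_cutoff(pd.Series(s, index=range(len(s))), pd.Series(y, index=range(len(s))), c)
        if t.tp + t.fp == 0 or t.fn + t.tn == 0:
            continue
        rr, ci_lo, ci_hi = relative_risk(t, z=z, continuity=continuity)
        if best is None or rr > best[1]:  # strict: ties keep the smaller cutoff
            best = (float(c), rr, ci_lo, ci_hi, t)
    if best is None:
        raise ValueError("relative risk undefined at every cutoff in range")
    c, rr, ci_lo, ci_hi, t = best
    return RRResult(
        endpoint=endpoint,
        time_point=time_point,
        best_cutoff=c,
        relative_risk=rr,
        ci_low=ci_lo,
        ci_high=ci_hi,
        cutoff_range=(float(lo), float(hi)),
        confusion=t,
    )


def endpoint_rr_table(
    scores_by_tp: pd.DataFrame,
    endpoint_records: pd.DataFrame,
    threshold: float = 500.0,
    cutoff_range: Tuple[float, float] = (1.0, 2.0),
    z: float = 1.96,
    continuity: float = 0.5,
    min_positives: int = 2,
) -> pd.DataFrame:
    """Per-endpoint maximum relative risks across time points.

    ``scores_by_tp`` is a normalized-score table (compound, time_point, score);
    ``endpoint_records`` an endpoint LEL table.  For each endpoint with enough
    positive compounds, the relative risk is maximized over in-range cutoffs
    at each time point; one row per endpoint x time point, with the overall
    best time point flagged.
    """
    rows = []
    for endpoint, grp in endpoint_records.groupby("endpoint", sort=True):
        lel = pd.to_numeric(grp["mg_lel"], errors="coerce")
        pos = pd.Series((lel <= threshold).to_numpy(), index=grp["compound"].to_numpy())
        pos = pos.groupby(level=0).any()
        for tp, sgrp in scores_by_tp.groupby("time_point", sort=True):
            s = pd.Series(sgrp["score"].to_numpy(), index=sgrp["compound"].to_numpy())
            s = s[s.index.isin(pos.index)]
            try:
                r = max_rr_in_range(
                    s,
                    pos,
                    cutoff_range=cutoff_range,
                    z=z,
                    continuity=continuity,
                    min_positives=min_positives,
                    endpoint=str(endpoint),
                    time_point=str(tp),
                )
            except ValueError:
                continue
            rows.append(
                {
                    "endpoint": endpoint,
                    "time_point": tp,
                    "best_cutoff": r.best_cutoff,
                    "relative_risk": r.relative_risk,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["endpoint", "time_point", "best_cutoff", "relative_risk", "ci_low", "ci_high"],
    )
    if not out.empty:
        out["is_best_time_point"] = out.groupby("endpoint")["relative_risk"].transform(
            lambda v: v == v.max()
        )
    return out
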
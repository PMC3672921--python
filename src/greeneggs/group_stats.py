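"""Nonparametric two-group comparisons (two-tailed Mann-Whitney U).

Used both to compare exposure groups against DMSO and to test whether the
screen's scores partition reproductive toxicants from non-toxicants.  Small
tie-free samples get the exact permutation distribution; larger or tied
samples a tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "mann_whitney_u", "compare_categories"]

#: largest total sample size for which the exact null distribution is used
EXACT_LIMIT = 20


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    members_a: tuple = ()
    members_b: tuple = ()


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    label_a: str = "a",
    label_b: str = "b",
    members_a: Sequence = (),
    members_b: Sequence = (),
) -> GroupComparison:
    """Mann-Whitney U test between two observation vectors.

    U is the rank-sum statistic of group ``a`` with midranks on ties.  The
    exact permutation p-value is used when the pooled sample has at most
    :data:`EXACT_LIMIT` observations and no ties; otherwise the normal
    approximation with tie-corrected variance and 0.5 continuity correction.
    The two-sided p-value is ``min(1, 2 * one-sided)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        members_a=tuple(members_a),
        members_b=tuple(members_b),
    )


def compare_categories(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    grouping: str = "reprotox_vs_none",
    time_point: Optional[str] = None,
    k: int = 10,
    values: Optional[Mapping[str, float]] = None,
) -> GroupComparison:
    """Mann-Whitney comparison between screen-defined compound groups.

    grouping = "reprotox_vs_none": compounds in the high or intermediate
    reproductive-toxicity category vs compounds in the none category;
    the compared values default to the assay scores at ``time_point``.

    grouping = "most_vs_least_k": the k highest-scoring vs k lowest-scoring
    compounds at ``time_point``; ``values`` can map compounds to an external
    measurement (e.g. apoptotic nucleus counts) to compare instead of the
    scores themselves.
    """
    sub = scores if time_point is None else scores[scores["time_point"] == time_point]
    if sub.empty:
        raise ValueError(f"no scores at time point {time_point!r}")
    s = pd.Series(sub["score"].to_numpy(), index=sub["compound"].to_numpy())
    if s.index.duplicated().any():
        raise ValueError("one score per compound required; pass time_point to disambiguate")

    if grouping == "reprotox_vs_none":
        lab = labels[~labels["excluded"].astype(bool)]
        cat = pd.Series(lab["category"].to_numpy(), index=lab["compound"].to_numpy())
        cat = cat[cat.index.isin(s.index)]
        tox = cat.index[cat.isin(["high", "intermediate"])]
        none = cat.index[cat == "none"]
        if len(tox) == 0 or len(none) == 0:
            raise ValueError(
                f"empty comparison group: {len(tox)} reprotox vs {len(none)} none"
            )
        members_a, members_b = list(tox), list(none)
        label_a, label_b = "high+intermediate", "none"
    elif grouping == "most_vs_least_k":
        if 2 * k > s.size:
            raise ValueError(f"need at least 2k={2 * k} scored compounds, have {s.size}")
        ranked = s.sort_values(ascending=False, kind="mergesort")
        members_a = list(ranked.index[:k])
        members_b = list(ranked.index[-k:])
        label_a, label_b = f"{k} most aneugenic", f"{k} least aneugenic"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    if set(members_a) & set(members_b):
        raise ValueError("comparison groups overlap")
    vals = pd.Series(values) if values is not None else s
    missing = [c for c in (*members_a, *members_b) if c not in vals.index]
    if missing:
        raise ValueError(f"no value for compounds: {sorted(missing)}")
    return mann_whitney_u(
        vals.loc[members_a].to_numpy(),
        vals.loc[members_b].to_numpy(),
        label_a=label_a,
        label_b=label_b,
        members_a=members_a,
        members_b=members_b,
    )
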
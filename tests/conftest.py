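"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never call package code)

def brute_force_sweep(scores: np.ndarray, labels: np.ndarray):
    """Recompute the cutoff sweep by direct counting at every threshold.

    Returns a list of dicts (cutoff, tp, fp, fn, tn, sens, spec, ba) over the
    unique scores plus an all-negative sentinel, and the (smallest-cutoff)
    argmax of balanced accuracy.
    """
    grid = sorted(set(float(s) for s in scores))
    grid.append(grid[-1] + 1.0)
    rows = []
    for c in grid:
        tp = sum(1 for s, y in zip(scores, labels) if s >= c and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= c and not y)
        fn = sum(1 for s, y in zip(scores, labels) if s < c and y)
        tn = sum(1 for s, y in zip(scores, labels) if s < c and not y)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        rows.append(
            dict(cutoff=c, tp=tp, fp=fp, fn=fn, tn=tn, sens=sens, spec=spec,
                 ba=0.5 * (sens + spec))
        )
    best = max(rows, key=lambda r: (r["ba"], -r["cutoff"]))
    return rows, best


def katz_rr_by_hand(tp, fp, fn, tn, z=1.96):
    """Direct arithmetic for the RR point estimate and log-method CI."""
    import math

    rr = (tp / (tp + fp)) / (fn / (fn + tn))
    se = math.sqrt(1 / tp - 1 / (tp + fp) + 1 / fn - 1 / (fn + tn))
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements.

    Tie-free samples only.  U is counted as the number of (a_i, b_j) pairs
    with a_i > b_j; the two-sided p doubles the smaller tail of the exact
    permutation distribution of U, capped at 1.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp = set(idx)
        u = sum(
            1
            for i in grp
            for j in range(len(pooled))
            if j not in grp and pooled[i] > pooled[j]
        )
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def tiny_assay() -> pd.DataFrame:
    """Two compounds + DMSO on one plate, both time points, two replicates."""
    rows = []
    counts = {
        ("DMSO", "24h"): [(3000, 6), (3100, 7)],
        ("DMSO", "65h"): [(2900, 5), (3050, 6)],
        ("cmpdA", "24h"): [(2500, 40), (2400, 38)],
        ("cmpdA", "65h"): [(2300, 80), (2350, 85)],
        ("cmpdB", "24h"): [(3010, 7), (2990, 6)],
        ("cmpdB", "65h"): [(3005, 5), (2995, 7)],
    }
    for (compound, tp), reps in counts.items():
        for i, (e, gfp) in enumerate(reps, start=1):
            rows.append(
                dict(compound=compound, time_point=tp, replicate=i,
                     plate=f"{tp}-p1", n_worms=300, n_embryos=e, n_gfp_pos=gfp)
            )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_endpoints() -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("c1", "epA", 100.0),
            ("c1", "epB", np.nan),
            ("c2", "epA", 600.0),
            ("c3", "epA", np.nan),
            ("c3", "epB", np.nan),
            ("c4", "epA", 499.0),
            ("c4", "epB", 250.0),
        ],
        columns=["compound", "endpoint", "mg_lel"],
    )
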
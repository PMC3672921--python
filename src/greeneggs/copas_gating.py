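"""Large-particle flow-sorter event simulation and gating.

A COPAS-style sorter reports, per event, a time-of-flight (ToF, a size
proxy) and a GFP peak height.  Gating proceeds in two steps: a ToF window
keeps only objects of embryo size (everything else is debris), and a GFP
threshold — calibrated as a high quantile of in-gate heights from an
untreated wild-type control population — splits in-gate events into GFP-
and GFP+ embryos.  The default 99.8th-percentile calibration anchors the
false-positive rate to the < 0.2% natural XO male frequency.

Event streams are simulated as seeded log-normal mixtures of debris,
GFP- embryos, and GFP+ embryos, with the component identity retained as
hidden truth for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "GateConfig",
    "EventCounts",
    "wildtype_mixture",
    "him8_mixture",
    "simulate_events",
    "calibrate_threshold",
    "classify_events",
    "fold_induction",
]

EVENT_COLUMNS = ["tof", "gfp_height"]


@dataclass(frozen=True)
class Population:
    """One mixture component: weight and log-normal (ToF, GFP) parameters."""

    weight: float
    tof_meanlog: float
    tof_sdlog: float
    gfp_meanlog: float
    gfp_sdlog: float


#: default component shapes, in arbitrary sorter units: debris is small and
#: dim, embryos sit in the ToF gate, GFP+ embryos are ~50x brighter than GFP-
_DEBRIS = dict(tof_meanlog=math.log(30.0), tof_sdlog=0.35, gfp_meanlog=math.log(5.0), gfp_sdlog=0.6)
_EMBRYO_TOF = dict(tof_meanlog=math.log(200.0), tof_sdlog=0.15)
_GFP_NEG = dict(gfp_meanlog=math.log(10.0), gfp_sdlog=0.5)
_GFP_POS = dict(gfp_meanlog=math.log(500.0), gfp_sdlog=0.4)


def _mixture(debris_weight: float, gfp_pos_rate: float) -> dict[str, Population]:
    embryo = 1.0 - debris_weight
    return {
        "debris": Population(weight=debris_weight, **_DEBRIS),
        "gfp_neg_embryo": Population(
            weight=embryo * (1.0 - gfp_pos_rate), **_EMBRYO_TOF, **_GFP_NEG
        ),
        "gfp_pos_embryo": Population(
            weight=embryo * gfp_pos_rate, **_EMBRYO_TOF, **_GFP_POS
        ),
    }


def wildtype_mixture(gfp_pos_rate: float = 0.002, debris_weight: float = 0.3) -> dict[str, Population]:
    """Untreated wild-type stream: rare GFP+ embryos (natural male frequency)."""
    return _mixture(debris_weight, gfp_pos_rate)


def him8_mixture(gfp_pos_rate: float = 0.30, debris_weight: float = 0.2) -> dict[str, Population]:
    """him-8-like stream: ~30% of embryo events are GFP+ (male)."""
    return _mixture(debris_weight, gfp_pos_rate)


@dataclass(frozen=True)
class GateConfig:
    """Size gate plus GFP threshold calibration."""

    tof_window: Tuple[float, float] = (100.0, 400.0)
    control_quantile: float = 0.998
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.tof_window
        if not lo < hi:
            raise ValueError(f"ToF window must satisfy lo < hi, got {self.tof_window}")
        if not 0.0 < self.control_quantile < 1.0:
            raise ValueError("control_quantile must lie in (0, 1)")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class EventCounts:
    n_total: int
    n_debris: int
    n_gfp_neg: int
    n_gfp_pos: int

    def __post_init__(self) -> None:
        if self.n_debris + self.n_gfp_neg + self.n_gfp_pos != self.n_total:
            raise ValueError("event counts must partition the stream")

    @property
    def n_in_gate(self) -> int:
        return self.n_gfp_neg + self.n_gfp_pos

    @property
    def gfp_pos_fraction(self) -> float:
        return self.n_gfp_pos / self.n_in_gate


def simulate_events(
    n_events: int,
    populations: Mapping[str, Population],
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded draw of an event stream from a log-normal mixture.

    Returns a DataFrame (tof, gfp_height, truth_component); the truth column
    is the hidden component identity, for testing only.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    names = list(populations)
    weights = np.array([populations[k].weight for k in names], dtype=float)
    if (weights < 0).any() or not math.isclose(weights.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"mixture weights must be non-negative and sum to 1, got {weights}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(names), size=n_events, p=weights / weights.sum())
    tof = np.empty(n_events)
    gfp = np.empty(n_events)
    for i, name in enumerate(names):
        pop = populations[name]
        m = comp == i
        k = int(m.sum())
        if k == 0:
            continue
        tof[m] = rng.lognormal(pop.tof_meanlog, pop.tof_sdlog, size=k)
        gfp[m] = rng.lognormal(pop.gfp_meanlog, pop.gfp_sdlog, size=k)
    return pd.DataFrame(
        {
            "tof": tof,
            "gfp_height": gfp,
            "truth_component": np.array(names, dtype=object)[comp],
        }
    )


def _in_gate(events: pd.DataFrame, gate: GateConfig) -> np.ndarray:
    lo, hi = gate.tof_window
    tof = events["tof"].to_numpy(dtype=float)
    return (tof >= lo) & (tof <= hi)


def calibrate_threshold(
    control_events: pd.DataFrame,
    gate: GateConfig,
    min_events: int = 100,
) -> GateConfig:
    """Set the GFP+ threshold from an untreated control stream.

    The threshold is the empirical ``control_quantile`` (linear interpolation
    between order statistics) of GFP heights among in-gate control events.
    """
    heights = control_events.loc[_in_gate(control_events, gate), "gfp_height"].to_numpy(dtype=float)
    if heights.size < min_events:
        raise ValueError(
            f"calibration needs >= {min_events} in-gate control events, got {heights.size}"
        )
    thr = float(np.quantile(heights, gate.control_quantile, method="linear"))
    return replace(gate, threshold=thr)


def classify_events(events: pd.DataFrame, gate: GateConfig) -> EventCounts:
    """Partition a stream into debris / GFP- / GFP+ using a calibrated gate."""
    if gate.threshold is None:
        raise ValueError("gate is not calibrated: threshold unset")
    in_gate = _in_gate(events, gate)
    gfp = events["gfp_height"].to_numpy(dtype=float)
    pos = in_gate & (gfp > gate.threshold)
    neg = in_gate & ~pos
    return EventCounts(
        n_total=int(len(events)),
        n_debris=int((~in_gate).sum()),
        n_gfp_neg=int(neg.sum()),
        n_gfp_pos=int(pos.sum()),
    )


def fold_induction(
    treated: EventCounts, control: EventCounts, pseudo: float = 0.5
) -> float:
    """Ratio of GFP+ in-gate fractions, treated over control.

    A Haldane-style pseudo-count (applied to both streams' counts) kicks in
    only when either GFP+ count is zero, keeping the ratio finite for
    rare-event control streams.
    """
    if control.n_in_gate == 0:
        raise ValueError("fold induction undefined: no in-gate control events")
    if treated.n_in_gate == 0:
        raise ValueError("fold induction undefined: no in-gate treated events")
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    if pseudo > 0 and (treated.n_gfp_pos == 0 or control.n_gfp_pos == 0):
        ft = (treated.n_gfp_pos + pseudo) / (treated.n_in_gate + 2.0 * pseudo)
        fc = (control.n_gfp_pos + pseudo) / (control.n_in_gate + 2.0 * pseudo)
    else:
        if control.n_gfp_pos == 0:
            raise ValueError("fold induction undefined: zero control GFP+ count and zero pseudo")
        ft = treated.gfp_pos_fraction
        fc = control.gfp_pos_fraction
    return ft / fc
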
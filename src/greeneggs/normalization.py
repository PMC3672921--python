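"""Turn raw screen counts into the assay readout.

The screen's readout per compound and exposure duration is the log fold
ratio of GFP+ embryo incidence over the matched DMSO control.  Incidence
is GFP+ embryos per total embryo, which corrects the per-worm GFP+ count
for the average number of embryos per worm and thereby for reduced embryo
production in affected broods.  Embryonic viability (larvae hatched per
egg laid) is computed here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "AssayRecord",
    "NormalizedScore",
    "ViabilityResult",
    "gfp_incidence",
    "log_fold_ratio",
    "normalize_table",
    "embryonic_viability",
]

#: columns an assay table must carry
ASSAY_COLUMNS = [
    "compound",
    "time_point",
    "replicate",
    "plate",
    "n_worms",
    "n_embryos",
    "n_gfp_pos",
]


@dataclass(frozen=True)
class AssayRecord:
    """Raw counts for one compound x time point x replicate well."""

    compound: str
    time_point: str
    replicate: int
    plate: str
    n_worms: int
    n_embryos: int
    n_gfp_pos: int

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError(f"n_worms must be >= 1, got {self.n_worms}")
        if not 0 <= self.n_gfp_pos <= self.n_embryos:
            raise ValueError(
                f"need 0 <= n_gfp_pos <= n_embryos, got "
                f"n_gfp_pos={self.n_gfp_pos}, n_embryos={self.n_embryos}"
            )


@dataclass(frozen=True)
class NormalizedScore:
    """Log fold ratio of a compound's GFP+ incidence over DMSO."""

    compound: str
    time_point: str
    score: float
    n_replicates_used: int


@dataclass(frozen=True)
class ViabilityResult:
    eggs_laid: int
    larvae_hatched: int
    viability: float
    percent_change_vs_control: Optional[float] = None


def gfp_incidence(
    record: Union[AssayRecord, tuple],
    pseudo: float = 0.0,
) -> float:
    """GFP+ embryos per embryo, with an optional symmetric pseudo-count.

    Accepts an :class:`AssayRecord` or a ``(n_gfp_pos, n_embryos)`` pair.
    Returns ``(n_gfp_pos + pseudo) / (n_embryos + 2 * pseudo)``.
    """
    if isinstance(record, AssayRecord):
        g, e = record.n_gfp_pos, record.n_embryos
    else:
        g, e = record
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    if e == 0 and pseudo == 0:
        raise ValueError("incidence undefined: zero embryos and zero pseudo-count")
    return (g + pseudo) / (e + 2.0 * pseudo)


def _pooled_counts(records: Iterable[AssayRecord]) -> tuple[int, int, int]:
    g = e = n = 0
    for r in records:
        g += r.n_gfp_pos
        e += r.n_embryos
        n += 1
    return g, e, n


def log_fold_ratio(
    treated: Sequence[AssayRecord],
    control: Sequence[AssayRecord],
    base: float = 2.0,
    pseudo: float = 0.5,
) -> NormalizedScore:
    """Log fold ratio of pooled treated incidence over pooled control incidence.

    Replicates are pooled by summing counts before taking the ratio; rare-event
    per-replicate ratios are too unstable to average.  The Haldane-style
    pseudo-count ``pseudo`` is applied symmetrically to both groups only when
    either pooled GFP+ count is zero, keeping the score finite at the rare-event
    baseline without biasing typical wells.

    Parameters
    ----------
    base : log base of the score; 2 by default so a score of 1 means a
        two-fold induction over DMSO.
    """
    if base <= 1:
        raise ValueError("log base must be > 1")
    if not control:
        raise ValueError("control collection is empty: no matched DMSO records")
    if not treated:
        raise ValueError("treated collection is empty")
    gt, et, nt = _pooled_counts(treated)
    gc, ec, _ = _pooled_counts(control)
    eff = pseudo if (gt == 0 or gc == 0) else 0.0
    score = math.log(
        gfp_incidence((gt, et), eff) / gfp_incidence((gc, ec), eff), base
    )
    first = treated[0]
    return NormalizedScore(
        compound=first.compound,
        time_point=first.time_point,
        score=score,
        n_replicates_used=nt,
    )


def _records_from_frame(df: pd.DataFrame) -> list[AssayRecord]:
    return [
        AssayRecord(
            compound=str(r.compound),
            time_point=str(r.time_point),
            replicate=int(r.replicate),
            plate=str(r.plate),
            n_worms=int(r.n_worms),
            n_embryos=int(r.n_embryos),
            n_gfp_pos=int(r.n_gfp_pos),
        )
        for r in df.itertuples(index=False)
    ]


def normalize_table(
    assay: pd.DataFrame,
    control_label: str = "DMSO",
    base: float = 2.0,
    pseudo: float = 0.5,
    pooling: str = "sum",
    control_matching: str = "plate",
) -> pd.DataFrame:
    """Score every non-control compound at every time point against DMSO.

    Parameters
    ----------
    assay : table with :data:`ASSAY_COLUMNS`.
    pooling : ``"sum"`` pools counts across replicates before the ratio
        (default); ``"mean"`` averages per-replicate log ratios, provided for
        sensitivity analysis.
    control_matching : ``"plate"`` pairs each treated record with the control
        records of its own plate (every plate ran a DMSO well); ``"global"``
        pools all control records at the same time point.

    Returns
    -------
    DataFrame with columns compound, time_point, score, n_replicates_used.
    """
    if pooling not in ("sum", "mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    if control_matching not in ("plate", "global"):
        raise ValueError(f"unknown control matching mode {control_matching!r}")
    missing = [c for c in ASSAY_COLUMNS if c not in assay.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")

    controls = assay[assay["compound"] == control_label]
    treated_all = assay[assay["compound"] != control_label]
    rows = []
    for (compound, tp), grp in treated_all.groupby(["compound", "time_point"], sort=True):
        ctl_tp = controls[controls["time_point"] == tp]
        if control_matching == "plate":
            ctl_tp = ctl_tp[ctl_tp["plate"].isin(set(grp["plate"]))]
        if ctl_tp.empty:
            raise ValueError(
                f"no matched {control_label!r} control for compound "
                f"{compound!r} at time point {tp!r} "
                f"(plates {sorted(set(grp['plate']))})"
            )
        trec = _records_from_frame(grp)
        crec = _records_from_frame(ctl_tp)
        if pooling == "sum":
            ns = log_fold_ratio(trec, crec, base=base, pseudo=pseudo)
            score, nrep = ns.score, ns.n_replicates_used
        else:
            per_rep = []
            for r in trec:
                ctl_r = [c for c in crec if c.plate == r.plate] or crec
                per_rep.append(log_fold_ratio([r], ctl_r, base=base, pseudo=pseudo).score)
            score, nrep = float(pd.Series(per_rep).mean()), len(per_rep)
        rows.append(
            {
                "compound": compound,
                "time_point": tp,
                "score": score,
                "n_replicates_used": nrep,
            }
        )
    return pd.DataFrame(rows, columns=["compound", "time_point", "score", "n_replicates_used"])


def embryonic_viability(
    eggs_laid: int,
    larvae_hatched: int,
    control_viability: Optional[float] = None,
) -> ViabilityResult:
    """Hatching success, optionally as a signed percent change vs control."""
    if eggs_laid == 0:
        raise ValueError("viability undefined: zero eggs laid")
    if not 0 <= larvae_hatched <= eggs_laid:
        raise ValueError("need 0 <= larvae_hatched <= eggs_laid")
    v = larvae_hatched / eggs_laid
    change = None
    if control_viability is not None:
        if control_viability <= 0:
            raise ValueError("control viability must be positive")
        change = 100.0 * (v / control_viability - 1.0)
    return ViabilityResult(eggs_laid, larvae_hatched, v, change)
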
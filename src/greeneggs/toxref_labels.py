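"""Binary and three-way reproductive-toxicity labels from mammalian endpoints.

A compound is a positive reproductive toxicant when any multigenerational
endpoint shows a lowest effect level (MG-LEL) at or below a dose threshold
(500 mg/kg/day by default); compounds with endpoint records but none in
range are negatives; compounds with no records at all are excluded, never
imputed negative.  Counting positive endpoints per compound gives the
three-way category: none (0), intermediate (1), high (>= 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "EndpointRecord",
    "dichotomize",
    "categorize",
    "binary_labels",
]

ENDPOINT_COLUMNS = ["compound", "endpoint", "mg_lel"]

LABEL_COLUMNS = [
    "compound",
    "binary_label",
    "n_positive_endpoints",
    "category",
    "excluded",
]


@dataclass(frozen=True)
class EndpointRecord:
    """One compound x endpoint lowest-effect-level observation.

    ``mg_lel`` is the lowest dose (mg/kg/day) at which the endpoint was
    affected in a multigenerational study, or None when the endpoint was
    never called for the compound.
    """

    compound: str
    endpoint: str
    mg_lel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mg_lel is not None:
            if not math.isfinite(self.mg_lel) or self.mg_lel <= 0:
                raise ValueError(
                    f"mg_lel must be a positive finite dose, got {self.mg_lel}"
                )


def _as_frame(records: Union[pd.DataFrame, Iterable[EndpointRecord]]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in ENDPOINT_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"endpoint table missing columns: {missing}")
        return records
    return pd.DataFrame(
        [(r.compound, r.endpoint, r.mg_lel) for r in records],
        columns=ENDPOINT_COLUMNS,
    )


def dichotomize(
    records: Union[pd.DataFrame, Iterable[EndpointRecord]],
    threshold: float = 500.0,
    compounds: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-compound binary labels from MG-LEL endpoint records.

    A compound is positive iff any of its endpoints has ``mg_lel <= threshold``
    (the boundary dose itself counts as positive).  ``compounds`` optionally
    names the full screened panel; panel members without any endpoint record
    are returned with ``excluded=True`` and a missing binary label.

    Returns a label table with :data:`LABEL_COLUMNS`; the ``category`` column
    is filled by :func:`categorize`.
    """
    if not math.isfinite(threshold) or threshold <= 0:
        raise ValueError(f"dose threshold must be positive and finite, got {threshold}")
    df = _as_frame(records)
    rows = []
    seen = set()
    for compound, grp in df.groupby("compound", sort=True):
        seen.add(compound)
        lel = pd.to_numeric(grp["mg_lel"], errors="coerce")
        n_pos = int((lel <= threshold).sum())
        rows.append(
            {
                "compound": compound,
                "binary_label": "positive" if n_pos > 0 else "negative",
                "n_positive_endpoints": n_pos,
                "category": None,
                "excluded": False,
            }
        )
    if compounds is not None:
        for compound in compounds:
            if compound not in seen:
                rows.append(
                    {
                        "compound": compound,
                        "binary_label": None,
                        "n_positive_endpoints": 0,
                        "category": None,
                        "excluded": True,
                    }
                )
    labels = pd.DataFrame(rows, columns=LABEL_COLUMNS).sort_values("compound")
    return categorize(labels.reset_index(drop=True))


def categorize(labels: pd.DataFrame) -> pd.DataFrame:
    """Fill the three-way reproductive-toxicity category.

    Mapping on positive-endpoint counts: 0 -> none, 1 -> intermediate,
    >= 2 -> high.  Excluded compounds keep a missing category.  The mapping
    partitions every non-excluded compound.
    """
    out = labels.copy()
    def _cat(row):
        if row["excluded"]:
            return None
        n = row["n_positive_endpoints"]
        if n == 0:
            return "none"
        if n == 1:
            return "intermediate"
        return "high"
    out["category"] = out.apply(_cat, axis=1)
    return out


def binary_labels(labels: pd.DataFrame) -> pd.Series:
    """Boolean positive/negative series over non-excluded compounds."""
    kept = labels[~labels["excluded"].astype(bool)]
    return pd.Series(
        (kept["binary_label"] == "positive").to_numpy(),
        index=kept["compound"].to_numpy(),
        name="label",
    )
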
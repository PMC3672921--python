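"""Flat-file formats for the pipeline.

Everything is CSV: UTF-8, comma-separated, header row, dot decimal, empty
cell = missing.  Readers validate rows and report offenders by line number
(header = line 1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .normalization import ASSAY_COLUMNS
from .toxref_labels import ENDPOINT_COLUMNS

log = logging.getLogger("greeneggs")

SCORE_COLUMNS = ["compound", "time_point", "score", "n_replicates_used"]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns: list[str], path: PathLike) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_assay_csv(path: PathLike) -> pd.DataFrame:
    """Read and validate a raw assay count table."""
    df = pd.read_csv(path)
    _require_columns(df, ASSAY_COLUMNS, path)
    if df.empty:
        log.warning("%s: empty assay table", path)
        return df
    problems = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.n_embryos) or pd.isna(row.n_gfp_pos) or pd.isna(row.n_worms):
            problems.append(f"line {pos}: missing count")
        elif row.n_gfp_pos > row.n_embryos:
            problems.append(
                f"line {pos}: n_gfp_pos={row.n_gfp_pos} exceeds n_embryos={row.n_embryos}"
            )
        elif row.n_worms < 1 or row.n_embryos < 0 or row.n_gfp_pos < 0:
            problems.append(f"line {pos}: negative or zero-worm counts")
    if problems:
        raise ValueError(f"{path}: invalid assay rows:\n" + "\n".join(problems))
    for col in ("replicate", "n_worms", "n_embryos", "n_gfp_pos"):
        df[col] = df[col].astype(int)
    log.info("%s: read %d assay records", path, len(df))
    return df


def read_endpoint_csv(path: PathLike) -> pd.DataFrame:
    """Read an endpoint LEL table; empty mg_lel cells mean absent."""
    df = pd.read_csv(path)
    _require_columns(df, ENDPOINT_COLUMNS, path)
    bad = df.index[pd.to_numeric(df["mg_lel"], errors="coerce").le(0)].tolist()
    if bad:
        lines = ", ".join(str(i + 2) for i in bad)
        raise ValueError(f"{path}: non-positive mg_lel on lines {lines}")
    log.info("%s: read %d endpoint records", path, len(df))
    return df


def read_scores_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SCORE_COLUMNS[:3], path)
    return df


def read_events_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["tof", "gfp_height"], path)
    if (df["tof"] <= 0).any():
        raise ValueError(f"{path}: time-of-flight must be positive")
    return df


def write_csv(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    log.info("%s: wrote %d rows", path, len(df))
    return path
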
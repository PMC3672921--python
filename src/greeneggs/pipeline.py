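"""End-to-end orchestration: counts -> scores -> labels -> predictivity.

``run_pipeline`` ties the stages together deterministically: read (or
simulate) the assay and endpoint tables, normalize to log fold ratios over
DMSO, dichotomize and categorize the mammalian endpoints, sweep the
positivity cutoff per time point, maximize per-endpoint relative risks in
the configured cutoff range, and run the cross-category Mann-Whitney
comparison.  A manifest records the configuration, seed, package version
and input checksums so every artifact is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd

from . import __version__
from .group_stats import compare_categories
from .io import read_assay_csv, read_endpoint_csv, write_csv
from .normalization import normalize_table
from .predictivity import SweepResult, endpoint_rr_table, sweep
from .synthetic_screen import (
    EndpointSimConfig,
    ScreenSimConfig,
    simulate_endpoints,
    simulate_screen,
)
from .toxref_labels import binary_labels, dichotomize

log = logging.getLogger("greeneggs")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible pipeline run.

    Either CSV paths (``assay_path``/``endpoint_path``) or simulator configs
    supply the inputs; paths win when both are set.
    """

    assay_path: Optional[str] = None
    endpoint_path: Optional[str] = None
    screen_sim: Optional[ScreenSimConfig] = None
    endpoint_sim: Optional[EndpointSimConfig] = None
    log_base: float = 2.0
    pseudo: float = 0.5
    dichotomization_threshold: float = 500.0
    cutoff_range: Tuple[float, float] = (1.0, 2.0)
    z: float = 1.96
    control_label: str = "DMSO"
    positive_control_label: str = "nocodazole"
    seed: int = 0
    outdir: Optional[str] = None


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    labels: pd.DataFrame
    sweeps: dict[str, SweepResult]
    rr_table: pd.DataFrame
    comparisons: dict[str, dict]
    manifest: dict


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain; optionally write the result bundle.

    Outputs (when ``config.outdir`` is set): scores.csv, labels.csv,
    sweep_<tp>.csv, rr.csv, summary.json, comparisons.json, manifest.json.
    """
    checksums = {}
    if config.assay_path:
        assay = read_assay_csv(config.assay_path)
        checksums["assay"] = _sha256(config.assay_path)
    else:
        sim = config.screen_sim or ScreenSimConfig(seed=config.seed)
        assay, truth = simulate_screen(sim)
        log.info("simulated screen: %d assay records", len(assay))
    if config.endpoint_path:
        endpoints = read_endpoint_csv(config.endpoint_path)
        checksums["endpoints"] = _sha256(config.endpoint_path)
    else:
        if config.assay_path:
            raise ValueError("endpoint_path required when assay comes from a file")
        esim = config.endpoint_sim or EndpointSimConfig(seed=config.seed + 1)
        endpoints = simulate_endpoints(truth, esim)
        log.info("simulated endpoints: %d records", len(endpoints))

    test_mask = ~assay["compound"].isin([config.control_label, config.positive_control_label])
    panel = sorted(assay.loc[test_mask, "compound"].unique())

    scores = normalize_table(
        assay[test_mask | (assay["compound"] == config.control_label)],
        control_label=config.control_label,
        base=config.log_base,
        pseudo=config.pseudo,
    )
    labels = dichotomize(
        endpoints, threshold=config.dichotomization_threshold, compounds=panel
    )
    n_excluded = int(labels["excluded"].sum())
    log.info(
        "labels: %d compounds (%d positive, %d excluded)",
        len(labels),
        int((labels["binary_label"] == "positive").sum()),
        n_excluded,
    )

    lab = binary_labels(labels)
    sweeps: dict[str, SweepResult] = {}
    for tp, grp in scores.groupby("time_point", sort=True):
        s = pd.Series(grp["score"].to_numpy(), index=grp["compound"].to_numpy())
        s = s[s.index.isin(lab.index)]
        sweeps[str(tp)] = sweep(s, lab, time_point=str(tp))
        log.info(
            "sweep %s: best balanced accuracy %.3f at cutoff %.3f",
            tp,
            sweeps[str(tp)].best_balanced_accuracy,
            sweeps[str(tp)].best_cutoff,
        )

    rr = endpoint_rr_table(
        scores,
        endpoints,
        threshold=config.dichotomization_threshold,
        cutoff_range=config.cutoff_range,
        z=config.z,
    )

    comparisons: dict[str, dict] = {}
    for tp in sweeps:
        try:
            cmp_ = compare_categories(scores, labels, "reprotox_vs_none", time_point=tp)
        except ValueError as err:
            log.warning("comparison skipped at %s: %s", tp, err)
            continue
        comparisons[tp] = {
            "grouping": "reprotox_vs_none",
            "U": cmp_.u_statistic,
            "p_value": cmp_.p_value,
            "method": cmp_.method,
            "n_a": cmp_.n_a,
            "n_b": cmp_.n_b,
        }

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "input_checksums": checksums,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_compounds": len(panel),
        "n_excluded": n_excluded,
    }

    result = PipelineResult(scores, labels, sweeps, rr, comparisons, manifest)
    if config.outdir:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(result.scores, outdir / "scores.csv")
    write_csv(result.labels, outdir / "labels.csv")
    summary = {}
    for tp, sw in result.sweeps.items():
        write_csv(sw.table, outdir / f"sweep_{tp}.csv")
        best = sw.table.loc[sw.table["cutoff"] == sw.best_cutoff].iloc[0]
        summary[tp] = {
            "best_cutoff": sw.best_cutoff,
            "best_balanced_accuracy": sw.best_balanced_accuracy,
            "sensitivity": float(best["sensitivity"]),
            "specificity": float(best["specificity"]),
        }
    write_csv(result.rr_table, outdir / "rr.csv")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (outdir / "comparisons.json").write_text(json.dumps(result.comparisons, indent=2) + "\n")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str) + "\n"
    )
    log.info("wrote result bundle to %s", outdir)
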
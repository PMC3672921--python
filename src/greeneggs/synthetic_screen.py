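"""Synthetic green-eggs screen generator.

Emulates the statistical structure of the aneuploidy screen so the whole
analysis chain is testable without wet-lab data: ~47 compounds exposed for
24 h and 65 h in 24-well plates (one DMSO and one nocodazole well per
plate), 300 worms per well, a rare baseline GFP+ embryo rate (< 0.2%, the
natural XO male frequency), latent aneugenic effects that multiply that
rate on a log2-fold scale, fecundity suppression in aneugenic broods,
beta-binomial replicate overdispersion, and mammalian endpoint positivity
coupled to the latent effect through a logistic link.

Every draw flows from a single integer seed; identical configs give
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ScreenSimConfig",
    "EndpointSimConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_endpoints",
]

#: well layout: 24-well plates with one negative and one positive control well
WELLS_PER_PLATE = 24
TEST_WELLS_PER_PLATE = WELLS_PER_PLATE - 2
NEGATIVE_CONTROL = "DMSO"
POSITIVE_CONTROL = "nocodazole"
#: latent effect assigned to the nocodazole positive-control wells
#: (log2 of the ~3-fold induction it produces over DMSO)
POSITIVE_CONTROL_ALPHA = math.log2(3.0)

DEFAULT_ENDPOINTS = (
    "MGR_Rat_Fertility",
    "MGR_Rat_LitterSize",
    "MGR_Rat_Ovary",
    "MGR_Rat_ReproductiveOutcome",
    "MGR_Rat_ReproductivePerformance",
    "MGR_Rat_ViabilityPND4",
)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for the simulated screen.

    ``effect_log_mean``/``effect_log_sd`` locate the latent aneugenic effect
    alpha (log2-fold units) of aneugenic compounds; non-aneugenic compounds
    have alpha = 0 exactly.  ``overdispersion_rho`` is the beta-binomial
    intra-well correlation (0 recovers a pure binomial).
    """

    n_compounds: int = 47
    frac_aneugenic: float = 0.4
    effect_log_mean: float = 1.5
    effect_log_sd: float = 0.6
    baseline_gfp_rate: float = 0.002
    fecundity_mean: float = 12.0
    fecundity_suppression: float = 0.3
    overdispersion_rho: float = 0.05
    n_replicates: int = 3
    worms_per_well: int = 300
    time_points: Tuple[str, ...] = ("24h", "65h")
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_aneugenic", "baseline_gfp_rate"):
            v = getattr(self, name)
            _check(math.isfinite(v) and 0.0 <= v <= 1.0, f"{name} must lie in [0,1], got {v}")
        for name in ("fecundity_suppression", "overdispersion_rho"):
            v = getattr(self, name)
            _check(math.isfinite(v) and 0.0 <= v < 1.0, f"{name} must lie in [0,1), got {v}")
        _check(math.isfinite(self.effect_log_mean), "effect_log_mean must be finite")
        _check(
            math.isfinite(self.effect_log_sd) and self.effect_log_sd >= 0,
            "effect_log_sd must be finite and non-negative",
        )
        _check(
            math.isfinite(self.fecundity_mean) and self.fecundity_mean > 0,
            "fecundity_mean must be positive",
        )
        for name in ("n_compounds", "n_replicates", "worms_per_well"):
            _check(getattr(self, name) >= 1, f"{name} must be >= 1")
        _check(len(self.time_points) >= 1, "need at least one time point")


@dataclass(frozen=True)
class EndpointSimConfig:
    """Logistic coupling of mammalian endpoint positivity to the latent effect.

    P(endpoint positive | compound) = logistic(beta0 + beta1 * alpha).  A
    positive call receives a lowest effect level drawn uniformly from
    ``lel_grid`` (all within the positive dose range); otherwise the endpoint
    is absent for the compound.  ``missing_data_rate`` removes all endpoint
    records for a fraction of compounds, emulating compounds without any
    mammalian study data (to be excluded downstream, not called negative).
    """

    endpoint_names: Tuple[str, ...] = DEFAULT_ENDPOINTS
    intercept_beta0: float = -3.3
    slope_beta1: float = 1.2
    lel_grid: Tuple[float, ...] = (10.0, 50.0, 100.0, 250.0, 500.0)
    seed: int = 0
    missing_data_rate: float = 0.0

    def validate(self) -> None:
        _check(len(self.endpoint_names) > 0, "endpoint_names must be non-empty")
        _check(
            len(set(self.endpoint_names)) == len(self.endpoint_names),
            "endpoint_names must be unique",
        )
        _check(
            math.isfinite(self.intercept_beta0) and math.isfinite(self.slope_beta1),
            "logistic coefficients must be finite",
        )
        _check(len(self.lel_grid) > 0, "lel_grid must be non-empty")
        _check(all(v > 0 and math.isfinite(v) for v in self.lel_grid), "lel_grid doses must be positive")
        _check(0.0 <= self.missing_data_rate < 1.0, "missing_data_rate must lie in [0,1)")


@dataclass
class GroundTruth:
    """Hidden per-compound state behind a simulated screen.

    ``alpha`` is the compound's latent aneugenic effect at the longest
    exposure (the value the endpoint model couples to); ``alpha_by_time``
    and ``true_gfp_rate`` resolve it per time point (longer exposures
    capture a superset of germline stages, so effects are non-decreasing
    in exposure time).
    """

    compounds: Tuple[str, ...]
    alpha: pd.Series  # compound -> latent effect (log2-fold), 0 iff non-aneugenic
    alpha_by_time: pd.DataFrame  # compound x time point
    true_gfp_rate: pd.DataFrame  # compound x time point
    true_endpoint_status: Optional[pd.DataFrame] = None  # compound x endpoint bool

    def to_frame(self) -> pd.DataFrame:
        out = self.alpha_by_time.add_prefix("alpha_")
        out = out.join(self.true_gfp_rate.add_prefix("gfp_rate_"))
        out.insert(0, "alpha", self.alpha)
        out.insert(1, "aneugenic", self.alpha > 0)
        if self.true_endpoint_status is not None:
            out = out.join(self.true_endpoint_status.add_prefix("endpoint_"))
        out.index.name = "compound"
        return out


def _beta_binomial(rng: np.random.Generator, n: int, p: float, rho: float) -> int:
    """Beta-binomial draw with mean np and intra-well correlation rho."""
    if n == 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    if rho == 0.0:
        return int(rng.binomial(n, p))
    k = (1.0 - rho) / rho  # rho = 1 / (a + b + 1)
    q = rng.beta(p * k, (1.0 - p) * k)
    return int(rng.binomial(n, q))


def _true_rate(baseline: float, alpha: float) -> float:
    return min(baseline * 2.0**alpha, 0.5)


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a full assay table plus its hidden ground truth.

    Returns one record per compound x time point x replicate, laid out on
    24-well plates each carrying a DMSO and a nocodazole control well, plus
    those control records.  GFP+ counts are beta-binomial at rate
    ``min(baseline * 2**alpha, 0.5)``; total embryos are Poisson with the
    per-worm fecundity suppressed for aneugenic compounds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    compounds = tuple(f"cmpd{i + 1:03d}" for i in range(config.n_compounds))

    n_aneu = int(round(config.frac_aneugenic * config.n_compounds))
    aneu_idx = rng.choice(config.n_compounds, size=n_aneu, replace=False)
    aneugenic = np.zeros(config.n_compounds, dtype=bool)
    aneugenic[aneu_idx] = True

    # base latent effect at the shortest exposure: truncated-at-zero normal
    base_alpha = np.zeros(config.n_compounds)
    if n_aneu:
        draws = np.empty(n_aneu)
        need = np.ones(n_aneu, dtype=bool)
        while need.any():
            cand = rng.normal(config.effect_log_mean, config.effect_log_sd, size=int(need.sum()))
            ok = cand > 0
            idx = np.flatnonzero(need)[ok]
            draws[idx] = cand[ok]
            need[idx] = False
        base_alpha[aneu_idx] = draws

    # non-decreasing effect with exposure duration: longer exposures add a
    # half-normal increment (they capture additional germline stages)
    tps = tuple(config.time_points)
    alpha_by_time = pd.DataFrame(0.0, index=list(compounds), columns=list(tps))
    current = base_alpha.copy()
    for j, tp in enumerate(tps):
        if j > 0:
            incr = np.abs(rng.normal(0.0, 0.5 * config.effect_log_sd, size=config.n_compounds))
            current = current + np.where(aneugenic, incr, 0.0)
        alpha_by_time[tp] = current
    alpha = pd.Series(alpha_by_time[tps[-1]].to_numpy(), index=list(compounds), name="alpha")

    rate_by_time = (config.baseline_gfp_rate * 2.0**alpha_by_time).clip(upper=0.5)

    n_plates = math.ceil(config.n_compounds / TEST_WELLS_PER_PLATE)
    records = []
    for tp in tps:
        for rep in range(1, config.n_replicates + 1):
            for p in range(n_plates):
                plate = f"{tp}-r{rep}-p{p + 1}"
                members = compounds[p * TEST_WELLS_PER_PLATE : (p + 1) * TEST_WELLS_PER_PLATE]
                wells = [(NEGATIVE_CONTROL, 0.0), (POSITIVE_CONTROL, POSITIVE_CONTROL_ALPHA)]
                wells += [(c, float(alpha_by_time.loc[c, tp])) for c in members]
                for compound, a in wells:
                    # aneugenic exposure (incl. the nocodazole well) suppresses brood size
                    fec = config.fecundity_mean * (
                        1.0 - config.fecundity_suppression if a > 0 else 1.0
                    )
                    n_embryos = int(rng.poisson(config.worms_per_well * fec))
                    rate = _true_rate(config.baseline_gfp_rate, a)
                    n_gfp = _beta_binomial(rng, n_embryos, rate, config.overdispersion_rho)
                    records.append(
                        {
                            "compound": compound,
                            "time_point": tp,
                            "replicate": rep,
                            "plate": plate,
                            "n_worms": config.worms_per_well,
                            "n_embryos": n_embryos,
                            "n_gfp_pos": n_gfp,
                        }
                    )
    assay = pd.DataFrame.from_records(records)
    truth = GroundTruth(
        compounds=compounds,
        alpha=alpha,
        alpha_by_time=alpha_by_time,
        true_gfp_rate=rate_by_time,
    )
    return assay, truth


def simulate_endpoints(
    truth: GroundTruth, config: EndpointSimConfig
) -> pd.DataFrame:
    """Draw a mammalian endpoint LEL table coupled to the latent effects.

    Each compound x endpoint is positive with probability
    ``logistic(beta0 + beta1 * alpha)``; positives get a lowest effect level
    drawn from ``lel_grid``, negatives an absent (NaN) LEL.  Compounds hit by
    ``missing_data_rate`` contribute no rows at all.  Fills
    ``truth.true_endpoint_status`` as a side effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    compounds = list(truth.compounds)
    missing_alpha = [c for c in compounds if c not in truth.alpha.index]
    if missing_alpha:
        raise ValueError(f"ground truth lacks alpha for compounds: {missing_alpha}")
    alpha = truth.alpha.loc[compounds].to_numpy(dtype=float)
    endpoints = list(config.endpoint_names)
    p_pos = expit(config.intercept_beta0 + config.slope_beta1 * alpha)
    status = rng.random((len(compounds), len(endpoints))) < p_pos[:, None]
    has_data = rng.random(len(compounds)) >= config.missing_data_rate

    rows = []
    for i, compound in enumerate(compounds):
        if not has_data[i]:
            continue
        for j, ep in enumerate(endpoints):
            lel = float(rng.choice(config.lel_grid)) if status[i, j] else np.nan
            rows.append({"compound": compound, "endpoint": ep, "mg_lel": lel})
    truth.true_endpoint_status = pd.DataFrame(status, index=compounds, columns=endpoints)
    return pd.DataFrame(rows, columns=["compound", "endpoint", "mg_lel"])
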
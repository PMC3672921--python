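# Methods

This note documents the models, defaults, and numerical choices behind
`greeneggs`, and what the synthetic-data generator does and does not emulate.

## Score model

The screen's readout is the GFP⁺-embryo incidence — GFP⁺ embryos per total
embryo — expressed as a log fold ratio over the DMSO control. Working per
embryo rather than per worm corrects for reduced embryo production in
affected broods, which would otherwise deflate per-worm GFP⁺ counts.

Two conventions required a decision:

- **Log base.** Scores use log2 by default (configurable via `base`). Under
  base 2 the customary cutoff window of 1–2 corresponds to 2–4-fold
  inductions, which sits consistently with a ~3-fold induction from the
  nocodazole positive control being a strong hit.
- **Pooling.** Replicates are pooled by summing counts before the ratio.
  At a baseline incidence of 0.002, per-replicate ratios involve single-digit
  counts and are wildly unstable; the pooled ratio is the maximum-likelihood
  rate ratio under a binomial model. A per-replicate `pooling="mean"` mode is
  provided for sensitivity analysis only.
- **Pseudo-count.** A Haldane-style 0.5 is added symmetrically to both
  groups' counts only when either pooled GFP⁺ count is zero. Applying it
  unconditionally would bias typical wells at so rare a baseline; applying it
  conditionally keeps every score finite.
- **Control matching.** Every plate carries a DMSO well, so controls are
  matched per plate by default (`control_matching="plate"`); a global mode
  pools all same-time-point controls.

## Labels

A compound is a positive reproductive toxicant iff **any** multigenerational
endpoint has a lowest effect level ≤ 500 mg/kg/day; the boundary value is
positive. Compounds whose records are all out of range are negatives;
compounds with no records are **excluded** from predictivity computations
rather than imputed negative. The three-way category maps positive-endpoint
counts {0, 1, ≥ 2} to {none, intermediate, high}; ≥ 2 (rather than > 2) for
"high" is the only reading under which the three categories partition all
labeled compounds, and is used throughout.

## Cutoff sweep

Metrics are step functions of the cutoff, so the grid of unique observed
scores plus one supremum sentinel (everything called negative) is exhaustive;
no continuous optimization is warranted. The positive call is `score ≥
cutoff` (ties inclusive), which makes the lowest grid point classify every
compound positive. Argmax ties in balanced accuracy break toward the
smaller cutoff, favouring sensitivity — the screening use case. The sweep
requires at least one positive and one negative label; balanced accuracy is
undefined otherwise and the call raises.

## Relative risk

`RR = [TP/(TP+FP)] / [FN/(FN+TN)]` is the risk of mammalian endpoint
positivity among assay-positives over assay-negatives. The 95% interval is
the Katz log-method CI — the standard 2×2 relative-risk interval — with
z = 1.96 and a 0.5 continuity correction added to all four cells (before
both the point estimate and the interval) when any cell is zero. The
orientation (risk of endpoint positivity given the assay call, not its
transpose) is fixed here; the maximization over in-range cutoffs breaks ties
toward the smaller cutoff and skips cutoffs where either margin is empty.
Endpoints enter the per-endpoint analysis when they have at least 2 positive
compounds (`min_positives`, configurable). No multiple-testing adjustment is
applied across endpoints; maxima are reported per endpoint as-is. Note that
a maximum over cutoffs is an optimistic, in-sample statistic; the CI is
conditional on the chosen cutoff and does not account for the selection.

## Mann–Whitney U

Exact permutation p-values are used for pooled samples of ≤ 20 observations
without ties (at these sizes enumeration is cheap and the normal
approximation is at its weakest); otherwise the normal approximation with
midrank tie correction and 0.5 continuity correction. Two-sided p is
`min(1, 2 · one-sided)`. The computation delegates to
`scipy.stats.mannwhitneyu` behind this module's method-selection contract,
and the test suite checks the exact branch against a full enumeration
oracle. No location confidence interval (e.g. Hodges–Lehmann) is computed:
the analysis chain consumes only p-values, and the interval definition that
would accompany them is not pinned down by the upstream protocol.

## Sorter gating

Events are (time-of-flight, GFP peak height) pairs. The size gate is a ToF
window (default 100–400 arbitrary units, configuration not inference — the
instrument window is a protocol choice); out-of-window events are debris.
The GFP⁺ threshold is the empirical `control_quantile` (default 0.998) of
in-gate heights from an untreated control stream, computed with linear
interpolation between order statistics (numpy's default quantile rule,
named in the config so any instrument dialect can be matched). The 99.8th
percentile anchors the in-gate false-positive rate to the < 0.2% natural
male frequency. Note the choice of calibration stream matters at the 0.2%
scale: a control containing its natural rare bright males puts the threshold
at the top of the GFP⁻ distribution (measured fractions ≈ true positive
fractions), while a male-free control leaves a `1 − quantile` false-positive
floor in every downstream measurement; fold inductions computed under the
latter compress toward 1.

## Synthetic-screen generator

The generator draws, per compound, a latent aneugenic effect α on the
log2-fold scale and produces count tables with the structure the analysis
assumes. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_compounds | 47 | labeled panel size |
| frac_aneugenic | 0.4 | ≈ 20/47 positives |
| effect_log_mean, sd | 1.5, 0.6 | puts aneugenic scores in the 1–2.3 band where informative cutoffs live |
| baseline_gfp_rate | 0.002 | natural XO male frequency (< 0.2%) |
| fecundity_mean | 12 embryos/worm | order of magnitude of an in-utero brood |
| fecundity_suppression | 0.3 | aneugenic exposures reduce embryo production |
| overdispersion_rho | 0.05 | beta-binomial intra-well correlation; 0 recovers pure binomial |
| n_replicates | 3 | replicate count of the environmental screen |
| worms_per_well | 300 | protocol well loading |
| endpoint coupling β0, β1 | −3.3, 1.2 | per-endpoint logistic rates whose any-of-6 union yields ≈ 20/47 positive compounds (non-aneugenic ≈ 0.20, aneugenic ≈ 0.7 compound-level positivity) |

Mechanics and choices:

- Aneugenic compounds (a fixed count, `round(frac · n)`) draw α from a
  normal truncated at zero; all others have α = 0 exactly. The 65-hr effect
  adds a half-normal increment to the 24-hr effect, so longer exposures are
  never weaker — they capture a superset of germline stages.
- The GFP⁺ rate is `min(baseline · 2^α, 0.5)`; the cap keeps rates valid at
  extreme effects (a him-8-scale ~30% male brood corresponds to α ≈ 7.2).
- GFP⁺ counts are beta-binomial with intra-well correlation ρ
  (`Beta(pk, (1−p)k)` mixing with `k = (1−ρ)/ρ`). At rare rates this mixing
  is extremely right-skewed: with ρ = 0.05 most wells draw an effectively
  zero rate and occasional wells a large one, so single-screen scores are
  very noisy. This is intentional realism pressure on the pipeline, and why
  oracle-style recovery tests run at ρ = 0, where the binomial sampling
  theory used in the assertions holds.
- Plates carry 22 test wells plus one DMSO and one nocodazole well; the
  positive control's latent effect is fixed at log2(3), the ~3-fold
  induction scale of a microtubule disruptor.
- Endpoint positivity is per endpoint, `logistic(β0 + β1·α)` with α the
  longest-exposure effect; positives draw an LEL uniformly from
  {10, 50, 100, 250, 500} mg/kg/day, negatives are absent. An optional
  `missing_data_rate` removes all records for a fraction of compounds to
  exercise the excluded-label path (the real panel had 7 such compounds).

What the generator does **not** emulate: dose–response structure (one
concentration per compound), lethality-driven dilutions, compound-specific
ADME/uptake differences, inter-plate batch effects, correlations between
endpoints beyond their shared dependence on α, and any relationship between
LEL magnitude and effect size. Passing tests therefore demonstrate that the
analysis chain is correct and well-calibrated under its own statistical
assumptions — not that those assumptions describe any particular wet-lab
dataset.

## Problem sizes in the test and acceptance runs

Statistical checks use sizes chosen for tight Monte-Carlo error at desk
scale: 500 random sweep instances (n ≤ 50) against a brute-force oracle;
2,000 simulated 2×2 tables for CI coverage and 10⁵ bootstrap resamples for
interval agreement (compared as relative difference of log-widths, the scale
on which the Katz interval is symmetric); exhaustive Mann–Whitney
enumeration for all pooled sizes ≤ 12; 200 seeded screens per recovery
regime; 200 five-thousand-event gating streams with 20k–100k-event
calibrations. The null-coupling recovery arm (β1 = 0) re-matches β0 so the
label marginal stays at ≈ 20/47 positives — removing the association while
holding the marginals, as in a permutation null; both recovery arms evaluate
the 65-hr time point, the one the endpoint model couples to.

## Known limitations

- Apparent (in-sample) accuracy only: the sweep optimizes and reports on the
  same compounds, as the upstream analysis does; no cross-validation.
- The reported per-endpoint RR maxima inherit selection optimism from the
  cutoff search (see above).
- The Katz CI is asymptotic; with the small cell counts typical at
  informative cutoffs its coverage is approximate and its width large.
- The ANOVA-with-post-test comparison used for per-compound apoptosis
  asterisks in follow-up assays is out of scope; only the Mann–Whitney
  contract is exposed.
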
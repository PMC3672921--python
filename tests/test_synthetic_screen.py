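"""Synthetic screen generator: rates, determinism, overdispersion, coupling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2

from greeneggs.synthetic_screen import (
    EndpointSimConfig,
    GroundTruth,
    ScreenSimConfig,
    simulate_endpoints,
    simulate_screen,
)


class TestSimulateScreen:
    def test_null_screen_sits_at_baseline(self):
        # no aneugenic compounds: pooled GFP+ fraction is binomial at baseline
        cfg = ScreenSimConfig(
            n_compounds=20, frac_aneugenic=0.0, overdispersion_rho=0.0, seed=3
        )
        assay, truth = simulate_screen(cfg)
        assert (truth.alpha == 0).all()
        test = assay[~assay["compound"].isin(["DMSO", "nocodazole"])]
        g, e = test["n_gfp_pos"].sum(), test["n_embryos"].sum()
        se = math.sqrt(0.002 * 0.998 / e)
        assert abs(g / e - 0.002) < 3 * se

    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = ScreenSimConfig(seed=17)
        a1, t1 = simulate_screen(cfg)
        a2, t2 = simulate_screen(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_series_equal(t1.alpha, t2.alpha)
        assert a1.to_csv() == a2.to_csv()

    def test_known_effect_recovers_closed_form_rate(self):
        # alpha = 4 over baseline 0.002 -> rate 0.032 = 0.002 * 2**4
        cfg = ScreenSimConfig(
            n_compounds=1, frac_aneugenic=1.0, effect_log_mean=4.0,
            effect_log_sd=1e-9, overdispersion_rho=0.0, fecundity_mean=60.0,
            n_replicates=2, time_points=("24h",), seed=9,
        )
        assay, truth = simulate_screen(cfg)
        assert truth.alpha.iloc[0] == pytest.approx(4.0, abs=1e-6)
        rows = assay[assay["compound"] == "cmpd001"]
        g, e = rows["n_gfp_pos"].sum(), rows["n_embryos"].sum()
        assert e > 1e4
        se = math.sqrt(0.032 * 0.968 / e)
        assert abs(g / e - 0.032) < 3 * se

    def test_plate_layout_carries_both_controls(self):
        assay, _ = simulate_screen(ScreenSimConfig(n_compounds=47, seed=1))
        for plate, grp in assay.groupby("plate"):
            names = set(grp["compound"])
            assert {"DMSO", "nocodazole"} <= names
            assert len(grp) <= 24

    def test_effects_nondecreasing_with_exposure_time(self):
        _, truth = simulate_screen(ScreenSimConfig(seed=5))
        assert (truth.alpha_by_time["65h"] >= truth.alpha_by_time["24h"] - 1e-12).all()
        # aneugenic compounds have alpha > 0, others exactly 0
        aneu = truth.alpha > 0
        assert aneu.sum() == round(0.4 * 47)
        assert (truth.alpha[~aneu] == 0.0).all()

    def test_fecundity_suppression_reduces_brood(self):
        cfg = ScreenSimConfig(
            n_compounds=30, frac_aneugenic=0.5, fecundity_suppression=0.5, seed=8
        )
        assay, truth = simulate_screen(cfg)
        aneu = set(truth.alpha.index[truth.alpha > 0])
        test = assay[~assay["compound"].isin(["DMSO", "nocodazole"])]
        mean_aneu = test[test["compound"].isin(aneu)]["n_embryos"].mean()
        mean_clean = test[~test["compound"].isin(aneu)]["n_embryos"].mean()
        assert mean_aneu < 0.6 * mean_clean

    def test_rate_cap_keeps_probabilities_valid(self):
        cfg = ScreenSimConfig(
            n_compounds=5, frac_aneugenic=1.0, effect_log_mean=12.0, seed=2
        )
        _, truth = simulate_screen(cfg)
        assert (truth.true_gfp_rate <= 0.5).all().all()
        assert (truth.true_gfp_rate >= 0).all().all()

    @pytest.mark.parametrize(
        "field, value",
        [
            ("frac_aneugenic", 1.5),
            ("baseline_gfp_rate", -0.1),
            ("overdispersion_rho", 1.0),
            ("fecundity_mean", 0.0),
            ("n_compounds", 0),
            ("effect_log_sd", float("nan")),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            simulate_screen(ScreenSimConfig(**{field: value}))

    def test_control_counts_binomially_consistent_across_seeds(self):
        # chi-square goodness of fit of pooled DMSO counts to the baseline
        # rate, aggregated over many seeds; rho=0 so the binomial model holds
        stat = 0.0
        dof = 0
        for seed in range(100):
            cfg = ScreenSimConfig(
                n_compounds=10, n_replicates=1, time_points=("24h",),
                overdispersion_rho=0.0, seed=seed,
            )
            assay, _ = simulate_screen(cfg)
            ctl = assay[assay["compound"] == "DMSO"]
            e = ctl["n_embryos"].sum()
            g = ctl["n_gfp_pos"].sum()
            mu = 0.002 * e
            stat += (g - mu) ** 2 / (mu * 0.998)
            dof += 1
        p = chi2.sf(stat, dof)
        assert p > 0.01

    def test_overdispersion_inflates_replicate_variance(self):
        # beta-binomial replicate fractions spread wider than binomial ones
        def rep_var(rho, seed):
            cfg = ScreenSimConfig(
                n_compounds=2, frac_aneugenic=1.0, effect_log_mean=5.0,
                effect_log_sd=1e-9, n_replicates=50, time_points=("24h",),
                overdispersion_rho=rho, seed=seed,
            )
            assay, _ = simulate_screen(cfg)
            test = assay[~assay["compound"].isin(["DMSO", "nocodazole"])]
            frac = test["n_gfp_pos"] / test["n_embryos"]
            return float(frac.var())

        assert rep_var(0.1, 21) > 5 * rep_var(0.0, 22)


class TestSimulateEndpoints:
    def make_truth(self, alphas):
        names = tuple(f"c{i}" for i in range(len(alphas)))
        alpha = pd.Series(list(alphas), index=list(names), dtype=float, name="alpha")
        by_time = pd.DataFrame({"24h": alpha, "65h": alpha})
        return GroundTruth(
            compounds=names,
            alpha=alpha,
            alpha_by_time=by_time,
            true_gfp_rate=(0.002 * 2.0**by_time).clip(upper=0.5),
        )

    def test_no_association_rate_matches_logistic_intercept(self):
        truth = self.make_truth([0.0, 1.0, 2.0, 3.0] * 250)
        cfg = EndpointSimConfig(
            endpoint_names=("ep1",), intercept_beta0=-1.0, slope_beta1=0.0, seed=4
        )
        table = simulate_endpoints(truth, cfg)
        frac = table["mg_lel"].notna().mean()
        p = expit(-1.0)
        se = math.sqrt(p * (1 - p) / len(table))
        assert abs(frac - p) < 3 * se

    def test_separation_limit_marks_exactly_strong_effects(self):
        truth = self.make_truth([0.0, 0.2, 0.4, 0.8, 1.5, 3.0])
        cfg = EndpointSimConfig(
            endpoint_names=("ep1",), intercept_beta0=-25.0, slope_beta1=50.0, seed=6
        )
        table = simulate_endpoints(truth, cfg).set_index("compound")
        want = truth.alpha > 0.5
        got = table["mg_lel"].notna()
        assert (got == want.loc[got.index]).all()

    def test_logistic_rates_at_known_alphas(self):
        # alpha in {0, 2} with beta0=0, beta1=1: rates logistic(0)=0.5 and
        # logistic(2)~0.881 within 3 binomial SE at 1e4 draws each
        n = 10_000
        truth = self.make_truth([0.0] * n + [2.0] * n)
        cfg = EndpointSimConfig(
            endpoint_names=("ep1",), intercept_beta0=0.0, slope_beta1=1.0, seed=12
        )
        table = simulate_endpoints(truth, cfg).set_index("compound")
        pos = table["mg_lel"].notna()
        for alpha, p in [(0.0, 0.5), (2.0, expit(2.0))]:
            members = truth.alpha.index[truth.alpha == alpha]
            frac = pos.loc[members].mean()
            assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_lels_drawn_from_grid_and_within_positive_range(self):
        truth = self.make_truth([2.0] * 50)
        cfg = EndpointSimConfig(seed=3)
        table = simulate_endpoints(truth, cfg)
        drawn = table["mg_lel"].dropna()
        assert set(drawn).issubset(set(cfg.lel_grid))
        assert (drawn <= 500).all()

    def test_missing_data_rate_drops_whole_compounds(self):
        truth = self.make_truth([1.0] * 200)
        cfg = EndpointSimConfig(seed=5, missing_data_rate=0.3)
        table = simulate_endpoints(truth, cfg)
        present = table["compound"].nunique()
        assert 100 < present < 180  # ~0.7 * 200

    def test_determinism_and_truth_status_side_effect(self):
        truth = self.make_truth([0.0, 1.0, 2.0])
        cfg = EndpointSimConfig(seed=9)
        t1 = simulate_endpoints(truth, cfg)
        status = truth.true_endpoint_status.copy()
        t2 = simulate_endpoints(truth, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(status, truth.true_endpoint_status)

    def test_invalid_config_rejected(self):
        truth = self.make_truth([1.0])
        with pytest.raises(ValueError):
            simulate_endpoints(truth, EndpointSimConfig(endpoint_names=()))
        with pytest.raises(ValueError):
            simulate_endpoints(truth, EndpointSimConfig(endpoint_names=("a", "a")))
        with pytest.raises(ValueError):
            simulate_endpoints(truth, EndpointSimConfig(lel_grid=(-1.0,)))
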
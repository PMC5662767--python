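"""Mixture fitting, bimodality, responder fractions, threshold-CDF fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smoscreen import (
    IndeterminateResponseError,
    PopulationConfig,
    ThresholdModel,
    WellSummary,
    bimodality_decision,
    fit_mixture,
    fit_threshold_distribution,
    parse_medium_ratio,
    responder_fraction,
    saturation_dose,
    simulate_well,
    summarize_time_course,
)


def lognormal_mixture(rng, n, w_hi, mu_lo, mu_hi, sigma):
    hi = rng.random(n) < w_hi
    x = rng.normal(np.where(hi, mu_hi, mu_lo), sigma)
    return np.exp(x)


class TestFitMixture:
    def test_single_population_flags_degenerate_bimodal(self, rng):
        fl = np.exp(rng.normal(5.0, 0.3, 10_000))
        fit = fit_mixture(fl, k=2, seed=0)
        assert fit.degenerate_bimodal

    def test_recovers_minority_weight(self, rng):
        fl = lognormal_mixture(rng, 10_000, w_hi=0.7, mu_lo=4.0, mu_hi=5.6, sigma=0.4)
        fit = fit_mixture(fl, k=2, seed=0)
        assert fit.weights[0] == pytest.approx(0.3, abs=0.02)
        assert fit.converged

    def test_em_beats_grid_search_oracle(self, rng):
        # brute-force 20x20x11 grid over (mu_lo, mu_hi, weight) at a common
        # fixed scale must not outscore EM by more than 1e-3 log-likelihood
        fl = lognormal_mixture(rng, 60, w_hi=0.5, mu_lo=3.0, mu_hi=7.0, sigma=0.3)
        x = np.log(fl)
        fit = fit_mixture(fl, k=2, seed=0)

        sigma = 0.3
        mus = np.linspace(x.min(), x.max(), 20)
        best = -np.inf
        for mu1 in mus:
            for mu2 in mus:
                for w in np.linspace(0.0, 1.0, 11):
                    dens = w * stats.norm.pdf(x, mu2, sigma) + (1 - w) * stats.norm.pdf(
                        x, mu1, sigma
                    )
                    ll = np.sum(np.log(np.maximum(dens, 1e-300)))
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-3

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 50"):
            fit_mixture(np.exp(rng.normal(0, 1, 10)), k=2)

    def test_constant_data_degenerate_k1(self):
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_mixture(np.full(100, 7.5), k=2)
        assert fit.k == 1 and fit.degenerate_bimodal

    def test_weights_simplex_and_ordered_locations(self, rng):
        fl = lognormal_mixture(rng, 5000, 0.4, 4.0, 6.0, 0.3)
        fit = fit_mixture(fl, k=2, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.locations[0] < fit.locations[1]
        assert (fit.scales >= 1e-3).all()

    def test_deterministic_under_fixed_seed(self, rng):
        fl = lognormal_mixture(rng, 2000, 0.5, 4.0, 6.0, 0.4)
        a = fit_mixture(fl, k=2, seed=3, n_random_restarts=2)
        b = fit_mixture(fl, k=2, seed=3, n_random_restarts=2)
        assert np.array_equal(a.locations, b.locations)


class TestBimodalityDecision:
    def test_null_unimodal_rate(self):
        # single log-normal at n = 4000: type-I (bimodal) rate <= 5%
        calls = []
        for s in range(40):
            rng = np.random.default_rng(s)
            fl = np.exp(rng.normal(5.0, 0.35, 4000))
            calls.append(bimodality_decision(fl, seed=s)[0])
        assert calls.count("bimodal") <= 2

    def test_separated_mixture_called_bimodal(self):
        calls = []
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            fl = lognormal_mixture(rng, 4000, 0.5, 5.0, 7.8, 0.35)
            calls.append(bimodality_decision(fl, seed=s)[0])
        assert calls.count("bimodal") == 40

    def test_constant_data_unimodal(self):
        with pytest.warns(UserWarning):
            verdict, delta = bimodality_decision(np.full(200, 3.0))
        assert verdict == "unimodal"


class TestResponderFraction:
    def test_unstimulated_well_is_zero_with_own_reference(self, clean_config):
        table = simulate_well(clean_config, 0.0, seed=5)
        ref = fit_mixture(table.fl, k=1)
        assert responder_fraction(table.fl, reference_off=ref, seed=0) == 0.0

    def test_median_threshold_dose_near_half(self):
        cfg = PopulationConfig(n_events=10_000, debris_fraction=0.0, seed=0)
        table = simulate_well(cfg, float(np.exp(cfg.mu_theta)), seed=6)
        frac = responder_fraction(table.fl, seed=0)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_saturating_dose_near_one(self):
        cfg = PopulationConfig(n_events=10_000, debris_fraction=0.0, seed=0)
        ref = fit_mixture(simulate_well(cfg, 0.0, seed=7).fl, k=1)
        table = simulate_well(cfg, 1.0, seed=8)
        assert responder_fraction(table.fl, reference_off=ref, seed=0) >= 0.95

    def test_unimodal_without_reference_indeterminate(self, rng):
        fl = np.exp(rng.normal(5.0, 0.3, 4000))
        with pytest.raises(IndeterminateResponseError):
            responder_fraction(fl, seed=0)

    def test_mode_below_reference_not_called_responding(self, rng):
        ref = fit_mixture(np.exp(rng.normal(5.0, 0.3, 4000)), k=1)
        low = np.exp(rng.normal(2.0, 0.3, 4000))
        assert responder_fraction(low, reference_off=ref, seed=0) == 0.0

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(77)
        fl = lognormal_mixture(rng, 3000, 0.4, 4.0, 6.5, 0.3)
        a = responder_fraction(fl, seed=0)
        b = responder_fraction(scale * fl, seed=0)
        assert a == pytest.approx(b, abs=1e-6)


class TestThresholdFit:
    def test_exact_interpolation_limit(self):
        mu, sigma = np.log(0.05), 0.8
        doses = np.array([0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.6])
        fracs = stats.norm.cdf((np.log(doses) - mu) / sigma)
        series = [(d, f, 10_000) for d, f in zip(doses, fracs)]
        model = fit_threshold_distribution(series, n_boot=0)
        assert model.mu_theta_hat == pytest.approx(mu, abs=1e-4)
        assert model.sigma_theta_hat == pytest.approx(sigma, abs=1e-4)
        assert model.fit_rss < 1e-12

    def test_three_doses_insufficient(self):
        series = [(0.01, 0.1, 100), (0.05, 0.5, 100), (0.2, 0.9, 100)]
        with pytest.raises(ValueError, match="4 distinct"):
            fit_threshold_distribution(series)

    def test_all_zero_fractions_unidentifiable(self):
        series = [(d, 0.0, 100) for d in (0.01, 0.02, 0.05, 0.1)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_threshold_distribution(series)

    def test_bootstrap_ci_covers_truth_on_noisy_series(self):
        mu, sigma = np.log(0.05), 0.8
        rng = np.random.default_rng(3)
        doses = np.array([0.004, 0.008, 0.016, 0.03, 0.06, 0.12, 0.25, 0.5])
        n = 4000
        fracs = [
            rng.binomial(n, stats.norm.cdf((np.log(d) - mu) / sigma)) / n
            for d in doses
        ]
        model = fit_threshold_distribution(
            [(d, f, n) for d, f in zip(doses, fracs)], n_boot=200, seed=9
        )
        lo, hi = model.ci["mu_theta"]
        assert lo <= model.mu_theta_hat <= hi
        assert model.mu_theta_hat == pytest.approx(mu, rel=0.1)

    def test_end_to_end_recovery_single_run(self, control_gate):
        # one full pipeline pass: events -> gate -> mixture -> fractions -> fit
        from smoscreen import apply_gate, simulate_dilution_series

        cfg = PopulationConfig(n_events=10_000, debris_fraction=0.0, seed=0)
        doses = [0.005, 0.01, 0.02, 0.05, 0.1, 0.15, 0.25, 0.5]
        ref = fit_mixture(simulate_well(cfg, 0.0, seed=55).fl, k=1)
        series = []
        for table, d in zip(simulate_dilution_series(cfg, doses, seed=56), doses):
            g = apply_gate(table, control_gate)
            series.append(
                (d, responder_fraction(g.gated_events.fl, ref, seed=0), g.n_gated)
            )
        model = fit_threshold_distribution(series, n_boot=0)
        assert model.mu_theta_hat == pytest.approx(cfg.mu_theta, rel=0.1)
        assert model.sigma_theta_hat == pytest.approx(cfg.sigma_theta, rel=0.1)


class TestSaturationDose:
    def test_median_is_exp_mu(self):
        model = ThresholdModel(np.log(0.05), 0.8, [], 0.0)
        assert saturation_dose(model, 0.5) == pytest.approx(0.05)

    def test_matches_closed_form_quantile(self):
        model = ThresholdModel(np.log(0.05), 0.8, [], 0.0)
        expected = float(np.exp(np.log(0.05) + 0.8 * stats.norm.ppf(0.95)))
        assert saturation_dose(model, 0.95) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_level(self):
        model = ThresholdModel(np.log(0.1), 0.5, [], 0.0)
        assert saturation_dose(model, 0.95) > saturation_dose(model, 0.5)

    def test_level_bounds(self):
        model = ThresholdModel(0.0, 1.0, [], 0.0)
        with pytest.raises(ValueError):
            saturation_dose(model, 1.0)


def ws(median_fl, resp):
    return WellSummary("w", "sample", None, None, True, True, 100, median_fl, resp)


class TestTimeCourse:
    def test_sorted_output(self):
        table = summarize_time_course([(24.0, ws(900, 98)), (4.0, ws(200, 10))])
        assert table["time_h"].tolist() == [4.0, 24.0]

    def test_two_points_required(self):
        with pytest.raises(ValueError):
            summarize_time_course([(4.0, ws(200, 10))])


class TestMediumRatio:
    @pytest.mark.parametrize(
        "text,expected",
        [("1:1", 0.5), ("1:5", 1 / 6), ("1:100", 1 / 101), ("0.25", 0.25), ("0", 0.0)],
    )
    def test_parse(self, text, expected):
        assert parse_medium_ratio(text) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            parse_medium_ratio("-1:5")
        with pytest.raises(ValueError):
            parse_medium_ratio("1.5")
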
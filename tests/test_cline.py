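"""Cline model evaluation, likelihood, fitting, model selection, support
limits, neutral width and the concordance LRT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridzone.cline import (ClineData, ClineModel, cline_eval, cline_loglik,
                              concordance_test, fit_cline, neutral_cline_width,
                              select_cline_model, support_interval,
                              time_since_contact)
from hybridzone.simulate import simulate_clinal_counts

# AIC quadruples (null, I, II, III) of the ten published locus fits, with
# the lowest-AIC model selected for each
PUBLISHED_AIC_TABLE = {
    "FhATG6": ((104.387, 11.734, 15.031, 22.600), "I"),
    "FhATGB101": ((193.265, 99.297, 75.779, 67.566), "III"),
    "mtDNA": ((366.149, 38.951, 21.727, 29.046), "II"),
    "FhATG18": ((26.395, 21.223, 15.922, 24.875), "II"),
    "FhATG20": ((195.100, 68.824, 6.03, 37.43), "II"),
    "FhATG4": ((197.64, 24.630, 28.257, 34.347), "I"),
    "FhATG2": ((92.462, 32.921, 32.855, 32.919), "II"),
    "FhATGB128": ((242.700, 39.626, 24.446, 28.374), "II"),
    "FhCA-1": ((164.162, 18.286, 21.263, 26.942), "I"),
    "FhATG17": ((30.973, 30.254, 29.783, 38.029), "II"),
}


class _FakeFit:
    def __init__(self, aic):
        self.aic = aic


class TestClineEval:
    def test_midpoint_is_mean_of_ends(self):
        model = ClineModel(centre=1217.47, width=57.89, p_min=0.0, p_max=0.98)
        assert cline_eval(model, 1217.47) == pytest.approx(0.49)

    def test_limits(self):
        model = ClineModel(centre=0.0, width=10.0, p_min=0.0, p_max=1.0)
        assert cline_eval(model, -1e6) == pytest.approx(0.0, abs=1e-12)
        assert cline_eval(model, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_monotone_without_tails(self):
        model = ClineModel(centre=50.0, width=30.0, p_min=0.1, p_max=0.9)
        x = np.linspace(-100, 200, 400)
        p = cline_eval(model, x)
        assert np.all(np.diff(p) > 0)

    def test_tails_continuous_at_splice(self):
        model = ClineModel(centre=100.0, width=40.0, p_min=0.05, p_max=0.95,
                           delta_l=30.0, tau_l=0.4, delta_r=20.0, tau_r=0.6,
                           variant="III")
        for splice in (100.0 - 30.0, 100.0 + 20.0):
            lo = cline_eval(model, splice - 1e-9)
            hi = cline_eval(model, splice + 1e-9)
            assert lo == pytest.approx(hi, abs=1e-6)
        # tails decay toward the end frequencies
        assert cline_eval(model, -1e5) == pytest.approx(0.05, abs=1e-6)
        assert cline_eval(model, 1e5) == pytest.approx(0.95, abs=1e-6)

    def test_tail_slope_ratio(self):
        model = ClineModel(centre=0.0, width=40.0, p_min=0.0, p_max=1.0,
                           delta_l=25.0, tau_l=0.5, variant="III")
        x0 = -25.0
        eps = 1e-6
        slope_tail = (cline_eval(model, x0 - eps) - cline_eval(model, x0 - 3 * eps)) / (2 * eps)
        slope_sig = (cline_eval(model, x0 + 3 * eps) - cline_eval(model, x0 + eps)) / (2 * eps)
        assert slope_tail / slope_sig == pytest.approx(0.5, rel=1e-3)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            ClineModel(centre=0.0, width=0.0)


class TestClineLoglik:
    def _data(self):
        return ClineData(np.array([0.0, 50.0, 100.0]),
                         np.array([2.0, 10.0, 18.0]),
                         np.array([20.0, 20.0, 20.0]))

    def test_hand_summed_terms(self):
        data = self._data()
        model = ClineModel(centre=50.0, width=40.0, p_min=0.0, p_max=1.0)
        expected = 0.0
        for x, k, n in zip(data.distance_km, data.successes, data.totals):
            p = 0.5 * (1 + math.tanh(2 * (x - 50.0) / 40.0))
            p = min(max(p, 1e-9), 1 - 1e-9)
            expected += k * math.log(p) + (n - k) * math.log(1 - p)
        assert cline_loglik(model, data) == pytest.approx(expected, abs=1e-9)

    def test_flat_half_model(self):
        data = ClineData(np.array([0.0, 10.0]), np.array([5.0, 5.0]),
                         np.array([10.0, 10.0]))
        model = ClineModel(centre=0.0, width=1.0, p_min=0.5, p_max=0.5)
        assert cline_loglik(model, data) == pytest.approx(20 * math.log(0.5))

    def test_saturated_model_attains_binomial_maxima(self):
        from scipy import stats as sps
        data = self._data()
        # a steep cline passing exactly through the observed proportions
        # cannot beat the sum of per-site binomial log-pmf maxima
        best = sum(float(sps.binom.logpmf(k, n, k / n))
                   for k, n in zip(data.successes, data.totals))
        model = ClineModel(centre=50.0, width=100.0, p_min=0.1, p_max=0.9)
        logl = cline_loglik(model, data)
        const = sum(float(sps.binom.logpmf(k, n, 0.5) - k * math.log(0.5)
                          - (n - k) * math.log(0.5))
                    for k, n in zip(data.successes, data.totals))
        assert logl + const <= best + 1e-9


class TestFitCline:
    def test_monotone_data_orders_end_frequencies(self):
        data = ClineData(np.array([0, 25, 50, 75, 100.0]),
                         np.array([1, 5, 10, 15, 19.0]), np.full(5, 20.0))
        fit = fit_cline(data, variant="II", seed=0, compute_support=False)
        assert fit.model.p_max >= fit.model.p_min

    def test_recovers_generating_centre(self):
        true = ClineModel(centre=1200.0, width=60.0, p_min=0.0, p_max=1.0)
        sites = [(d, 100) for d in (0, 1145.77, 1186.03, 1208.94, 1228.41,
                                    1231.88, 1242.06, 1257.54, 1285.31,
                                    1357.23, 1363.41, 1393.09, 1631.0)]
        data = ClineData.from_frame(simulate_clinal_counts(true, sites, seed=10))
        fit = fit_cline(data, variant="II", seed=0, compute_support=False)
        assert abs(fit.model.centre - 1200.0) < 25.0
        assert fit.aic == pytest.approx(2 * 4 - 2 * fit.log_lik)

    def test_too_few_sites_error(self):
        data = ClineData(np.array([0.0, 1.0]), np.array([1.0, 9.0]),
                         np.array([10.0, 10.0]))
        with pytest.raises(ValueError):
            fit_cline(data, variant="II")

    def test_generating_variant_wins_aic_usually(self):
        true = ClineModel(centre=1220.0, width=80.0, p_min=0.02, p_max=0.98)
        sites = [(d, 500) for d in np.linspace(1000, 1500, 13)]
        wins = 0
        reps = 30
        for rep in range(reps):
            data = ClineData.from_frame(
                simulate_clinal_counts(true, sites, seed=100 + rep))
            fits = {v: fit_cline(data, variant=v, seed=rep,
                                 compute_support=False, n_starts=4,
                                 fixed={"p_min": 0.0, "p_max": 1.0}
                                 if v == "I" else None)
                    for v in ("null", "I", "II", "III")}
            if select_cline_model(fits) == "II":
                wins += 1
        assert wins >= 0.7 * reps


class TestModelSelection:
    @pytest.mark.parametrize("locus", sorted(PUBLISHED_AIC_TABLE))
    def test_reproduces_published_choices(self, locus):
        aics, expected = PUBLISHED_AIC_TABLE[locus]
        fits = dict(zip(("null", "I", "II", "III"), map(_FakeFit, aics)))
        assert select_cline_model(fits) == expected

    def test_tie_prefers_fewer_parameters(self):
        fits = {"II": _FakeFit(10.0), "III": _FakeFit(10.0)}
        assert select_cline_model(fits) == "II"

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            select_cline_model({})


class TestSupportInterval:
    def test_quadratic_closed_form(self):
        si = support_interval(lambda th: -(th - 3.0) ** 2, 3.0, (-100.0, 100.0))
        assert si.low == pytest.approx(3 - math.sqrt(2), abs=1e-5)
        assert si.high == pytest.approx(3 + math.sqrt(2), abs=1e-5)
        assert 3.0 in si

    def test_clipped_at_bounds_flagged(self):
        si = support_interval(lambda th: -0.001 * (th - 3.0) ** 2, 3.0, (0.0, 4.0))
        assert si.clipped_high and si.high == 4.0

    def test_profile_matches_bruteforce_grid(self):
        true = ClineModel(centre=50.0, width=30.0, p_min=0.0, p_max=1.0)
        sites = [(d, 60) for d in np.linspace(0, 100, 9)]
        data = ClineData.from_frame(simulate_clinal_counts(true, sites, seed=3))
        fit = fit_cline(data, variant="I", seed=0,
                        fixed={"p_min": 0.0, "p_max": 1.0},
                        support_params=("centre",))
        si = fit.support["centre"]
        from hybridzone.cline import profile_support, _model_from_vector

        def profile(c):
            from scipy.optimize import minimize_scalar
            res = minimize_scalar(
                lambda w: -cline_loglik(ClineModel(centre=c, width=w,
                                                   p_min=0.0, p_max=1.0), data),
                bounds=(1.0, 3000.0), method="bounded")
            return -res.fun
        lmax = profile(fit.model.centre)
        for endpoint in (si.low, si.high):
            grid = np.arange(endpoint - 0.05, endpoint + 0.05, 1e-3)
            vals = np.array([profile(c) for c in grid])
            inside = grid[vals >= lmax - 2.0]
            # the profile crossing lies within one grid step of the endpoint
            if endpoint == si.low:
                assert abs(inside.min() - endpoint) < 2e-3
            else:
                assert abs(inside.max() - endpoint) < 2e-3

    def test_interval_contains_mle(self):
        true = ClineModel(centre=40.0, width=25.0, p_min=0.0, p_max=1.0)
        sites = [(d, 50) for d in np.linspace(0, 100, 7)]
        data = ClineData.from_frame(simulate_clinal_counts(true, sites, seed=5))
        fit = fit_cline(data, variant="II", seed=0,
                        support_params=("centre", "width"))
        assert fit.model.centre in fit.support["centre"]
        assert fit.model.width in fit.support["width"]


class TestNeutralWidth:
    def test_reported_value(self):
        w = neutral_cline_width(T=15000, sigma=2.0)
        assert float(f"{w:.3g}") == 614.0

    def test_unit_case(self):
        assert neutral_cline_width(1, 1) == pytest.approx(math.sqrt(2 * math.pi))

    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    @given(T=st.floats(1e-3, 1e6), sigma=st.floats(1e-3, 1e3))
    def test_round_trip_inversion(self, T, sigma):
        assert time_since_contact(neutral_cline_width(T, sigma), sigma) == \
            pytest.approx(T, rel=1e-9)

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            neutral_cline_width(0, 1)
        with pytest.raises(ValueError):
            neutral_cline_width(100, -2)


class TestConcordance:
    def _datasets(self, centres, widths, seed, n=200):
        sites = [(d, n) for d in np.linspace(1000, 1500, 13)]
        out = []
        for i, (c, w) in enumerate(zip(centres, widths)):
            model = ClineModel(centre=c, width=w, p_min=0.02, p_max=0.98)
            out.append(ClineData.from_frame(
                simulate_clinal_counts(model, sites, seed=seed + i)))
        return out

    def test_single_locus_degenerate(self):
        data = self._datasets([1200], [80], seed=0)
        res = concordance_test(data, seed=0)
        assert res.degenerate and res.chi2 == 0.0 and res.df == 0

    def test_free_likelihood_dominates_constrained(self):
        data = self._datasets([1150, 1250, 1300], [60, 120, 200], seed=2)
        res = concordance_test(data, seed=0)
        assert res.log_lik_free >= res.log_lik_constrained - 1e-6
        assert res.df == 4

    def test_displaced_centres_detected(self):
        data = self._datasets([1100, 1400], [60, 60], seed=4)
        res = concordance_test(data, seed=0)
        assert res.p_value < 0.01

    def test_shared_cline_not_rejected_typically(self):
        data = self._datasets([1220, 1220, 1220], [90, 90, 90], seed=8)
        res = concordance_test(data, seed=0)
        assert res.p_value > 0.01
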
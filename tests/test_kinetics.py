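"""Equal-production binning, decay fits, fold declines, yield extrapolation."""

import numpy as np
import pytest

import phlux as px
from phlux.errors import FitError, InsufficientSignalError
from phlux.kinetics import RateSeries


def _series(times, cumulative, censored_prefix_end=-1):
    return px.ProductionSeries(
        well_id="A01", times=np.asarray(times, float),
        cumulative=np.asarray(cumulative, float), mode="acid",
        censored_prefix_end=censored_prefix_end,
    )


def _rates_from(times, rates):
    times = np.asarray(times, float)
    rates = np.asarray(rates, float)
    return RateSeries(
        bin_edges=np.arange(len(rates) + 1, dtype=float) * 1e-3,
        bin_mid_cumulative=(np.arange(len(rates)) + 0.5) * 1e-3,
        bin_mid_time=times,
        rate=rates,
        bin_width=1e-3,
    )


class TestBinRates:
    def test_linear_production_gives_constant_rates(self):
        t = np.arange(0.0, 50.0, 0.5)
        s = _series(t, 0.001 * t)
        rates = px.bin_rates(s, 0.001)
        np.testing.assert_allclose(rates.rate, 0.001, rtol=1e-12)
        assert rates.n_bins == 49

    def test_first_order_production_matches_instantaneous_rate(self):
        # P(t) = (r0/k)(1 - e^(-kt)); bin rates approximate r(t_mid)
        r0, k = 4e-4, 8e-3
        t = np.arange(0.0, 400.0, 0.05)
        s = _series(t, (r0 / k) * (1 - np.exp(-k * t)))
        rates = px.bin_rates(s, 0.001)
        analytic = r0 * np.exp(-k * rates.bin_mid_time[:20])
        np.testing.assert_allclose(rates.rate[:20], analytic, rtol=0.02)

    def test_entirely_censored_series_errors(self):
        t = np.arange(0.0, 10.0, 0.5)
        s = _series(t, 0.001 * t, censored_prefix_end=len(t) - 1)
        with pytest.raises(InsufficientSignalError):
            px.bin_rates(s)

    def test_sub_bin_span_errors(self):
        s = _series([0.0, 1.0, 2.0], [0.0, 1e-4, 2e-4])
        with pytest.raises(InsufficientSignalError, match="insufficient production"):
            px.bin_rates(s, 0.001)

    def test_sampling_density_invariance_for_noiseless_input(self):
        r0, k = 4e-4, 8e-3
        def build(dt):
            t = np.arange(0.0, 300.0, dt)
            return _series(t, (r0 / k) * (1 - np.exp(-k * t)))
        coarse = px.bin_rates(build(0.5), 0.001)
        fine = px.bin_rates(build(0.25), 0.001)
        n = min(coarse.n_bins, fine.n_bins)
        np.testing.assert_allclose(coarse.rate[:n], fine.rate[:n], rtol=0.005)

    def test_bins_start_after_censored_prefix(self):
        t = np.arange(0.0, 100.0, 0.5)
        c = 0.001 * t
        idx = 20
        rates = px.bin_rates(_series(t, c, censored_prefix_end=idx - 1), 0.001)
        assert rates.bin_edges[0] == pytest.approx(c[idx])


class TestFitDecay:
    def test_exact_first_order_recovery(self):
        t = np.arange(10.0, 101.0, 10.0)
        r0, k = 4e-4, 0.02
        fit = px.fit_decay(_rates_from(t, r0 * np.exp(-k * t)), 1, "time")
        assert fit.decay_constant_k == pytest.approx(k, rel=1e-12)
        assert fit.initial_rate_r0 == pytest.approx(r0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_second_order_recovery(self):
        t = np.arange(10.0, 101.0, 10.0)
        r0, k = 4e-4, 50.0
        fit = px.fit_decay(_rates_from(t, r0 / (1 + r0 * k * t)), 2, "time")
        assert fit.decay_constant_k == pytest.approx(k, rel=1e-9)
        assert fit.initial_rate_r0 == pytest.approx(r0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("true_order,wrong_order", [(1, 2), (2, 1)])
    def test_mismatched_order_has_lower_r_squared(self, true_order, wrong_order):
        t = np.arange(5.0, 200.0, 5.0)
        r0 = 4e-4
        if true_order == 1:
            # mild decline keeps the 1/rate transform fittable too
            rates = r0 * np.exp(-0.005 * t)
        else:
            rates = r0 / (1 + r0 * 80.0 * t)
        rs = _rates_from(t, rates)
        good = px.fit_decay(rs, true_order, "time")
        bad = px.fit_decay(rs, wrong_order, "time")
        assert good.r_squared == pytest.approx(1.0, abs=1e-9)
        assert bad.r_squared < good.r_squared - 1e-6

    def test_cumulative_product_axis(self):
        # first-order-in-cumulative decline: ln r linear in P
        P = np.arange(1.0, 11.0) * 1e-3
        r0, k = 4e-4, 120.0
        rs = RateSeries(
            bin_edges=np.arange(11.0) * 1e-3,
            bin_mid_cumulative=P,
            bin_mid_time=np.arange(10.0),
            rate=r0 * np.exp(-k * P),
            bin_width=1e-3,
        )
        fit = px.fit_decay(rs, 1, "cumulative_product")
        assert fit.decay_constant_k == pytest.approx(k, rel=1e-9)

    def test_nonpositive_rate_rejected_listing_bins(self):
        rs = _rates_from([1.0, 2.0, 3.0, 4.0], [1e-4, -1e-5, 2e-4, 1e-4])
        with pytest.raises(FitError, match=r"\[1\]"):
            px.fit_decay(rs, 1, "time")

    def test_too_few_bins_rejected(self):
        rs = _rates_from([1.0, 2.0], [1e-4, 9e-5])
        with pytest.raises(FitError, match="3"):
            px.fit_decay(rs, 1, "time")


class TestFoldDecline:
    def test_printed_rate_pair(self):
        assert px.fold_decline((3.98e-4, 2.51e-5)) == pytest.approx(15.86, abs=0.005)

    def test_constant_rate_is_one(self):
        rs = _rates_from([1.0, 2.0, 3.0], [1e-4, 1e-4, 1e-4])
        assert px.fold_decline(rs) == pytest.approx(1.0)

    def test_first_order_fit_closed_form(self):
        fit = px.DecayFit(
            order=1, x_variable="time", slope=-0.02, intercept=np.log(4e-4),
            initial_rate_r0=4e-4, decay_constant_k=0.02, r_squared=1.0, n_points=10,
        )
        assert px.fold_decline(fit, 0.0, 100.0) == pytest.approx(np.exp(2.0), rel=1e-12)

    def test_multiplicative_over_windows(self):
        fit = px.DecayFit(
            order=2, x_variable="time", slope=50.0, intercept=1 / 4e-4,
            initial_rate_r0=4e-4, decay_constant_k=50.0, r_squared=1.0, n_points=10,
        )
        ab = px.fold_decline(fit, 0.0, 40.0)
        bc = px.fold_decline(fit, 40.0, 90.0)
        ac = px.fold_decline(fit, 0.0, 90.0)
        assert ab * bc == pytest.approx(ac, rel=1e-9)

    def test_nonpositive_end_rate_rejected(self):
        with pytest.raises(FitError):
            px.fold_decline((1e-4, 0.0))


class TestExtrapolateYield:
    def _fit(self, order, r0, k):
        return px.DecayFit(
            order=order, x_variable="time", slope=0.0, intercept=0.0,
            initial_rate_r0=r0, decay_constant_k=k, r_squared=1.0, n_points=10,
        )

    def test_zero_decay_limit(self):
        y = px.extrapolate_yield(self._fit(1, 4e-4, 0.0), 50.0)
        assert y.amount == pytest.approx(4e-4 * 50.0, rel=1e-12)

    def test_large_horizon_approaches_asymptote(self):
        fit = self._fit(1, 4e-4, 0.01)
        y = px.extrapolate_yield(fit, 1e4)
        assert y.amount == pytest.approx(4e-4 / 0.01, rel=1e-3)
        assert y.asymptote == pytest.approx(4e-4 / 0.01, rel=1e-12)

    def test_two_month_yield_matches_numeric_integration(self):
        r0 = 3.98e-4
        k = np.log(15.86) / 336.0
        horizon = 1440.0  # two months
        y = px.extrapolate_yield(self._fit(1, r0, k), horizon)
        t = np.arange(0.0, horizon + 1e-9, 0.01)
        numeric = np.trapezoid(r0 * np.exp(-k * t), t)
        assert y.amount == pytest.approx(numeric, rel=1e-6)

    def test_second_order_matches_numeric_integration(self):
        r0, k = 4e-4, 300.0
        y = px.extrapolate_yield(self._fit(2, r0, k), 500.0)
        t = np.arange(0.0, 500.0 + 1e-9, 0.01)
        numeric = np.trapezoid(r0 / (1 + r0 * k * t), t)
        assert y.amount == pytest.approx(numeric, rel=1e-6)
        assert y.asymptote is None

    def test_monotone_and_bounded_by_asymptote(self):
        fit = self._fit(1, 4e-4, 0.01)
        amounts = [px.extrapolate_yield(fit, h).amount for h in (10, 100, 1000, 1e5)]
        assert amounts == sorted(amounts)
        assert all(a <= 4e-4 / 0.01 + 1e-15 for a in amounts)

    def test_cumulative_axis_fit_rejected(self):
        fit = px.DecayFit(
            order=1, x_variable="cumulative_product", slope=0.0, intercept=0.0,
            initial_rate_r0=4e-4, decay_constant_k=100.0, r_squared=1.0, n_points=5,
        )
        with pytest.raises(FitError, match="time"):
            px.extrapolate_yield(fit, 100.0)


class TestLog10FoldChange:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(7.25, 5.65, 39.81), (3.0, 3.0, 1.0), (5.0, 4.0, 10.0)],
    )
    def test_worked_values(self, start, end, expected):
        assert px.log10_fold_change(start, end) == pytest.approx(expected, abs=0.005)
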
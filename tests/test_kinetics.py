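"""Shoulder-log-linear model, replicate averaging, fitting, model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phbdeg.kinetics import (
    AveragedSeries,
    KineticParams,
    average_replicates,
    fit_shoulder_log_linear,
    select_model,
    shoulder_log_linear,
)
from phbdeg.synthetic_data import (
    NoiseModel,
    ResidualMassDataset,
    SamplingDesign,
    Treatment,
    simulate_mass_timeseries,
)

params_st = st.tuples(
    st.floats(1.0, 1000.0),     # m0
    st.floats(0.0, 5.0),        # k
    st.floats(0.0, 200.0),      # lag
).map(lambda t: KineticParams(*t))


class TestShoulderLogLinear:
    def test_identity_at_t0(self):
        for m0, k, lag in [(100, 0.11, 13), (50, 2.0, 0), (1, 0.0, 90)]:
            assert shoulder_log_linear(0.0, KineticParams(m0, k, lag)) == pytest.approx(m0)

    def test_zero_lag_is_pure_exponential(self):
        t = np.linspace(0, 100, 31)
        p = KineticParams(m0=100, k=0.1, lag=0)
        np.testing.assert_allclose(shoulder_log_linear(t, p), 100 * np.exp(-0.1 * t), rtol=1e-12)
        assert shoulder_log_linear(10.0, p) == pytest.approx(100 * np.exp(-1), rel=1e-12)

    def test_closed_form_at_t_equals_lag(self):
        # substituting t = L gives m(L) = m0 / (2 - exp(-kL))
        p = KineticParams(m0=100, k=0.11, lag=13)
        assert shoulder_log_linear(13.0, p) == pytest.approx(100 / (2 - np.exp(-1.43)), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="time"):
            shoulder_log_linear(-1.0, KineticParams(100, 0.1, 0))

    @given(params_st)
    def test_monotone_non_increasing(self, params):
        t = np.linspace(0, 400, 200)
        m = shoulder_log_linear(t, params)
        assert np.all(np.diff(m) <= 1e-9 * params.m0)

    @given(params_st.filter(lambda p: p.k > 0.01))
    def test_asymptotic_log_linear_slope(self, params):
        # well past the lag, d ln(m)/dt approaches -k
        t = params.lag + np.array([50.0, 60.0]) + 10.0 / params.k
        m = shoulder_log_linear(t, params)
        if m.min() > 1e-300:  # avoid complete underflow for very fast decay
            slope = (np.log(m[1]) - np.log(m[0])) / (t[1] - t[0])
            assert slope == pytest.approx(-params.k, rel=1e-3)

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ValueError, match="k"):
            KineticParams(100, -0.1, 0)
        with pytest.raises(ValueError, match="lag"):
            KineticParams(100, 0.1, -5)
        with pytest.raises(ValueError, match="m0"):
            KineticParams(0, 0.1, 0)


def _dataset(rows):
    df = pd.DataFrame(rows, columns=["time_d", "replicate", "initial_mass_mg", "residual_mass_mg"])
    df["residual_percent"] = 100 * df["residual_mass_mg"] / df["initial_mass_mg"]
    return ResidualMassDataset(treatment=Treatment(), observations=df)


class TestAverageReplicates:
    def test_mean_and_sample_sd(self):
        ds = _dataset([(0, 1, 100, 100), (0, 2, 100, 98), (0, 3, 100, 96)])
        s = average_replicates(ds)
        assert s.means[0] == pytest.approx(98.0)
        assert s.sds[0] == pytest.approx(2.0)  # sqrt(((4+0+4)/2))
        assert s.n_replicates[0] == 3

    def test_single_replicate_sd_missing(self):
        ds = _dataset([(0, 1, 100, 97.0), (7, 1, 100, 80.0)])
        s = average_replicates(ds)
        np.testing.assert_array_equal(s.means, [97.0, 80.0])
        assert np.all(np.isnan(s.sds))

    def test_identical_triplicates_zero_sd(self):
        ds = _dataset([(t, r, 100, v) for t, v in [(0, 100.0), (7, 50.0)] for r in (1, 2, 3)])
        s = average_replicates(ds)
        np.testing.assert_array_equal(s.sds, [0.0, 0.0])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            average_replicates(_dataset([]))


def noise_free_series(m0, k, lag, times):
    ds = simulate_mass_timeseries(
        KineticParams(m0, k, lag), SamplingDesign(times=times), NoiseModel()
    )
    return average_replicates(ds)


class TestFitShoulderLogLinear:
    @pytest.mark.parametrize(
        "k,lag", [(0.081, 24.0), (0.11, 13.0), (0.22, 5.0), (0.0045, 0.0)]
    )
    def test_zero_noise_recovery(self, k, lag):
        horizon = lag + 4.0 / k
        series = noise_free_series(100, k, lag, np.linspace(0, horizon, 11))
        fit = fit_shoulder_log_linear(series)
        assert fit.converged
        assert fit.k_hat == pytest.approx(k, rel=1e-6)
        assert fit.lag_hat == pytest.approx(lag, rel=1e-6, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_true_exponential_lag_not_significant(self):
        series = noise_free_series(100, 0.1, 0.0, np.arange(0.0, 71, 7))
        fit = fit_shoulder_log_linear(series)
        assert fit.lag_hat == pytest.approx(0.0, abs=1e-6)
        assert fit.p_lag > 0.05

    def test_nesting_rss_free_le_zero(self, rng):
        for _ in range(5):
            ds = simulate_mass_timeseries(
                KineticParams(100, 0.08, 20),
                SamplingDesign(times=np.linspace(0, 80, 10)),
                NoiseModel(sigma_abs=2.0, seed=int(rng.integers(2**31))),
            )
            series = average_replicates(ds)
            free = fit_shoulder_log_linear(series, fix_lag_to_zero=False)
            zero = fit_shoulder_log_linear(series, fix_lag_to_zero=True)
            assert free.rss <= zero.rss + 1e-9

    def test_information_criterion_identities(self):
        series = noise_free_series(100, 0.05, 10, np.linspace(0, 90, 12))
        # perturb so RSS > 0
        series = AveragedSeries(
            times=series.times,
            means=series.means + np.sin(series.times),
            sds=series.sds,
            n_replicates=series.n_replicates,
        )
        for fix in (False, True):
            fit = fit_shoulder_log_linear(series, fix_lag_to_zero=fix)
            p = 1 if fix else 2
            n = fit.n_points
            assert fit.neg2loglik == pytest.approx(n * (np.log(2 * np.pi * fit.rss / n) + 1))
            assert fit.aic == pytest.approx(fit.neg2loglik + 2 * p)
            assert fit.bic == pytest.approx(fit.neg2loglik + p * np.log(n))

    def test_chi_squared_replicate_weighted(self):
        ds = simulate_mass_timeseries(
            KineticParams(100, 0.1, 0),
            SamplingDesign(times=[0.0, 10.0, 20.0, 30.0], replicates=3),
            NoiseModel(sigma_abs=1.5, seed=7),
        )
        series = average_replicates(ds)
        fit = fit_shoulder_log_linear(series, fix_lag_to_zero=True)
        if np.all(series.sds > 0):
            assert not fit.chi_squared_is_rss
            model = shoulder_log_linear(series.times, fit.params)
            expected = np.sum((series.means - model) ** 2 / (series.sds**2 / series.n_replicates))
            assert fit.chi_squared == pytest.approx(expected)

    def test_no_mass_loss_returns_finite_near_zero_k(self):
        series = AveragedSeries(
            times=[0.0, 30.0, 60.0, 90.0],
            means=[100.0, 99.5, 100.2, 99.8],
            sds=[1.0, 1.0, 1.0, 1.0],
            n_replicates=[3, 3, 3, 3],
        )
        fit = fit_shoulder_log_linear(series)
        assert fit.converged
        assert 0 <= fit.k_hat < 0.01

    def test_too_few_points_rejected(self):
        series = AveragedSeries(times=[0.0, 10.0], means=[100.0, 50.0],
                                sds=[1.0, 1.0], n_replicates=[3, 3])
        with pytest.raises(ValueError, match="time points"):
            fit_shoulder_log_linear(series, fix_lag_to_zero=False)


class TestSelectModel:
    def _fits(self, p_lag):
        series = noise_free_series(100, 0.05, 25, np.linspace(0, 100, 10))
        free = fit_shoulder_log_linear(series)
        zero = fit_shoulder_log_linear(series, fix_lag_to_zero=True)
        free.p_lag = p_lag
        return free, zero

    @pytest.mark.parametrize(
        "p_lag,expect_variant",
        [(0.58, "lag-fixed-zero"), (0.001, "free-lag"), (0.05, "free-lag")],
    )
    def test_lag_significance_rule(self, p_lag, expect_variant):
        free, zero = self._fits(p_lag)
        chosen = select_model(free, zero, alpha=0.05)
        assert chosen.variant == expect_variant
        assert chosen.comparison.lag_significant == (expect_variant == "free-lag")
        assert chosen.comparison.free_lag.aic is not None
        assert chosen.comparison.lag_zero.bic is not None

    def test_mismatched_series_rejected(self):
        free, _ = self._fits(0.01)
        other = noise_free_series(100, 0.1, 0, np.linspace(0, 40, 6))
        zero_other = fit_shoulder_log_linear(other, fix_lag_to_zero=True)
        with pytest.raises(ValueError, match="same series"):
            select_model(free, zero_other)

    def test_invalid_alpha_rejected(self):
        free, zero = self._fits(0.01)
        with pytest.raises(ValueError, match="alpha"):
            select_model(free, zero, alpha=1.5)
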
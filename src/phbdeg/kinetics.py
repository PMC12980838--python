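"""Shoulder-log-linear kinetics of polymer mass loss in soil.

The model describes residual polymer mass over incubation time as an
initial shoulder (lag phase) of duration ``L`` during which no net mass
loss occurs, followed by pseudo-first-order (log-linear) decay at rate
``k``:

.. math::

    m(t) = m_0 \\, e^{-kt} \\, \\frac{e^{kL}}{1 + (e^{kL} - 1) e^{-kt}}

At ``L = 0`` this reduces exactly to exponential decay
``m(t) = m_0 e^{-kt}``; at ``t = 0`` it equals ``m_0`` for any ``(k, L)``.
The lag phase is interpreted as the time microorganisms need to colonize
the polymer surface before measurable degradation starts.

Fitting operates on replicate-averaged residual-percent series: the
arithmetic mean over replicates is fitted per time point with unweighted
least squares, because replicates drawn from the same incubation vial
design are not independent observations of the decay curve.  The initial
mass is fixed at the normalized 100 % rather than fitted, since it is the
measured amount of polymer added to each vial.

Whether the lag phase belongs in the model for a given treatment is
decided by a Wald significance test on the fitted ``L`` (two-sided, at a
caller-chosen ``alpha``): when the lag is not significant the nested
zero-lag (pure first-order) fit is reported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticParams",
    "AveragedSeries",
    "KineticFit",
    "ModelComparison",
    "shoulder_log_linear",
    "average_replicates",
    "fit_shoulder_log_linear",
    "select_model",
]

#: Optimizer bounds for the rate constant, d^-1.
K_BOUNDS = (0.0, 10.0)

#: Fraction of m0 above which a time point is considered pre-decay when
#: choosing the initial lag guess.
_SHOULDER_FRACTION = 0.95

_N_RESTARTS = 10


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the shoulder-log-linear decay model.

    Attributes
    ----------
    m0 : float
        Initial polymer mass (mg, or percent on the normalized scale); > 0.
    k : float
        Pseudo-first-order mass-loss rate constant, d^-1; >= 0.
    lag : float
        Lag-phase duration L, days; >= 0.  ``lag = 0`` gives pure
        exponential decay.
    """

    m0: float
    k: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if not (self.m0 > 0):
            raise ValueError(f"m0 must be > 0, got {self.m0}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")


def shoulder_log_linear(t, params: KineticParams):
    """Residual mass at time(s) ``t`` under the shoulder-log-linear model.

    Parameters
    ----------
    t : float or array-like
        Incubation time in days; must be >= 0.
    params : KineticParams

    Returns
    -------
    float or ndarray
        Residual mass in the units of ``params.m0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    m = _model(t, params.m0, params.k, params.lag)
    return float(m) if m.ndim == 0 else m


def _model(t, m0, k, lag):
    # exp(kL) can overflow for large lag*k; work with exp(-k(t-L)) instead:
    # m = m0 * e^{-k(t-L)} / (1 + (e^{kL}-1) e^{-kt})
    #   = m0 / (e^{k(t-L)} + e^{-kL}(e^{kL}-1) e^{-k(t-L)}) ... keep simple,
    # equivalent stable form: m0 / (e^{k(t-L)} - e^{-kL} e^{k(t-L)} e^{-kt} ... )
    # Use: m = m0 / (exp(k*(t-L)) + 1 - exp(-k*L))  [algebraic rearrangement]
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        denom = np.exp(k * (t - lag)) + 1.0 - np.exp(-k * lag)
    return m0 / denom


@dataclass(frozen=True)
class AveragedSeries:
    """Replicate-averaged residual-mass series for one treatment.

    ``sds`` holds the sample (n-1) standard deviation per time point, or
    NaN where only a single replicate exists.
    """

    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "means", "sds", "n_replicates"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if not (len(self.means) == len(self.sds) == len(self.n_replicates) == n):
            raise ValueError("times, means, sds, n_replicates must have equal length")
        if n == 0:
            raise ValueError("series is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.means < 0):
            raise ValueError("mean residual masses must be >= 0")


def average_replicates(dataset) -> AveragedSeries:
    """Collapse a replicate-level dataset to per-time means and SDs.

    Operates on the residual-percent column.  SD is the sample (n-1)
    standard deviation; with a single replicate it is reported as NaN.
    """
    df = dataset.observations
    if len(df) == 0:
        raise ValueError("dataset has no observations")
    grouped = df.groupby("time_d")["residual_percent"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)  # NaN for single replicate
    counts = grouped.count()
    return AveragedSeries(
        times=means.index.to_numpy(dtype=float),
        means=means.to_numpy(dtype=float),
        sds=sds.to_numpy(dtype=float),
        n_replicates=counts.to_numpy(dtype=float),
    )


@dataclass
class KineticFit:
    """Result of fitting the shoulder-log-linear model to one series.

    Model-comparison statistics use a Gaussian likelihood with the MLE
    variance RSS/n, so ``neg2loglik = n*(ln(2*pi*RSS/n) + 1)`` includes
    the additive constant; only differences between nested fits are
    meaningful.  ``chi_squared`` is the replicate-variance-weighted
    statistic sum((mean_i - model_i)^2 / (sd_i^2 / n_i)) when every time
    point has a positive SD, otherwise it falls back to the plain RSS and
    ``chi_squared_is_rss`` is set.
    """

    variant: str  # "free-lag" | "lag-fixed-zero"
    k_hat: float
    se_k: float
    p_k: float
    lag_hat: float
    se_lag: Optional[float]
    p_lag: Optional[float]
    r_squared: float
    rss: float
    aic: float
    bic: float
    chi_squared: float
    chi_squared_is_rss: bool
    neg2loglik: float
    n_points: int
    m0: float
    converged: bool = True
    message: str = ""
    comparison: Optional["ModelComparison"] = None

    @property
    def params(self) -> KineticParams:
        return KineticParams(m0=self.m0, k=self.k_hat, lag=self.lag_hat)


@dataclass
class ModelComparison:
    """Side-by-side statistics of the free-lag and zero-lag fits."""

    alpha: float
    lag_significant: bool
    selected_variant: str
    free_lag: "KineticFit" = field(repr=False, default=None)
    lag_zero: "KineticFit" = field(repr=False, default=None)


def _initial_guess(series: AveragedSeries, m0: float):
    """Heuristic start: lag = last time still on the shoulder, k from the
    log-linear slope of the declining phase."""
    t, y = series.times, series.means
    shoulder = y >= _SHOULDER_FRACTION * m0
    lag0 = float(t[shoulder][-1]) if shoulder.any() else 0.0
    declining = (y > 0) & (t >= lag0)
    if declining.sum() >= 2:
        slope = np.polyfit(t[declining], np.log(y[declining]), 1)[0]
        k0 = max(-slope, 1e-4)
    else:
        k0 = 0.01
    k0 = min(max(k0, K_BOUNDS[0] + 1e-6), K_BOUNDS[1])
    return k0, lag0


def fit_shoulder_log_linear(
    series: AveragedSeries,
    fix_lag_to_zero: bool = False,
    m0_fixed: float = 100.0,
) -> KineticFit:
    """Least-squares fit of the shoulder-log-linear model.

    Parameters
    ----------
    series : AveragedSeries
        Replicate-averaged residual-percent series.
    fix_lag_to_zero : bool
        Fit the nested pure-first-order model (L = 0) instead of the
        two-parameter model.
    m0_fixed : float
        The initial value, fixed (not fitted); 100 on the percent scale.

    Returns
    -------
    KineticFit
        With standard errors from the Gauss-Newton covariance
        ``s^2 (J'J)^-1`` at ``s^2 = RSS/(n-p)`` and two-sided t-test
        p-values at ``df = n - p``.  Non-convergence after jittered
        restarts is reported via ``converged=False`` rather than raised.
    """
    t, y = series.times, series.means
    n = len(t)
    n_fitted = 1 if fix_lag_to_zero else 2
    if n < n_fitted + 1:
        raise ValueError(
            f"need at least {n_fitted + 1} time points to fit {n_fitted} parameter(s), got {n}"
        )
    m0 = float(m0_fixed)
    lag_bounds = (0.0, float(t[-1]) if t[-1] > 0 else 1.0)
    k0, lag0 = _initial_guess(series, m0)

    if fix_lag_to_zero:
        def resid(theta):
            return _model(t, m0, theta[0], 0.0) - y
        x0 = np.array([k0])
        lo, hi = np.array([K_BOUNDS[0]]), np.array([K_BOUNDS[1]])
    else:
        def resid(theta):
            return _model(t, m0, theta[0], theta[1]) - y
        x0 = np.array([k0, min(lag0, lag_bounds[1])])
        lo = np.array([K_BOUNDS[0], lag_bounds[0]])
        hi = np.array([K_BOUNDS[1], lag_bounds[1]])

    rng = np.random.default_rng(0)
    best = None
    message = ""
    for attempt in range(_N_RESTARTS + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 * np.exp(rng.normal(0, 0.5, size=x0.shape)) + rng.normal(0, 1e-3, size=x0.shape),
            lo, hi,
        )
        try:
            res = optimize.least_squares(
                resid, start, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer internal failure
            message = str(exc)
            continue
        if res.success and np.isfinite(res.cost):
            if best is None or res.cost < best.cost - 1e-12:
                best = res
            if attempt == 0:
                break  # first try converged; restarts only on failure
        else:
            message = res.message

    if best is None:
        return KineticFit(
            variant="lag-fixed-zero" if fix_lag_to_zero else "free-lag",
            k_hat=math.nan, se_k=math.nan, p_k=math.nan,
            lag_hat=0.0 if fix_lag_to_zero else math.nan,
            se_lag=None if fix_lag_to_zero else math.nan,
            p_lag=None if fix_lag_to_zero else math.nan,
            r_squared=math.nan, rss=math.nan, aic=math.nan, bic=math.nan,
            chi_squared=math.nan, chi_squared_is_rss=True,
            neg2loglik=math.nan, n_points=n, m0=m0,
            converged=False, message=message or "no successful optimizer run",
        )

    theta = best.x
    residuals = resid(theta)
    rss = float(residuals @ residuals)
    dof = n - n_fitted
    s2 = rss / dof if dof > 0 else math.nan

    # Gauss-Newton covariance from the optimizer Jacobian at the solution.
    J = best.jac
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
    ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    def p_value(est, se):
        if not np.isfinite(se) or se == 0:
            return math.nan
        return float(2.0 * stats.t.sf(abs(est / se), dof))

    k_hat = float(theta[0])
    se_k = float(ses[0])
    p_k = p_value(k_hat, se_k)
    if fix_lag_to_zero:
        lag_hat, se_lag, p_lag = 0.0, None, None
    else:
        lag_hat = float(theta[1])
        se_lag = float(ses[1])
        # A lag at the zero boundary below numerical resolution carries no
        # shoulder at all; the Wald ratio of two numerical zeros is noise,
        # so report exactly zero with no evidence of a lag.
        if lag_hat < 1e-8 * max(t[-1], 1.0):
            lag_hat, p_lag = 0.0, 1.0
        else:
            p_lag = p_value(lag_hat, se_lag)

    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else math.nan

    with np.errstate(divide="ignore"):
        neg2loglik = n * (np.log(2.0 * np.pi * rss / n) + 1.0) if rss > 0 else -math.inf
    aic = neg2loglik + 2.0 * n_fitted
    bic = neg2loglik + n_fitted * math.log(n)

    sds, counts = series.sds, series.n_replicates
    if np.all(np.isfinite(sds)) and np.all(sds > 0):
        chi_squared = float(np.sum(residuals**2 / (sds**2 / counts)))
        chi_is_rss = False
    else:
        chi_squared = rss
        chi_is_rss = True

    return KineticFit(
        variant="lag-fixed-zero" if fix_lag_to_zero else "free-lag",
        k_hat=k_hat, se_k=se_k, p_k=p_k,
        lag_hat=lag_hat, se_lag=se_lag, p_lag=p_lag,
        r_squared=r_squared, rss=rss, aic=aic, bic=bic,
        chi_squared=chi_squared, chi_squared_is_rss=chi_is_rss,
        neg2loglik=neg2loglik, n_points=n, m0=m0,
        converged=True, message=best.message,
    )


def select_model(fit_free: KineticFit, fit_zero: KineticFit, alpha: float = 0.05) -> KineticFit:
    """Choose between the free-lag and zero-lag fits by lag significance.

    The free-lag fit is kept when its lag p-value is <= ``alpha``
    (boundary counts as significant); otherwise the nested zero-lag fit
    is returned.  The returned fit carries a :class:`ModelComparison`
    with both candidates' AIC/BIC/chi-squared/-2logL for reporting.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fit_free.variant != "free-lag" or fit_zero.variant != "lag-fixed-zero":
        raise ValueError("expected one free-lag and one lag-fixed-zero fit")
    if fit_free.n_points != fit_zero.n_points or fit_free.m0 != fit_zero.m0:
        raise ValueError("fits were not computed on the same series")
    p_lag = fit_free.p_lag
    significant = bool(np.isfinite(p_lag) and p_lag <= alpha) if p_lag is not None else False
    chosen = fit_free if significant else fit_zero
    chosen.comparison = ModelComparison(
        alpha=alpha,
        lag_significant=significant,
        selected_variant=chosen.variant,
        free_lag=fit_free,
        lag_zero=fit_zero,
    )
    return chosen
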
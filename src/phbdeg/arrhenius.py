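"""Arrhenius analysis of temperature-resolved biodegradation rate constants.

The Arrhenius rate law, ``ln k = -Ea/(R T) + ln A``, is fitted by
ordinary least squares of ln(k) on inverse absolute temperature; the
apparent activation energy is ``Ea = -slope * R`` with R = 8.314
J K^-1 mol^-1.  Biodegradation is a multistep process (colonization,
extracellular hydrolysis, microbial uptake), so Ea here is an apparent,
lumped quantity; curvature of ln(k) vs 1/T is expected at the
temperature extremes, which is why temperature-subset fits are
supported.

Activation energies convert to Q10 temperature coefficients — the
factor change in rate per 10 degC — either as the geometric mean over a
span (the 10-degC-normalized rate ratio between the span's endpoints)
or as the arithmetic mean of the per-10-degC factors over consecutive
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "KELVIN_OFFSET",
    "RateConstantSet",
    "ArrheniusFit",
    "Q10Result",
    "fit_arrhenius",
    "predict_k",
    "q10_from_ea",
]

GAS_CONSTANT = 8.314  # J K^-1 mol^-1
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class RateConstantSet:
    """Rate constants k (d^-1) at several incubation temperatures for one
    soil/polymer-variant combination.  Optional per-point standard errors
    are carried as metadata but do not weight the regression."""

    soil: str
    variant: str
    points: Sequence[tuple[float, float]]  # (temperature degC, k d^-1)
    se_k: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.points]
        ks = [k for _, k in self.points]
        if len(set(temps)) != len(temps):
            raise ValueError("temperatures must be distinct")
        if any(k <= 0 for k in ks):
            raise ValueError("all rate constants must be > 0 (log must be finite)")
        if self.se_k is not None and len(self.se_k) != len(self.points):
            raise ValueError("se_k length must match points")

    def subset(self, t_min_c: float, t_max_c: float) -> "RateConstantSet":
        """Points with temperature in [t_min_c, t_max_c], inclusive."""
        keep = [(t, k) for t, k in self.points if t_min_c <= t <= t_max_c]
        se = None
        if self.se_k is not None:
            se = [s for (t, _), s in zip(self.points, self.se_k) if t_min_c <= t <= t_max_c]
        return RateConstantSet(soil=self.soil, variant=self.variant, points=keep, se_k=se)


@dataclass
class ArrheniusFit:
    """OLS fit of ln(k) on 1/T_K.

    ``ea`` in J/mol; ``se_ea`` is NaN when only two points were fitted
    (no residual degrees of freedom).  ``r_squared`` is NaN for flat
    (zero-variance) responses.
    """

    ea: float
    se_ea: float
    ln_a: float
    r_squared: float
    n_points: int
    temp_range_used: tuple[float, float]
    soil: str = ""
    variant: str = ""
    gas_constant: float = GAS_CONSTANT


def fit_arrhenius(
    rates: RateConstantSet,
    t_min_c: float = -math.inf,
    t_max_c: float = math.inf,
) -> ArrheniusFit:
    """Fit the Arrhenius law to the rate constants inside [t_min_c, t_max_c].

    Unweighted OLS of ln(k) on 1/T_K (T_K = degC + 273.15);
    ``Ea = -slope * R`` and ``se_Ea = R * SE(slope)`` with the standard
    error from residual variance at n-2 degrees of freedom.
    """
    sub = rates.subset(t_min_c, t_max_c)
    n = len(sub.points)
    if n < 2:
        raise ValueError(f"need >= 2 points inside [{t_min_c}, {t_max_c}] degC, got {n}")
    temps_c = np.array([t for t, _ in sub.points])
    ks = np.array([k for _, k in sub.points])
    x = 1.0 / (temps_c + KELVIN_OFFSET)
    y = np.log(ks)

    if np.ptp(y) == 0.0:  # flat data: zero activation energy, R^2 undefined
        return ArrheniusFit(
            ea=0.0, se_ea=math.nan, ln_a=float(y[0]), r_squared=math.nan,
            n_points=n, temp_range_used=(float(temps_c.min()), float(temps_c.max())),
            soil=rates.soil, variant=rates.variant,
        )

    res = stats.linregress(x, y)
    se_slope = res.stderr if n > 2 else math.nan
    return ArrheniusFit(
        ea=float(-res.slope * GAS_CONSTANT),
        se_ea=float(GAS_CONSTANT * se_slope) if np.isfinite(se_slope) else math.nan,
        ln_a=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=n,
        temp_range_used=(float(temps_c.min()), float(temps_c.max())),
        soil=rates.soil,
        variant=rates.variant,
    )


def predict_k(fit: ArrheniusFit, temperature_c: float) -> float:
    """Rate constant (d^-1) predicted at a temperature from a fitted law."""
    if not np.isfinite(temperature_c):
        raise ValueError("temperature must be finite")
    t_k = temperature_c + KELVIN_OFFSET
    return math.exp(fit.ln_a - fit.ea / (fit.gas_constant * t_k))


@dataclass(frozen=True)
class Q10Result:
    q10: float
    ea: float
    t_low: float
    t_high: float
    method: str


def q10_from_ea(
    ea: float,
    t_low_c: float = 0.0,
    t_high_c: float = 40.0,
    method: str = "geometric-mean",
) -> Q10Result:
    """Q10 temperature coefficient implied by an activation energy.

    geometric-mean (default): the rate ratio between the span's
    endpoints normalized to a 10-degC step,
    ``[k(T_high)/k(T_low)]^(10/(T_high - T_low))``.

    per-interval: the arithmetic mean of ``exp(Ea/R (1/T - 1/(T+10)))``
    over consecutive 10-degC intervals covering the span.
    """
    if not np.isfinite(ea):
        raise ValueError("ea must be finite")
    if t_high_c < t_low_c + 10.0:
        raise ValueError(f"span must be >= 10 degC, got [{t_low_c}, {t_high_c}]")
    if method == "geometric-mean":
        t1 = t_low_c + KELVIN_OFFSET
        t2 = t_high_c + KELVIN_OFFSET
        log_ratio = ea / GAS_CONSTANT * (1.0 / t1 - 1.0 / t2)
        q10 = math.exp(log_ratio * 10.0 / (t_high_c - t_low_c))
    elif method == "per-interval":
        starts = np.arange(t_low_c, t_high_c - 10.0 + 1e-9, 10.0)
        t1 = starts + KELVIN_OFFSET
        t2 = t1 + 10.0
        q10 = float(np.mean(np.exp(ea / GAS_CONSTANT * (1.0 / t1 - 1.0 / t2))))
    else:
        raise ValueError(f"unknown method {method!r}; use 'geometric-mean' or 'per-interval'")
    return Q10Result(q10=q10, ea=ea, t_low=t_low_c, t_high=t_high_c, method=method)
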
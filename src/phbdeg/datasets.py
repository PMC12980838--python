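"""Published shoulder-log-linear fit parameters for PHBHH9 in LUFA soils.

Fitted pseudo-first-order rate constants k (d^-1) and lag phases L (d)
for poly(3-hydroxybutyrate-co-3-hydroxyhexanoate) with 9 mol% 3-HH
(PHBHH9) films incubated in three standardized LUFA agricultural soils
(6S clay, 2.4 loam, 2.2 sandy loam) at 5-35 degC.  A lag of 0 marks
treatments where the lag term was not statistically significant and the
nested first-order model was reported instead.

These serve two roles in the package: as ground-truth parameters for
the synthetic-data generator (the raw residual-mass series behind them
are not deposited anywhere machine-readable) and as the rate-constant
inputs for the Arrhenius/Q10 analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arrhenius import RateConstantSet

__all__ = ["KineticTableRow", "PHBHH9_KINETICS", "phbhh9_rate_constants"]


@dataclass(frozen=True)
class KineticTableRow:
    soil: str
    temperature_c: float
    k: float            # d^-1
    se_k: float
    p_k: float
    lag: float          # d; 0 when not significant
    se_lag: float       # 0 when lag fixed at 0
    p_lag: float
    r_squared: float


PHBHH9_KINETICS: tuple[KineticTableRow, ...] = (
    KineticTableRow("LUFA 6S", 5, 0.025, 0.007, 0.020, 82, 8, 0.001, 0.98),
    KineticTableRow("LUFA 6S", 15, 0.020, 0.002, 0.0002, 0, 0, 0.58, 0.97),
    KineticTableRow("LUFA 6S", 20, 0.043, 0.002, 1e-5, 0, 0, 0.16, 1.00),
    KineticTableRow("LUFA 6S", 25, 0.11, 0.02, 0.004, 13, 1, 0.001, 0.99),
    KineticTableRow("LUFA 6S", 30, 0.20, 0.02, 0.001, 5, 1, 0.002, 1.00),
    KineticTableRow("LUFA 6S", 35, 0.22, 0.01, 4e-5, 5, 0, 4e-5, 1.00),
    KineticTableRow("LUFA 2.4", 5, 0.011, 0.005, 0.069, 164, 128, 0.004, 0.93),
    KineticTableRow("LUFA 2.4", 15, 0.025, 0.008, 0.034, 74, 10, 0.002, 0.96),
    KineticTableRow("LUFA 2.4", 25, 0.081, 0.024, 0.026, 24, 4, 0.002, 0.96),
    KineticTableRow("LUFA 2.4", 35, 0.088, 0.003, 1e-5, 0, 0, 1.0, 1.00),
    KineticTableRow("LUFA 2.2", 5, 0.0008, 0.0001, 0.002, 0, 0, 1.0, 0.78),
    KineticTableRow("LUFA 2.2", 15, 0.0045, 0.0004, 0.0002, 0, 0, 0.84, 0.93),
    KineticTableRow("LUFA 2.2", 25, 0.034, 0.015, 0.080, 31, 13, 0.076, 0.95),
    KineticTableRow("LUFA 2.2", 35, 0.096, 0.029, 0.028, 14, 4, 0.016, 0.97),
)


def phbhh9_rate_constants(soil: str, variant: str = "PHBHH9") -> RateConstantSet:
    """Rate-constant set for one soil, ready for Arrhenius fitting."""
    rows = [r for r in PHBHH9_KINETICS if r.soil == soil]
    if not rows:
        soils = sorted({r.soil for r in PHBHH9_KINETICS})
        raise KeyError(f"unknown soil {soil!r}; available: {soils}")
    return RateConstantSet(
        soil=soil,
        variant=variant,
        points=[(r.temperature_c, r.k) for r in rows],
        se_k=[r.se_k for r in rows],
    )
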
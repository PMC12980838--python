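# Methods

## The decay model

Residual polymer mass under soil incubation is modeled as a shoulder
followed by log-linear loss:

m(t) = m₀ · e^(−kt) · e^(kL) / (1 + (e^(kL) − 1) · e^(−kt))

with m₀ the initially added mass (fixed at 100 on the normalized percent
scale), k ≥ 0 the pseudo-first-order rate constant (d⁻¹) and L ≥ 0 the lag
duration (d). The form is the classical shoulder/log-linear survival model
from microbial inactivation kinetics applied to polymer mass: during the
shoulder the film is being colonized and mass loss is negligible; once
active, degradation is first-order. At t = 0 the model equals m₀ for any
(k, L); at L = 0 it is exactly exponential decay; for t ≫ L the log-slope
tends to −k. Internally the equivalent form m₀ / (e^(k(t−L)) + 1 − e^(−kL))
is evaluated, which avoids overflow of e^(kL) for long lags.

Assumptions: a single homogeneous decay phase after the lag; no secondary
tailing; mass loss is irreversible. Multi-phase or Weibull-type decay and
respirometric (CO₂) kinetics are out of scope.

## Fitting and inference

Fits use the per-time arithmetic mean of replicate residual percents
(sample SDs are carried along for the χ² statistic). Replicates from one
sacrificed vial schedule are not independent realizations of the curve, so
fitting means rather than pooled points keeps the least-squares assumptions
honest. Residuals are unweighted on the percent scale.

The optimizer is bounded trust-region least squares (k ∈ [0, 10] d⁻¹,
L ∈ [0, t_max]; xtol = ftol = gtol = 1e−12), started from an OLS log-slope
over the declining phase and the last time point still ≥ 95 % of m₀; up to
10 jittered restarts run only if the first attempt fails. Standard errors
come from the Gauss–Newton covariance s²(JᵀJ)⁻¹ with s² = RSS/(n−p);
p-values are two-sided Wald t-tests at df = n−p. A fitted lag that lands on
the zero boundary below numerical resolution (< 1e−8·t_max) is reported as
exactly 0 with p = 1: the Wald ratio there is a quotient of two numerical
zeros and carries no information.

Model-comparison statistics use the Gaussian likelihood with MLE variance
RSS/n, so −2logL = n(ln(2π·RSS/n) + 1) **includes** the additive constant;
only differences between the free-lag and zero-lag fits on the same series
are meaningful. AIC = −2logL + 2p and BIC = −2logL + p·ln n. χ² is the
replicate-variance-weighted statistic Σ(meanᵢ − modelᵢ)²/(sdᵢ²/nᵢ) when all
per-time SDs are positive, otherwise the plain RSS with a flag
(`chi_squared_is_rss`).

Lag-phase selection: the free-lag fit is kept when its lag p-value is
≤ α (default 0.05, boundary counted as significant); otherwise the nested
zero-lag fit is reported, with both candidates' statistics attached. No
multiple-testing correction is applied across treatments. A series with no
measurable mass loss returns a finite fit with k near 0 rather than an
error — slow treatments are data, not failures.

## Arrhenius analysis and Q10

ln k is regressed on 1/T_K by unweighted OLS (Kelvin conversion uses
273.15 exactly; the choice matters < 0.1 % on Ea). Ea = −slope·R,
se(Ea) = R·SE(slope) from residual variance at df = n−2; with exactly two
points the SE is reported unavailable (NaN) rather than zero. Per-point
standard errors of k are carried as metadata but do not weight the fit:
the unweighted regression is what reproduces the published per-soil
activation energies from the printed rate constants. Temperature-subset
fits are inclusive at both bounds. Because biodegradation lumps
colonization, enzymatic hydrolysis and uptake, the fitted Ea is apparent;
curvature at the temperature extremes is expected and is the reason the
subset fit exists (for LUFA 6S, 15–30 °C raises Ea from ≈ 63 to
≈ 114 kJ/mol from the rounded published inputs, versus the published
115 ± 7 — the remaining ~1 kJ/mol is rounding of the input k values).

Q10 defaults to the geometric-mean convention over the span:
[k(T_high)/k(T_low)]^(10/(T_high−T_low)) via the fitted law — i.e., the
fourth root of the 0–40 °C rate ratio — because it directly expresses an
average factor change per 10 °C over that range. A per-interval convention
(arithmetic mean of the per-10 °C factors) is also provided; the two agree
within 2 % for Ea ≤ 130 kJ/mol over 0–40 °C. For Ea = 53 kJ/mol both give
≈ 2.11 where a value of 2.2 has been reported elsewhere with an unstated
averaging convention; no attempt is made to reverse-engineer that
arithmetic.

## qNMR quantification

Moles of each monomer unit follow the internal-standard ratio
n = (I/H) / (I_std/H_std) · m_std/M_std, with DMB (138.16 g/mol, 4 aromatic
protons) as the default standard and repeat-unit masses 86.09 (3-HB) and
114.14 g/mol (3-HH). Default diagnostic peaks are the 3-HB and 3-HH methyls
(3 protons each); all proton counts are per-peak fields, overridable
because actual assignment choices vary with spectrometer and deconvolution
practice. Residual mass is n_HB·86.09 + n_HH·114.14; the 3-HH content is
the per-proton mole fraction in percent, invariant to uniform integral
rescaling. When a tube volume is supplied, implied concentrations below
0.67 mg/mL raise a quality flag, reflecting where deconvolution uncertainty
grows. Spectral processing (FT, phasing, baseline, deconvolution) is out of
scope; the module starts from integrals.

## Colonization metrics

Label masks (0 intact, 1 hyphal skeleton, 2 colony, 3 hole) are summarized
as: skeleton length = Σ over unique 8-connected skeleton-pixel adjacencies
(orthogonal step = 1 px, diagonal = √2 px) × pixel size, per imaged area;
and colony/hole area fractions by pixel counting, with skeleton pixels
counted as intact film so fractions sum to one. The step metric is exact
for axis-aligned and 45° lines and deterministic, which is why it was
chosen over perimeter- or spline-based estimators. Segmentation of raw SEM
images into these classes is explicitly out of scope.

## Synthetic data

The generator is phenomenological: the decay law above plus additive
Gaussian measurement noise on the mass scale (default σ chosen per study;
the recovery study uses 2 % absolute), truncated at zero, with an optional
multiplicative extraction-recovery factor drawn once per sample (default
0.97 ± 0.04, the spike-recovery level of solvent extraction from soil).
Triplicates per time point are the default design. Rate constants are
generated from the Arrhenius law with log-normal scatter; qNMR peak tables
are built from exact stoichiometry with optional relative integral noise,
so they round-trip exactly at zero noise.

What this does **not** emulate: heteroscedastic or autocorrelated
measurement error, soil-to-soil microbial variability, non-first-order
tailing, and any mechanistic microbial growth — so passing recovery tests
demonstrates the estimators are correct and well-calibrated under the
stated noise model, not that real incubations obey it. The additive
Gaussian structure itself is an assumption (roughly constant error bars
across the mass range motivated it).

## Problem sizes and defaults

The parameter-recovery study simulates triplicate series at 12 time points
spanning the lag plus three decay time-constants (3/k) for each of the 14
published (soil, temperature) parameter rows, at 2 % absolute noise —
enough span to constrain both parameters without extrapolating past the
published incubation horizons. The test suite uses 200 noise seeds per row;
`scripts/acceptance.py` uses 100. The grid-search oracle used to
cross-check the NLS fit is a two-stage exhaustive search (coarse
200 × 161 grid over k ∈ [0.001, 0.4], L ∈ [0, t_max], then a 101 × 101
zoom around the coarse argmin).

## Known limitations

- Lag estimates for very slow treatments (k ≲ 0.001 d⁻¹) are weakly
  identified when the lag approaches the incubation length; the fit
  returns them with honest (large) standard errors rather than refusing.
- The Wald test on L is approximate near the L = 0 boundary; the nested
  comparison via AIC/BIC is reported alongside for that reason.
- Arrhenius fits assume a single apparent Ea across the fitted range;
  subset fitting is the provided remedy, not curvature models.
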
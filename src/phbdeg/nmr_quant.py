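"""Internal-standard quantitative 1H NMR of residual PHBHHx.

Converts peak-integral tables into (a) residual polymer mass via a known
mass of 1,4-dimethoxybenzene (DMB) internal standard and (b) the
3-hydroxyhexanoate comonomer content as mole percent of total monomer
units.  The module consumes integrals only; spectral acquisition,
phasing, baseline correction and peak deconvolution are upstream.

The quantification identity is the standard qNMR ratio: moles of an
analyte unit equal its per-proton integral relative to the per-proton
integral of the standard, times the moles of standard,

    n_analyte = (I_a / H_a) / (I_std / H_std) * (m_std / M_std).

Default diagnostic resonances are the 3-HB methyl (3 H per repeat unit),
the 3-HH terminal methyl (3 H per unit) and the 4 aromatic DMB protons;
all proton counts are carried per peak and overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "HB_UNIT_MASS",
    "HH_UNIT_MASS",
    "DMB_MOLAR_MASS",
    "Peak",
    "PeakTable",
    "InternalStandardSpec",
    "MonomerSpec",
    "QuantificationResult",
    "quantify_residual_mass",
    "hh_mole_fraction",
    "percent_residual",
]

#: Repeat-unit molar mass of 3-hydroxybutyrate, g/mol.
HB_UNIT_MASS = 86.09
#: Repeat-unit molar mass of 3-hydroxyhexanoate, g/mol.
HH_UNIT_MASS = 114.14
#: Molar mass of the 1,4-dimethoxybenzene internal standard, g/mol.
DMB_MOLAR_MASS = 138.16

#: Analyte concentration (mg/mL) below which quantification uncertainty
#: rises sharply due to spectral-deconvolution limits.
LOW_CONCENTRATION_THRESHOLD = 0.67

VALID_ASSIGNMENTS = ("internal_standard", "hb_diagnostic", "hh_diagnostic")


@dataclass(frozen=True)
class Peak:
    assignment: str
    integral: float
    protons_per_unit: int

    def __post_init__(self) -> None:
        if self.assignment not in VALID_ASSIGNMENTS:
            raise ValueError(
                f"assignment must be one of {VALID_ASSIGNMENTS}, got {self.assignment!r}"
            )
        if self.integral < 0:
            raise ValueError(f"integral must be >= 0, got {self.integral}")
        if not (int(self.protons_per_unit) == self.protons_per_unit and self.protons_per_unit >= 1):
            raise ValueError(f"protons_per_unit must be an integer >= 1, got {self.protons_per_unit}")


@dataclass(frozen=True)
class PeakTable:
    """A set of assigned peak integrals with exactly one internal standard."""

    peaks: Sequence[Peak]

    def __post_init__(self) -> None:
        std = [p for p in self.peaks if p.assignment == "internal_standard"]
        if len(std) != 1:
            raise ValueError(f"peak table must contain exactly one internal_standard peak, got {len(std)}")

    def get(self, assignment: str) -> Optional[Peak]:
        for p in self.peaks:
            if p.assignment == assignment:
                return p
        return None

    @property
    def standard(self) -> Peak:
        return self.get("internal_standard")


@dataclass(frozen=True)
class InternalStandardSpec:
    """Mass and identity of the internal standard in the measured tube."""

    mass_mg: float = 2.0
    molar_mass: float = DMB_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValueError(f"standard mass_mg must be > 0, got {self.mass_mg}")
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")


@dataclass(frozen=True)
class MonomerSpec:
    """Repeat-unit molar masses of the two PHBHHx monomers."""

    hb_unit_mass: float = HB_UNIT_MASS
    hh_unit_mass: float = HH_UNIT_MASS


@dataclass
class QuantificationResult:
    mass_mg: float
    hb_mmol: float
    hh_mmol: float
    flags: list = field(default_factory=list)


def _per_proton(peak: Optional[Peak]) -> float:
    return 0.0 if peak is None else peak.integral / peak.protons_per_unit


def quantify_residual_mass(
    peaks: PeakTable,
    standard: InternalStandardSpec = InternalStandardSpec(),
    monomers: MonomerSpec = MonomerSpec(),
    tube_volume_ml: Optional[float] = None,
) -> QuantificationResult:
    """Residual PHBHHx mass (mg) from a peak table by internal-standard ratio.

    A missing diagnostic peak contributes zero moles and raises a
    warning flag.  If ``tube_volume_ml`` is given, a low-concentration
    quality flag is attached when the implied analyte concentration
    falls below 0.67 mg/mL.
    """
    std_peak = peaks.standard
    if std_peak.integral <= 0:
        raise ValueError("internal standard integral must be > 0")
    n_std = standard.mass_mg / standard.molar_mass  # mmol
    std_per_proton = std_peak.integral / std_peak.protons_per_unit

    flags: list[str] = []
    moles = {}
    for name in ("hb_diagnostic", "hh_diagnostic"):
        peak = peaks.get(name)
        if peak is None:
            flags.append(f"missing_{name}")
            warnings.warn(f"peak table has no {name} peak; treating as zero moles", stacklevel=2)
            moles[name] = 0.0
        else:
            moles[name] = _per_proton(peak) / std_per_proton * n_std

    mass_mg = moles["hb_diagnostic"] * monomers.hb_unit_mass + moles["hh_diagnostic"] * monomers.hh_unit_mass
    if tube_volume_ml is not None and tube_volume_ml > 0:
        if mass_mg / tube_volume_ml < LOW_CONCENTRATION_THRESHOLD:
            flags.append("low_concentration")
    return QuantificationResult(
        mass_mg=mass_mg,
        hb_mmol=moles["hb_diagnostic"],
        hh_mmol=moles["hh_diagnostic"],
        flags=flags,
    )


def hh_mole_fraction(peaks: PeakTable) -> float:
    """3-HH content as mole percent of total (3-HB + 3-HH) monomer units.

    ``100 * (I_HH/H_HH) / (I_HB/H_HB + I_HH/H_HH)``; invariant to any
    uniform rescaling of the integrals.
    """
    hb = _per_proton(peaks.get("hb_diagnostic"))
    hh = _per_proton(peaks.get("hh_diagnostic"))
    if hb + hh <= 0:
        raise ValueError("both diagnostic integrals are zero; mole fraction undefined")
    return 100.0 * hh / (hb + hh)


def percent_residual(residual_mass_mg: float, initial_mass_mg: float) -> float:
    """Residual mass normalized to the initially added mass, in percent.

    Values above 100 % are permitted (measurement noise) but flagged via
    a warning.
    """
    if initial_mass_mg <= 0:
        raise ValueError(f"initial mass must be > 0, got {initial_mass_mg}")
    if residual_mass_mg < 0:
        raise ValueError(f"residual mass must be >= 0, got {residual_mass_mg}")
    pct = 100.0 * residual_mass_mg / initial_mass_mg
    if pct > 100.0:
        warnings.warn(f"residual percent {pct:.2f} exceeds 100 %", stacklevel=2)
    return pct
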
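"""End-to-end analysis pipeline: mass series -> kinetic fits -> Arrhenius -> Q10.

``run_pipeline`` composes the per-treatment shoulder-log-linear fits
(with lag-phase model selection), the per-soil/variant Arrhenius fits of
the selected rate constants, and the Q10 conversion, writing a flat
results table plus JSON records and a manifest with the configuration
hash and seed for reproducibility.  A treatment whose fit fails is
logged and skipped without aborting the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as pio
from .arrhenius import RateConstantSet, fit_arrhenius, q10_from_ea
from .kinetics import average_replicates, fit_shoulder_log_linear, select_model

logger = logging.getLogger("phbdeg")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``mass_csv`` (replicate-level residual-mass observations) or
    ``rates_csv`` (pre-fitted rate constants; skips the kinetics stage)
    must be provided.
    """

    output_dir: str | Path
    mass_csv: Optional[str | Path] = None
    rates_csv: Optional[str | Path] = None
    alpha: float = 0.05
    t_min_c: float = float("-inf")
    t_max_c: float = float("inf")
    q10_method: str = "geometric-mean"
    q10_t_low: float = 0.0
    q10_t_high: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mass_csv is None and self.rates_csv is None:
            raise ValueError("provide mass_csv and/or rates_csv")
        for attr in ("mass_csv", "rates_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{attr}: {path} does not exist")

    def config_hash(self) -> str:
        # output location does not affect the analysis, so it is excluded
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    kinetic_fits: dict = field(default_factory=dict)      # (soil, temp, variant) -> KineticFit
    arrhenius_fits: dict = field(default_factory=dict)    # (soil, variant) -> ArrheniusFit
    q10: dict = field(default_factory=dict)               # (soil, variant) -> Q10Result
    failures: list = field(default_factory=list)          # [(treatment key, message)]
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    if config.mass_csv is not None:
        datasets = pio.read_mass_csv(config.mass_csv)
        logger.info("loaded %d treatments from %s", len(datasets), config.mass_csv)
        for ds in datasets:
            key = (ds.treatment.soil, ds.treatment.temperature_c, ds.treatment.variant)
            try:
                series = average_replicates(ds)
                free = fit_shoulder_log_linear(series, fix_lag_to_zero=False)
                zero = fit_shoulder_log_linear(series, fix_lag_to_zero=True)
                if not (free.converged and zero.converged):
                    raise RuntimeError(f"fit failed: {free.message or zero.message}")
                chosen = select_model(free, zero, alpha=config.alpha)
                result.kinetic_fits[key] = chosen
                logger.info("fitted %s: %s model, k=%.4g d^-1, lag=%.3g d",
                            key, chosen.variant, chosen.k_hat, chosen.lag_hat)
            except Exception as exc:
                result.failures.append((key, str(exc)))
                logger.warning("treatment %s failed: %s", key, exc)

    # Assemble rate constants: fitted ones plus any supplied directly.
    rate_sets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (soil, temp, variant), fit in result.kinetic_fits.items():
        if fit.k_hat > 0:
            rate_sets.setdefault((soil, variant), []).append((temp, fit.k_hat))
    if config.rates_csv is not None:
        for rset in pio.read_rate_csv(config.rates_csv):
            rate_sets.setdefault((rset.soil, rset.variant), []).extend(rset.points)

    for (soil, variant), points in rate_sets.items():
        usable = [(t, k) for t, k in points if config.t_min_c <= t <= config.t_max_c]
        if len(usable) < 2:
            result.failures.append(((soil, variant), "fewer than 2 rate constants in range"))
            continue
        rset = RateConstantSet(soil=soil, variant=variant, points=usable)
        afit = fit_arrhenius(rset)
        result.arrhenius_fits[(soil, variant)] = afit
        result.q10[(soil, variant)] = q10_from_ea(
            afit.ea, config.q10_t_low, config.q10_t_high, config.q10_method
        )
        logger.info("Arrhenius %s/%s: Ea=%.1f kJ/mol, R^2=%.3f",
                    soil, variant, afit.ea / 1000.0, afit.r_squared)

    # Outputs
    if result.kinetic_fits:
        pio.kinetic_fits_to_table(result.kinetic_fits).to_csv(
            out_dir / "kinetic_fits.csv", index=False
        )
        pio.write_json(
            {"/".join(map(str, k)): pio.fit_to_dict(v) for k, v in result.kinetic_fits.items()},
            out_dir / "kinetic_fits.json",
        )
    if result.arrhenius_fits:
        pio.write_json(
            {"/".join(k): pio.fit_to_dict(v) for k, v in result.arrhenius_fits.items()},
            out_dir / "arrhenius_fits.json",
        )
        pio.write_json(
            {"/".join(k): pio.fit_to_dict(v) for k, v in result.q10.items()},
            out_dir / "q10.json",
        )

    from . import __version__

    result.manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_treatments_in": len(result.kinetic_fits) + len(result.failures),
        "n_treatments_fitted": len(result.kinetic_fits),
        "failures": [{"treatment": list(map(str, k)), "error": m} for k, m in result.failures],
    }
    pio.write_json(result.manifest, out_dir / "manifest.json")
    return result
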
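"""File schemas: CSV readers/writers and JSON serialization.

All CSV files use explicit headers, UTF-8 and period decimal separators;
temperatures are degrees Celsius on disk (Kelvin exists only inside the
Arrhenius math).  Every writer's output is readable by its paired
reader with equality of all numeric fields.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .arrhenius import ArrheniusFit, Q10Result, RateConstantSet
from .kinetics import KineticFit
from .nmr_quant import Peak, PeakTable
from .synthetic_data import ResidualMassDataset, Treatment

MASS_COLUMNS = ["soil", "temperature_c", "variant",
                "time_d", "replicate", "initial_mass_mg", "residual_mass_mg", "residual_percent"]
RATE_COLUMNS = ["soil", "variant", "temperature_c", "k_per_day"]
PEAK_COLUMNS = ["assignment", "integral", "protons_per_unit"]


def write_mass_csv(datasets: Iterable[ResidualMassDataset], path: str | Path) -> None:
    frames = []
    for ds in datasets:
        df = ds.observations.copy()
        df.insert(0, "soil", ds.treatment.soil)
        df.insert(1, "temperature_c", ds.treatment.temperature_c)
        df.insert(2, "variant", ds.treatment.variant)
        frames.append(df[MASS_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mass_csv(path: str | Path) -> list[ResidualMassDataset]:
    """One dataset per (soil, temperature, variant) group, in file order."""
    df = pd.read_csv(path)
    _require_columns(df, MASS_COLUMNS, path)
    out = []
    for (soil, temp, variant), group in df.groupby(
        ["soil", "temperature_c", "variant"], sort=False
    ):
        out.append(
            ResidualMassDataset(
                treatment=Treatment(soil=soil, temperature_c=float(temp), variant=variant),
                observations=group[list(ResidualMassDataset.COLUMNS)].reset_index(drop=True),
            )
        )
    return out


def write_rate_csv(sets: Iterable[RateConstantSet], path: str | Path) -> None:
    rows = [
        {"soil": s.soil, "variant": s.variant, "temperature_c": t, "k_per_day": k}
        for s in sets
        for t, k in s.points
    ]
    pd.DataFrame(rows, columns=RATE_COLUMNS).to_csv(path, index=False)


def read_rate_csv(path: str | Path) -> list[RateConstantSet]:
    df = pd.read_csv(path)
    _require_columns(df, RATE_COLUMNS, path)
    out = []
    for (soil, variant), group in df.groupby(["soil", "variant"], sort=False):
        out.append(
            RateConstantSet(
                soil=soil,
                variant=variant,
                points=list(zip(group["temperature_c"].astype(float), group["k_per_day"].astype(float))),
            )
        )
    return out


def read_peak_csv(path: str | Path) -> PeakTable:
    df = pd.read_csv(path)
    _require_columns(df, PEAK_COLUMNS, path)
    peaks = [
        Peak(assignment=row.assignment, integral=float(row.integral),
             protons_per_unit=int(row.protons_per_unit))
        for row in df.itertuples()
    ]
    return PeakTable(peaks=peaks)


def write_peak_csv(table: PeakTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"assignment": p.assignment, "integral": p.integral, "protons_per_unit": p.protons_per_unit}
         for p in table.peaks],
        columns=PEAK_COLUMNS,
    ).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; found {list(df.columns)}")


_COMPARISON_STATS = ("variant", "k_hat", "lag_hat", "p_lag", "rss",
                     "aic", "bic", "chi_squared", "neg2loglik")


def _jsonable(obj):
    from .kinetics import ModelComparison

    if isinstance(obj, ModelComparison):
        # the comparison references the selected fit itself; emit only the
        # per-variant statistics to keep the JSON acyclic
        return {
            "alpha": obj.alpha,
            "lag_significant": obj.lag_significant,
            "selected_variant": obj.selected_variant,
            "free_lag": {k: _jsonable(getattr(obj.free_lag, k)) for k in _COMPARISON_STATS},
            "lag_zero": {k: _jsonable(getattr(obj.lag_zero, k)) for k in _COMPARISON_STATS},
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, float):
        return None if not math.isfinite(obj) else obj
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def fit_to_dict(fit) -> dict:
    """Serialize a KineticFit / ArrheniusFit / Q10Result to plain JSON types.

    Non-finite floats become null (JSON has no NaN/inf)."""
    return _jsonable(fit)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n", encoding="utf-8")


def kinetic_fits_to_table(fits: dict[tuple[str, float, str], KineticFit]) -> pd.DataFrame:
    """Flat summary of selected fits, one row per treatment, mirroring a
    rate-constant/lag-phase results table."""
    rows = []
    for (soil, temp, variant), fit in fits.items():
        rows.append(
            {
                "soil": soil, "temperature_c": temp, "variant": variant,
                "k": fit.k_hat, "se_k": fit.se_k, "p_k": fit.p_k,
                "lag": fit.lag_hat, "se_lag": fit.se_lag, "p_lag": fit.p_lag,
                "r_squared": fit.r_squared, "model": fit.variant,
            }
        )
    return pd.DataFrame(rows)
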
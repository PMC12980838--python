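"""Quantification of microbial colonization on polymer films from label masks.

SEM mosaics of incubated films are segmented upstream into four classes:
intact film, skeletonized hyphae (one-pixel-wide centerlines of
filamentous structures), densely colonized regions where individual
hyphae are no longer distinguishable ("colony"), and fully eroded
regions ("hole").  This module computes the summary statistics from such
label masks:

* total hyphal length per unit film area (mm/mm^2), from the skeleton
  using the orthogonal/diagonal step metric (1 px for 4-neighbor steps,
  sqrt(2) px for diagonal steps);
* area fractions of colony, hole, and intact film, where
  skeleton pixels count toward the intact-film area so the three
  fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_INTACT",
    "CLASS_SKELETON",
    "CLASS_COLONY",
    "CLASS_HOLE",
    "ColonizationMask",
    "ColonizationSummary",
    "hyphal_length",
    "area_fractions",
    "summarize",
    "read_mask",
]

CLASS_INTACT = 0
CLASS_SKELETON = 1
CLASS_COLONY = 2
CLASS_HOLE = 3
_VALID_CLASSES = frozenset({CLASS_INTACT, CLASS_SKELETON, CLASS_COLONY, CLASS_HOLE})

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ColonizationMask:
    """A 2-D class-label image with physical pixel size in micrometers."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        present = set(np.unique(labels).tolist())
        if not present <= _VALID_CLASSES:
            raise ValueError(f"unknown class values {sorted(present - _VALID_CLASSES)}; "
                             "expected 0 intact, 1 skeleton, 2 colony, 3 hole")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))


@dataclass(frozen=True)
class ColonizationSummary:
    hyphal_length_per_area: float  # mm / mm^2
    colony_fraction: float
    hole_fraction: float
    intact_fraction: float
    imaged_area_mm2: float


def _skeleton_length_px(skeleton: np.ndarray) -> float:
    """Total skeleton length in pixel units: each 4-neighbor adjacency of
    skeleton pixels contributes 1, each diagonal adjacency sqrt(2); every
    unordered pixel pair is counted once."""
    s = skeleton.astype(bool)
    horizontal = np.count_nonzero(s[:, :-1] & s[:, 1:])
    vertical = np.count_nonzero(s[:-1, :] & s[1:, :])
    diag_main = np.count_nonzero(s[:-1, :-1] & s[1:, 1:])
    diag_anti = np.count_nonzero(s[:-1, 1:] & s[1:, :-1])
    return float(horizontal + vertical) + SQRT2 * float(diag_main + diag_anti)


def hyphal_length(mask: ColonizationMask) -> float:
    """Total hyphal skeleton length per unit imaged area, mm/mm^2."""
    um_per_px = mask.pixel_size_um
    length_mm = _skeleton_length_px(mask.labels == CLASS_SKELETON) * um_per_px / 1000.0
    area_mm2 = mask.labels.size * (um_per_px / 1000.0) ** 2
    return length_mm / area_mm2


def area_fractions(mask: ColonizationMask) -> tuple[float, float, float]:
    """(colony, hole, intact) area fractions; skeleton pixels count as
    intact film, so the three fractions sum to one."""
    total = mask.labels.size
    colony = np.count_nonzero(mask.labels == CLASS_COLONY) / total
    hole = np.count_nonzero(mask.labels == CLASS_HOLE) / total
    return colony, hole, 1.0 - colony - hole


def summarize(mask: ColonizationMask) -> ColonizationSummary:
    colony, hole, intact = area_fractions(mask)
    return ColonizationSummary(
        hyphal_length_per_area=hyphal_length(mask),
        colony_fraction=colony,
        hole_fraction=hole,
        intact_fraction=intact,
        imaged_area_mm2=mask.labels.size * (mask.pixel_size_um / 1000.0) ** 2,
    )


def read_mask(path: str | Path, pixel_size_um: float) -> ColonizationMask:
    """Read an 8-bit single-channel PNG/TIFF label image
    (0 intact, 1 skeleton, 2 colony, 3 hole)."""
    import imageio.v3 as iio

    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:  # collapse a redundant channel axis if present
        if labels.shape[2] not in (1,) and not np.all(labels[..., :1] == labels[..., :3]):
            raise ValueError(f"{path}: expected a single-channel label image")
        labels = labels[..., 0]
    return ColonizationMask(labels=labels, pixel_size_um=pixel_size_um)
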
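"""Fractional-landcover accounting over catchment masks.

Per-pixel class fractions (e.g. urban, cropland) on a regular grid are
thresholded — a pixel counts toward a class when its fraction strictly
exceeds 50% — and summed to per-catchment class areas and ratios. A
straight-line distance from the catchment outlet to the nearest urban
pixel is also provided as a crude proximity descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FractionGrid",
    "CatchmentMask",
    "class_area",
    "class_ratio",
    "distance_to_nearest_urban",
]

CLASSES = frozenset({"urban", "cropland", "other"})


@dataclass(frozen=True)
class FractionGrid:
    """Row-major fraction grid, origin upper-left, square pixels."""

    class_name: str
    pixel_size_m: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.class_name not in CLASSES:
            raise ValueError(f"unknown landcover class {self.class_name!r}")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("fraction grid must be 2-D")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CatchmentMask:
    """Boolean membership grid with the catchment outlet pixel (row, col)."""

    member: np.ndarray = field(repr=False)
    outlet: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        m = np.asarray(self.member, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("mask must contain at least one member pixel")
        r, c = self.outlet
        if not (0 <= r < m.shape[0] and 0 <= c < m.shape[1]):
            raise ValueError("outlet lies outside the grid")
        object.__setattr__(self, "member", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.member.shape

    @property
    def area_km2_factory(self) -> float:  # pragma: no cover - convenience only
        return float(self.member.sum())


def _check_shapes(grid: FractionGrid, mask: CatchmentMask) -> None:
    if grid.shape != mask.shape:
        raise ValueError(f"grid shape {grid.shape} != mask shape {mask.shape}")


def class_area(
    grid: FractionGrid, mask: CatchmentMask, threshold: float = 0.5
) -> float:
    """Area (km^2) of member pixels whose class fraction exceeds the threshold.

    The comparison is strict (> threshold), so a pixel at exactly 50% does
    not count toward the class.
    """
    _check_shapes(grid, mask)
    n = int(np.count_nonzero(mask.member & (grid.values > threshold)))
    return n * grid.pixel_size_m**2 * 1e-6


def class_ratio(class_area_km2: float, catchment_area_km2: float) -> float:
    """Class area as a percentage of the catchment area."""
    if catchment_area_km2 <= 0:
        raise ValueError("catchment area must be positive")
    return 100.0 * class_area_km2 / catchment_area_km2


def distance_to_nearest_urban(
    mask: CatchmentMask, urban_grid: FractionGrid, threshold: float = 0.5
) -> float | None:
    """Euclidean distance (km) from the outlet to the nearest urban pixel.

    Distances are measured between pixel centers. Returns None when no
    pixel exceeds the threshold (no urban presence on the grid).
    """
    _check_shapes(urban_grid, mask)
    urban = np.argwhere(urban_grid.values > threshold)
    if urban.size == 0:
        return None
    outlet = np.asarray(mask.outlet, dtype=float)
    d_pix = np.sqrt(((urban - outlet) ** 2).sum(axis=1)).min()
    return float(d_pix * urban_grid.pixel_size_m / 1000.0)
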
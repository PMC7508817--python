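"""Floating-vegetation cover time series and the areas feeding the budget.

Cover observations (already-extracted areas from satellite or field
surveys) are composited into two-month bins, summarised into annual peak
cover, and converted into the effective export areas the nutrient budget
consumes: either full channel coverage of a reach (conservative annual
export at a choke point) or a narrow fringing strip along the banks.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .budget import VegArea

__all__ = [
    "CoverObservation",
    "ReachGeometry",
    "PeriodSpec",
    "composite_bimonthly",
    "peak_annual_cover",
    "full_coverage_area",
    "fringe_area",
    "period_stats",
]

SENSORS = frozenset({"landsat", "highres", "field"})


@dataclass(frozen=True)
class CoverObservation:
    site: str
    date: _date
    cover_km2: float
    sensor: str = "landsat"

    def __post_init__(self) -> None:
        if self.cover_km2 < 0:
            raise ValueError("cover area cannot be negative")
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}")


@dataclass(frozen=True)
class ReachGeometry:
    """Geometry of a monitored stream reach; optional fields may be None."""

    length_km: float
    channel_area_km2: float | None = None
    fringe_width_m: float | None = None
    fringe_length_km: float | None = None

    def __post_init__(self) -> None:
        for name in ("length_km", "channel_area_km2", "fringe_width_m", "fringe_length_km"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class PeriodSpec:
    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("period start must not follow its end")


def _bin_index(month: int) -> int:
    """Calendar-aligned two-month bin: 0 = Jan-Feb ... 5 = Nov-Dec."""
    return (month - 1) // 2


def composite_bimonthly(obs: list[CoverObservation]) -> pd.DataFrame:
    """Maximum observed cover per calendar-aligned two-month bin.

    Returns columns (year, bin, max_cover_km2) with six possible bins per
    year (0 = Jan-Feb ... 5 = Nov-Dec); bins with no observations are
    simply absent. The per-bin maximum, not the mean, is used because
    peak standing cover is the export proxy.
    """
    rows = [
        {"year": o.date.year, "bin": _bin_index(o.date.month), "max_cover_km2": o.cover_km2}
        for o in obs
    ]
    if not rows:
        return pd.DataFrame(columns=["year", "bin", "max_cover_km2"])
    df = pd.DataFrame(rows)
    out = df.groupby(["year", "bin"], as_index=False)["max_cover_km2"].max()
    return out.sort_values(["year", "bin"], ignore_index=True)


def peak_annual_cover(obs: list[CoverObservation]) -> pd.Series:
    """Maximum cover (km^2) per calendar year, indexed by year."""
    if not obs:
        return pd.Series(dtype=float, name="peak_cover_km2")
    df = pd.DataFrame({"year": [o.date.year for o in obs], "cover": [o.cover_km2 for o in obs]})
    peaks = df.groupby("year")["cover"].max()
    peaks.name = "peak_cover_km2"
    return peaks


def full_coverage_area(
    reach: ReachGeometry,
    mean_width_m: float | None = None,
    site: str = "",
) -> VegArea:
    """Channel area of a reach under complete floating-vegetation coverage.

    Uses the surveyed channel area when present, otherwise reach length
    times a mean channel width. Complete coverage of a choke-point reach
    is a conservative stand-in for annual biomass export.
    """
    if reach.channel_area_km2 is not None:
        area = reach.channel_area_km2
    elif mean_width_m is not None:
        if mean_width_m <= 0:
            raise ValueError("mean channel width must be positive")
        area = reach.length_km * mean_width_m / 1000.0
    else:
        raise ValueError(
            "need either channel_area_km2 or a mean channel width to compute full coverage"
        )
    return VegArea(site=site, area_km2=area, basis="full_coverage")


def fringe_area(width_m: float, length_km: float, site: str = "") -> VegArea:
    """Area of a fringing vegetation strip: width (m) x length (km) in km^2."""
    if width_m <= 0 or length_km <= 0:
        raise ValueError("fringe width and length must be positive")
    return VegArea(site=site, area_km2=width_m / 1000.0 * length_km, basis="fringe")


def period_stats(
    obs: list[CoverObservation], periods: list[PeriodSpec]
) -> tuple[pd.DataFrame, int]:
    """Summarise the bimonthly-composited series within labelled year ranges.

    For each period reports the mean and max of bin maxima and the fraction
    of observed bins with nonzero cover; a period with no observations is
    flagged absent (NaN stats). Returns (summary, n_outside) where
    ``n_outside`` counts observations falling outside every period.

    Raises if the periods overlap.
    """
    for i, p in enumerate(periods):
        for q in periods[i + 1 :]:
            if p.start_year <= q.end_year and q.start_year <= p.end_year:
                raise ValueError(f"periods {p.label!r} and {q.label!r} overlap")
    binned = composite_bimonthly(obs)
    covered_years: set[int] = set()
    rows = []
    for p in periods:
        covered_years.update(range(p.start_year, p.end_year + 1))
        sel = binned[(binned["year"] >= p.start_year) & (binned["year"] <= p.end_year)]
        if sel.empty:
            rows.append(
                {"label": p.label, "mean_cover_km2": np.nan, "max_cover_km2": np.nan,
                 "frac_bins_nonzero": np.nan, "n_bins": 0}
            )
        else:
            vals = sel["max_cover_km2"]
            rows.append(
                {"label": p.label, "mean_cover_km2": float(vals.mean()),
                 "max_cover_km2": float(vals.max()),
                 "frac_bins_nonzero": float((vals > 0).mean()), "n_bins": int(len(vals))}
            )
    n_outside = sum(1 for o in obs if o.date.year not in covered_years)
    return pd.DataFrame(rows), n_outside
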
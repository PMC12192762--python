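"""Suitability binning, area accounting and centroid-shift analysis.

Suitability classes follow the four-band probability scheme: unsuitable
(p < 0.05), low (0.05 <= p < 0.33), medium (0.33 <= p < 0.66), high
(p >= 0.66).  Areas are reported in units of 10^4 km²; change percentages
are rounded half-up to two decimals only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .grid_io import EnvGrid
from .maxent_core import SuitabilityMap
from .preprocess import KM_PER_DEG

__all__ = [
    "CLASS_NAMES",
    "ClassifiedMap",
    "ClassBreakdown",
    "CentroidRecord",
    "classify_suitability",
    "class_areas",
    "area_change",
    "round_change",
    "centroid_shift",
    "haversine_km",
]

CLASS_NAMES = ("unsuitable", "low", "medium", "high")
SUITABLE_CLASSES = ("low", "medium", "high")

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClassifiedMap:
    """Per-cell suitability class codes 0..3 (nodata keeps the sentinel)."""

    codes: EnvGrid
    thresholds: tuple[float, float, float]
    scenario: str = ""

    def class_mask(self, name: str) -> np.ndarray:
        code = CLASS_NAMES.index(name)
        return self.codes.valid_mask & (self.codes.values == code)


def classify_suitability(
    smap: SuitabilityMap, thresholds: tuple[float, float, float] = (0.05, 0.33, 0.66)
) -> ClassifiedMap:
    """Bin a logistic map into the four suitability classes."""
    if smap.transform != "logistic":
        raise ValueError("classification requires a logistic-transform map")
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly increasing")
    g = smap.grid
    m = g.valid_mask
    p = g.values
    codes = np.full(p.shape, g.nodata_value, dtype=float)
    codes[m] = 0.0
    codes[m & (p >= t1)] = 1.0
    codes[m & (p >= t2)] = 2.0
    codes[m & (p >= t3)] = 3.0
    return ClassifiedMap(
        codes=g.like(codes, nodata_mask=~m),
        thresholds=(t1, t2, t3),
        scenario=smap.scenario,
    )


@dataclass
class ClassBreakdown:
    """Per-class areas in 10^4 km² (plus the unsuitable remainder)."""

    areas: dict[str, float]
    scenario: str = ""
    decade: str = ""

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.areas)
        if missing:
            raise ValueError(f"breakdown missing classes: {sorted(missing)}")

    @property
    def total_suitable(self) -> float:
        return sum(self.areas[c] for c in SUITABLE_CLASSES)

    @property
    def total_area(self) -> float:
        return self.total_suitable + self.areas["unsuitable"]

    @classmethod
    def from_suitable(
        cls, low: float, medium: float, high: float, unsuitable: float = 0.0, **kw
    ) -> "ClassBreakdown":
        return cls(
            areas={"unsuitable": unsuitable, "low": low, "medium": medium, "high": high},
            **kw,
        )


def _cell_areas_km2(grid: EnvGrid, crs_mode: str) -> np.ndarray:
    """(nrows, ncols) per-cell area in km²."""
    if crs_mode == "planar":
        return np.full((grid.nrows, grid.ncols), grid.cellsize**2)
    # geographic: equirectangular cell scaled by cos(latitude of the row
    # centre); 1 degree = 111.32 km along a meridian
    rows = np.arange(grid.nrows)
    lat = grid.yllcorner + (grid.nrows - rows - 0.5) * grid.cellsize
    row_area = (grid.cellsize * KM_PER_DEG) ** 2 * np.cos(np.deg2rad(lat))
    return np.broadcast_to(row_area[:, None], (grid.nrows, grid.ncols)).copy()


def class_areas(cmap: ClassifiedMap, crs_mode: str = "geographic") -> ClassBreakdown:
    """Sum per-class cell areas, reported in 10^4 km²."""
    cell = _cell_areas_km2(cmap.codes, crs_mode)
    areas = {}
    for name in CLASS_NAMES:
        areas[name] = float(cell[cmap.class_mask(name)].sum()) / 1e4
    return ClassBreakdown(areas=areas, scenario=cmap.scenario)


def area_change(current: ClassBreakdown, future: ClassBreakdown) -> dict[str, float | None]:
    """Percent change per class and for the suitable total (unrounded).

    Classes with a zero current area get ``None`` (undefined change).
    """
    out: dict[str, float | None] = {}
    for name in CLASS_NAMES:
        cur, fut = current.areas[name], future.areas[name]
        out[name] = None if cur == 0 else 100.0 * (fut - cur) / cur
    cur_t, fut_t = current.total_suitable, future.total_suitable
    out["total_suitable"] = None if cur_t == 0 else 100.0 * (fut_t - cur_t) / cur_t
    return out


def round_change(value: float | None, decimals: int = 2) -> float | None:
    """Half-up rounding for reported percentages."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def breakdown_table(
    breakdowns: list[ClassBreakdown], baseline: ClassBreakdown
) -> pd.DataFrame:
    """Table of areas and (rounded) change percentages vs a baseline."""
    rows = []
    for bd in breakdowns:
        chg = area_change(baseline, bd)
        rows.append(
            {
                "scenario": bd.scenario,
                "decade": bd.decade,
                "total_suitable": bd.total_suitable,
                "total_change_pct": round_change(chg["total_suitable"]),
                "low": bd.areas["low"],
                "low_change_pct": round_change(chg["low"]),
                "medium": bd.areas["medium"],
                "medium_change_pct": round_change(chg["medium"]),
                "high": bd.areas["high"],
                "high_change_pct": round_change(chg["high"]),
            }
        )
    return pd.DataFrame(rows)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def _bearing_deg(lon1, lat1, lon2, lat2, crs_mode: str) -> float:
    if crs_mode == "planar":
        ang = math.degrees(math.atan2(lon2 - lon1, lat2 - lat1))
    else:
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dl = math.radians(lon2 - lon1)
        y = math.sin(dl) * math.cos(p2)
        x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
        ang = math.degrees(math.atan2(y, x))
    return ang % 360.0


@dataclass
class CentroidRecord:
    """Weighted centroid of the high-suitability class and its shift."""

    scenario: str
    lon: float | None
    lat: float | None
    shift_km: float | None = None
    bearing_deg: float | None = None
    empty: bool = False
    weighted: bool = True


def _centroid(
    cmap: ClassifiedMap, smap: SuitabilityMap, weighted: bool
) -> tuple[float, float] | None:
    mask = cmap.class_mask("high")
    if not mask.any():
        return None
    g = cmap.codes
    x, y = g.cell_centers()
    w = smap.grid.values[mask] if weighted else np.ones(int(mask.sum()))
    w = np.maximum(w, 0.0)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return (
        float(np.average(x[mask], weights=w)),
        float(np.average(y[mask], weights=w)),
    )


def centroid_shift(
    baseline_cmap: ClassifiedMap,
    baseline_smap: SuitabilityMap,
    scenario_cmap: ClassifiedMap,
    scenario_smap: SuitabilityMap,
    crs_mode: str = "geographic",
    weighted: bool = True,
) -> CentroidRecord:
    """Shift of the suitability-weighted high-class centroid between a
    baseline and a scenario map (haversine distance + initial bearing in
    geographic mode, Euclidean in planar mode)."""
    if not baseline_cmap.codes.geometry_equal(scenario_cmap.codes):
        raise ValueError("baseline and scenario maps must share geometry")
    c0 = _centroid(baseline_cmap, baseline_smap, weighted)
    c1 = _centroid(scenario_cmap, scenario_smap, weighted)
    if c0 is None or c1 is None:
        return CentroidRecord(
            scenario=scenario_cmap.scenario,
            lon=None if c1 is None else c1[0],
            lat=None if c1 is None else c1[1],
            empty=True,
            weighted=weighted,
        )
    if crs_mode == "planar":
        dist = math.hypot(c1[0] - c0[0], c1[1] - c0[1])
    else:
        dist = haversine_km(c0[0], c0[1], c1[0], c1[1])
    bearing = _bearing_deg(c0[0], c0[1], c1[0], c1[1], crs_mode)
    return CentroidRecord(
        scenario=scenario_cmap.scenario,
        lon=c1[0],
        lat=c1[1],
        shift_km=dist,
        bearing_deg=bearing,
        weighted=weighted,
    )


def centroid_table(records: list[CentroidRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "lon": r.lon,
                "lat": r.lat,
                "distance_km": r.shift_km,
                "bearing_deg": r.bearing_deg,
                "empty_high_class": r.empty,
                "weighted": r.weighted,
            }
            for r in records
        ]
    )
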
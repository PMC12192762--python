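"""Occurrence handling and collinearity pruning.

Spatial thinning keeps at most one record per square grid cell of a given
edge length (km); Pearson-correlation pruning drops one member of every
over-threshold variable pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_io import EnvGridStack

__all__ = [
    "OccurrenceSet",
    "SampleMatrix",
    "CorrelationReport",
    "thin_occurrences",
    "extract_samples",
    "correlation_filter",
    "univariate_gain_priority",
    "KM_PER_DEG",
]

log = logging.getLogger(__name__)

#: kilometres per degree of latitude (equirectangular approximation)
KM_PER_DEG = 111.32


@dataclass
class OccurrenceSet:
    """Ordered species presence coordinates (lon, lat) or planar (x, y)."""

    species: str
    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = np.empty((0, 2))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        for need in ("species", "longitude", "latitude"):
            if need not in cols:
                raise ValueError(f"occurrence CSV missing column {need!r}")
        species = str(df[cols["species"]].iloc[0]) if len(df) else "unknown"
        pts = df[[cols["longitude"], cols["latitude"]]].to_numpy(dtype=float)
        return cls(species=species, points=pts)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "species": [self.species] * len(self),
                "longitude": self.points[:, 0],
                "latitude": self.points[:, 1],
            }
        ).to_csv(path, index=False)


@dataclass
class SampleMatrix:
    """Presence + background rows of environmental values.

    ``values`` is ``(n, d)``; ``is_presence`` flags presence rows;
    ``coords`` holds each row's (lon, lat).
    """

    variable_names: list[str]
    values: np.ndarray
    is_presence: np.ndarray
    coords: np.ndarray
    n_dropped_presences: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.is_presence = np.asarray(self.is_presence, dtype=bool)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variable_names):
            raise ValueError("values shape inconsistent with variable_names")
        if not np.isfinite(self.values).all():
            raise ValueError("sample matrix contains non-finite values")

    @property
    def n_presence(self) -> int:
        return int(self.is_presence.sum())

    @property
    def n_background(self) -> int:
        return int((~self.is_presence).sum())

    @property
    def presence_values(self) -> np.ndarray:
        return self.values[self.is_presence]

    @property
    def background_values(self) -> np.ndarray:
        return self.values[~self.is_presence]

    def select(self, names: Sequence[str]) -> "SampleMatrix":
        """Column subset, preserving rows."""
        idx = [self.variable_names.index(n) for n in names]
        return SampleMatrix(
            variable_names=list(names),
            values=self.values[:, idx],
            is_presence=self.is_presence.copy(),
            coords=self.coords.copy(),
            n_dropped_presences=self.n_dropped_presences,
        )

    def take_presences(self, idx: np.ndarray) -> "SampleMatrix":
        """Keep the given presence rows (indices into presence rows) plus
        every background row."""
        pres = np.flatnonzero(self.is_presence)[np.asarray(idx, dtype=int)]
        rows = np.concatenate([pres, np.flatnonzero(~self.is_presence)])
        return SampleMatrix(
            variable_names=list(self.variable_names),
            values=self.values[rows],
            is_presence=self.is_presence[rows],
            coords=self.coords[rows],
            n_dropped_presences=self.n_dropped_presences,
        )


def thin_occurrences(
    occ: OccurrenceSet,
    cell_km: float = 4.5,
    anchor: tuple[float, float] | None = None,
    ref_latitude: float | None = None,
    crs_mode: str = "geographic",
) -> OccurrenceSet:
    """Keep at most one record per ``cell_km`` × ``cell_km`` grid cell.

    Geographic coordinates are mapped to kilometres with an equirectangular
    conversion at ``ref_latitude`` (default: mean latitude of the input);
    planar coordinates are assumed to already be kilometres.  The first
    record (input order) in each cell is kept and input order is preserved.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be > 0")
    if len(occ) == 0:
        return OccurrenceSet(species=occ.species, points=np.empty((0, 2)))
    pts = occ.points
    if crs_mode == "geographic":
        lat0 = float(np.mean(pts[:, 1])) if ref_latitude is None else float(ref_latitude)
        x_km = pts[:, 0] * KM_PER_DEG * np.cos(np.deg2rad(lat0))
        y_km = pts[:, 1] * KM_PER_DEG
        if anchor is not None:
            ax = anchor[0] * KM_PER_DEG * np.cos(np.deg2rad(lat0))
            ay = anchor[1] * KM_PER_DEG
        else:
            ax, ay = x_km.min(), y_km.min()
    else:
        x_km, y_km = pts[:, 0], pts[:, 1]
        if anchor is not None:
            ax, ay = anchor
        else:
            ax, ay = x_km.min(), y_km.min()
    ci = np.floor((x_km - ax) / cell_km).astype(int)
    ri = np.floor((y_km - ay) / cell_km).astype(int)
    seen: set[tuple[int, int]] = set()
    keep = []
    for i, key in enumerate(zip(ri, ci)):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return OccurrenceSet(species=occ.species, points=pts[keep])


def extract_samples(
    stack: EnvGridStack,
    occ: OccurrenceSet,
    n_background: int = 10_000,
    seed: int | None = None,
) -> SampleMatrix:
    """Build presence + background rows from a stack.

    Presence rows take the layer values of the cell containing each point;
    points on NODATA cells are dropped (count logged).  Background rows are
    ``n_background`` valid cells sampled uniformly without replacement
    (capped at the number of valid cells only by an explicit error).
    """
    tmpl = stack.template
    names = stack.names
    vm = stack.valid_mask
    n_valid = int(vm.sum())
    if n_background > n_valid:
        raise ValueError(
            f"n_background={n_background} exceeds number of valid cells ({n_valid})"
        )
    pres_rows = []
    pres_coords = []
    dropped = 0
    for x, y in occ.points:
        rc = tmpl.cell_of(x, y)
        if rc is None:
            raise ValueError(f"occurrence ({x}, {y}) lies outside the grid bounds")
        r, c = rc
        if not vm[r, c]:
            dropped += 1
            continue
        pres_rows.append([stack.layers[n].values[r, c] for n in names])
        pres_coords.append([x, y])
    if dropped:
        log.info("extract_samples: dropped %d occurrence(s) on NODATA cells", dropped)

    rng = np.random.default_rng(seed)
    valid_rc = stack.valid_rc()
    pick = rng.choice(n_valid, size=n_background, replace=False)
    rr, cc = valid_rc[pick, 0], valid_rc[pick, 1]
    bg_rows = np.column_stack([stack.layers[n].values[rr, cc] for n in names])
    bx = tmpl.xllcorner + (cc + 0.5) * tmpl.cellsize
    by = tmpl.yllcorner + (tmpl.nrows - rr - 0.5) * tmpl.cellsize

    np_pres = len(pres_rows)
    values = np.vstack([np.array(pres_rows).reshape(np_pres, len(names)), bg_rows])
    coords = np.vstack(
        [np.array(pres_coords).reshape(np_pres, 2), np.column_stack([bx, by])]
    )
    is_presence = np.concatenate(
        [np.ones(np_pres, dtype=bool), np.zeros(n_background, dtype=bool)]
    )
    return SampleMatrix(
        variable_names=names,
        values=values,
        is_presence=is_presence,
        coords=coords,
        n_dropped_presences=dropped,
    )


@dataclass
class CorrelationReport:
    """Result of greedy Pearson pruning over candidate variables."""

    names: list[str]
    matrix: np.ndarray
    dropped: list[tuple[str, str, float]]  # (dropped, kept, r)
    retained: list[str]
    warnings: list[str] = field(default_factory=list)

    def matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.names, columns=self.names)


def correlation_filter(
    stack: EnvGridStack,
    candidates: Sequence[str] | None = None,
    threshold: float = 0.8,
    priority: Mapping[str, float] | None = None,
) -> CorrelationReport:
    """Greedy pruning of over-correlated layers.

    Pearson r is computed over all valid cells.  Pairs with ``|r| >
    threshold`` are visited in decreasing ``|r|``; within a pair the
    lower-priority variable is dropped (higher score in ``priority`` wins;
    ties keep the alphabetically earlier name).  Zero-variance layers are
    dropped up front with a warning.
    """
    names = list(candidates) if candidates is not None else stack.names
    if len(names) < 2:
        raise ValueError("correlation_filter needs at least 2 candidate variables")
    X = stack.table(names)
    warnings: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    sd = X.std(axis=0)
    alive = []
    for j, n in enumerate(names):
        if sd[j] == 0:
            warnings.append(f"layer {n!r} has zero variance; dropped (r undefined)")
            dropped.append((n, "", float("nan")))
        else:
            alive.append(n)
    with np.errstate(invalid="ignore"):
        full = np.corrcoef(X.T) if len(names) > 1 else np.ones((1, 1))
    full = np.atleast_2d(full)

    def score(n: str) -> float:
        return float(priority[n]) if priority is not None and n in priority else 0.0

    retained = list(alive)
    while True:
        best = None
        for a_i in range(len(retained)):
            for b_i in range(a_i + 1, len(retained)):
                a, b = retained[a_i], retained[b_i]
                r = full[names.index(a), names.index(b)]
                if abs(r) > threshold and (best is None or abs(r) > abs(best[2])):
                    best = (a, b, r)
        if best is None:
            break
        a, b, r = best
        # keep the higher-priority member; ties keep the alphabetically first
        if (score(a), a < b) >= (score(b), b < a):
            keep, drop = a, b
        else:
            keep, drop = b, a
        retained.remove(drop)
        dropped.append((drop, keep, float(r)))
    return CorrelationReport(
        names=names, matrix=full, dropped=dropped, retained=retained, warnings=warnings
    )


def univariate_gain_priority(samples: SampleMatrix, rm: float = 1.0) -> dict[str, float]:
    """Training gain of a single-variable linear+quadratic model, per variable.

    Used as the default priority when pruning correlated pairs: the member
    with higher standalone gain is kept.
    """
    from .maxent_core import build_features, fit_maxent  # local import: avoid cycle

    out: dict[str, float] = {}
    for name in samples.variable_names:
        sub = samples.select([name])
        feats = build_features(sub, classes=("L", "Q"))
        model = fit_maxent(sub, feats, rm=rm, max_iterations=500, tolerance=1e-6)
        out[name] = float(model.training_gain)
    return out
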
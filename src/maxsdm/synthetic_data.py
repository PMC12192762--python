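"""Synthetic landscapes with known truth.

Layers are moving-average-smoothed Gaussian noise fields, linearly mixed to
approximate a target cross-correlation matrix and then standardised.  The
true (unnormalised) log suitability is a Gibbs form

    log s(x) = intercept + Σ_v (a_v · x_v + b_v · x_v²)

so parameter- and importance-recovery have a known answer.  Presences are
sampled from the normalised density with within-cell jitter; future
scenarios are additive shifts of named layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.ndimage import uniform_filter

from .grid_io import EnvGrid, EnvGridStack, stack_layers, write_ascii_grid
from .preprocess import OccurrenceSet

__all__ = [
    "DEFAULT_LAYER_NAMES",
    "LandscapeSpec",
    "TruthSurface",
    "default_correlation",
    "default_truth_coefficients",
    "simulate_landscape",
    "sample_presences",
    "make_future_scenario",
    "write_landscape",
]

#: the eight retained environmental layer names
DEFAULT_LAYER_NAMES = ["alt", "bio1", "bio3", "bio6", "bio8", "bio12", "bio13", "bio15"]


def default_correlation(layer_names=None) -> np.ndarray:
    """Plausible cross-correlation target for the default layers.

    Includes one engineered near-collinear pair (bio12/bio13, r = 0.92) so
    the pruning stage always has work to do.
    """
    names = list(layer_names) if layer_names is not None else DEFAULT_LAYER_NAMES
    n = len(names)
    C = np.eye(n)
    pairs = {
        ("bio12", "bio13"): 0.92,
        ("bio1", "bio6"): 0.70,
        ("bio1", "bio8"): 0.45,
        ("bio6", "bio8"): 0.35,
        ("bio12", "bio15"): -0.30,
        ("bio13", "bio15"): -0.25,
        ("alt", "bio1"): -0.45,
        ("alt", "bio6"): -0.40,
    }
    idx = {nm: i for i, nm in enumerate(names)}
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


def default_truth_coefficients() -> dict[str, tuple[float, float]]:
    """Truth driven by bio12 and bio6 only, with interior optima."""
    return {"bio12": (1.4, -1.0), "bio6": (1.2, -0.8)}


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic landscape."""

    ncols: int = 60
    nrows: int = 50
    cellsize: float = 0.05
    xllcorner: float = 100.0
    yllcorner: float = 25.0
    crs_mode: str = "geographic"
    nodata_value: float = -9999.0
    layer_names: list[str] = field(default_factory=lambda: list(DEFAULT_LAYER_NAMES))
    smoothness: int = 5
    cross_correlation: np.ndarray | None = None
    truth_coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=default_truth_coefficients
    )
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 20 or self.ncols < 20:
            raise ValueError("landscape must be at least 20x20")
        if self.cross_correlation is None:
            self.cross_correlation = default_correlation(self.layer_names)
        C = np.asarray(self.cross_correlation, dtype=float)
        n = len(self.layer_names)
        if C.shape != (n, n):
            raise ValueError("correlation matrix shape does not match layer count")
        if not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValueError("correlation target is not positive semidefinite")
        self.cross_correlation = C
        unknown = set(self.truth_coefficients) - set(self.layer_names)
        if unknown:
            raise ValueError(f"truth coefficients for unknown layers: {sorted(unknown)}")


@dataclass
class TruthSurface:
    """True suitability: unnormalised log density and its normalisation."""

    log_density: EnvGrid
    normalized_density: EnvGrid

    def __post_init__(self) -> None:
        m = self.normalized_density.valid_mask
        if m.any():
            total = self.normalized_density.values[m].sum()
            if abs(total - 1.0) > 1e-9:
                raise ValueError("normalized density must sum to 1 over valid cells")


def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int, size: int) -> np.ndarray:
    z = rng.standard_normal((nrows, ncols))
    if size > 1:
        z = uniform_filter(z, size=size, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / (sd if sd > 0 else 1.0)


def simulate_landscape(spec: LandscapeSpec) -> tuple[EnvGridStack, TruthSurface]:
    """Generate the layer stack and its truth surface, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    n = len(spec.layer_names)
    fields = np.stack(
        [
            _smooth_field(rng, spec.nrows, spec.ncols, spec.smoothness).ravel()
            for _ in range(n)
        ]
    )  # (n_layers, n_cells)
    # symmetric square root of the correlation target mixes the fields
    w, V = np.linalg.eigh(spec.cross_correlation)
    A = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
    mixed = A @ fields
    mixed -= mixed.mean(axis=1, keepdims=True)
    mixed /= np.where(mixed.std(axis=1) > 0, mixed.std(axis=1), 1.0)[:, None]

    grids = []
    for i, name in enumerate(spec.layer_names):
        grids.append(
            (
                name,
                EnvGrid(
                    ncols=spec.ncols,
                    nrows=spec.nrows,
                    xllcorner=spec.xllcorner,
                    yllcorner=spec.yllcorner,
                    cellsize=spec.cellsize,
                    nodata_value=spec.nodata_value,
                    values=mixed[i].reshape(spec.nrows, spec.ncols),
                ),
            )
        )
    stack = stack_layers(grids, crs_mode=spec.crs_mode, label="current")

    log_s = np.full((spec.nrows, spec.ncols), spec.intercept, dtype=float)
    for name, (a, b) in spec.truth_coefficients.items():
        x = stack.layers[name].values
        log_s = log_s + a * x + b * x * x
    tmpl = stack.template
    m = stack.valid_mask
    dens = np.zeros_like(log_s)
    e = np.exp(log_s[m] - log_s[m].max())
    dens[m] = e / e.sum()
    truth = TruthSurface(
        log_density=tmpl.like(log_s),
        normalized_density=tmpl.like(dens),
    )
    return stack, truth


def sample_presences(
    truth: TruthSurface,
    stack: EnvGridStack,
    n: int,
    seed: int | None = None,
    species: str = "synthetic_species",
) -> OccurrenceSet:
    """Draw ``n`` presence points ∝ the normalised density (with replacement),
    jittered uniformly within the drawn cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = truth.normalized_density.valid_mask
    if not m.any():
        raise ValueError("truth surface has no valid cells")
    p = truth.normalized_density.values[m]
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    rc = np.argwhere(m)
    draws = rng.choice(len(p), size=n, replace=True, p=p)
    tmpl = stack.template
    r, c = rc[draws, 0], rc[draws, 1]
    cx = tmpl.xllcorner + (c + 0.5) * tmpl.cellsize
    cy = tmpl.yllcorner + (tmpl.nrows - r - 0.5) * tmpl.cellsize
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * tmpl.cellsize
    pts = np.column_stack([cx, cy]) + jitter
    return OccurrenceSet(species=species, points=pts)


def make_future_scenario(
    stack: EnvGridStack,
    deltas: Mapping[str, float | np.ndarray],
    label: str = "future",
) -> EnvGridStack:
    """Additively shift named layers; geometry, mask and untouched layers
    are unchanged."""
    unknown = set(deltas) - set(stack.names)
    if unknown:
        raise KeyError(f"deltas reference unknown layer(s): {sorted(unknown)}")
    out = stack.copy(label=label)
    for name, delta in deltas.items():
        g = out.layers[name]
        m = g.valid_mask
        if np.isscalar(delta):
            g.values[m] += float(delta)
        else:
            delta = np.asarray(delta, dtype=float)
            if delta.shape != g.values.shape:
                raise ValueError(
                    f"delta for {name!r} has shape {delta.shape}, grid is {g.values.shape}"
                )
            g.values[m] += delta[m]
    return out


def write_landscape(
    out_dir,
    stack: EnvGridStack,
    truth: TruthSurface | None = None,
    spec: LandscapeSpec | None = None,
) -> None:
    """Write one .asc per layer plus a JSON manifest (and optionally the
    truth surface)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, g in stack.layers.items():
        write_ascii_grid(g, out / f"{name}.asc")
    if truth is not None:
        write_ascii_grid(truth.log_density, out / "truth_log_density.asc")
        write_ascii_grid(truth.normalized_density, out / "truth_density.asc")
    manifest: dict = {
        "layers": stack.names,
        "crs_mode": stack.crs_mode,
        "label": stack.label,
    }
    if spec is not None:
        manifest["seed"] = spec.seed
        manifest["truth_coefficients"] = {
            k: list(v) for k, v in spec.truth_coefficients.items()
        }
        manifest["intercept"] = spec.intercept
        manifest["smoothness"] = spec.smoothness
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
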
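"""ESRI ASCII grid reading/writing and geometry-checked layer stacks.

Grids are stored exactly as the file lists them: row 0 is the northernmost
row.  The centre of cell ``(r, c)`` is::

    x = xllcorner + (c + 0.5) * cellsize
    y = yllcorner + (nrows - r - 0.5) * cellsize

Both the ``xllcorner`` and ``xllcenter`` header dialects are accepted on
read; files are always written in the corner dialect.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EnvGrid",
    "EnvGridStack",
    "GridFormatError",
    "GeometryError",
    "read_ascii_grid",
    "write_ascii_grid",
    "stack_layers",
]

#: relative tolerance for comparing floating-point geometry fields
GEOM_RTOL = 1e-9


class GridFormatError(ValueError):
    """Raised when an ASCII grid stream violates the format."""


class GeometryError(ValueError):
    """Raised when layers with incompatible geometry are combined."""


@dataclass
class EnvGrid:
    """A single environmental raster layer.

    ``values`` has shape ``(nrows, ncols)`` in north-to-south row order.
    Cells holding exactly ``nodata_value`` are treated as missing.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.ncols < 1 or self.nrows < 1:
            raise GridFormatError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise GridFormatError("cellsize must be > 0")
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"values shape {self.values.shape} != declared "
                f"({self.nrows}, {self.ncols})"
            )
        bad = ~np.isfinite(self.values) & ~self._nodata_eq(self.values)
        if bad.any():
            raise GridFormatError("grid contains non-finite non-nodata values")

    def _nodata_eq(self, arr: np.ndarray) -> np.ndarray:
        if np.isnan(self.nodata_value):
            return np.isnan(arr)
        return arr == self.nodata_value

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, ``True`` where the cell is NODATA."""
        return self._nodata_eq(self.values)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.mask

    @property
    def geometry(self) -> tuple:
        return (self.ncols, self.nrows, self.xllcorner, self.yllcorner, self.cellsize)

    def geometry_equal(self, other: "EnvGrid") -> bool:
        if (self.ncols, self.nrows) != (other.ncols, other.nrows):
            return False
        for a, b in (
            (self.xllcorner, other.xllcorner),
            (self.yllcorner, other.yllcorner),
            (self.cellsize, other.cellsize),
        ):
            if not np.isclose(a, b, rtol=GEOM_RTOL, atol=0.0):
                return False
        return True

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        x = self.xllcorner + (c + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - r - 0.5) * self.cellsize
        return (x, y)

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Return (row, col) containing map coordinate (x, y), or None."""
        c = int(np.floor((x - self.xllcorner) / self.cellsize))
        r = self.nrows - 1 - int(np.floor((y - self.yllcorner) / self.cellsize))
        if 0 <= r < self.nrows and 0 <= c < self.ncols:
            return (r, c)
        return None

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates as ``(nrows, ncols)`` arrays."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(x, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            y[:, None], (self.nrows, self.ncols)
        ).copy()

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "EnvGrid":
        """New grid with the same geometry holding ``values``."""
        out = np.asarray(values, dtype=float).copy()
        if nodata_mask is None:
            nodata_mask = self.mask
        out[nodata_mask] = self.nodata_value
        return replace(self, values=out)

    def copy(self) -> "EnvGrid":
        return replace(self, values=self.values.copy())


_HEADER_KEYS = ("ncols", "nrows", "xll", "yll", "cellsize", "nodata_value")


def read_ascii_grid(source) -> EnvGrid:
    """Read an ESRI ASCII grid from a path, text string or file-like object.

    Accepts both corner (``xllcorner``) and centre (``xllcenter``) header
    dialects; centre coordinates are converted to the corner convention.
    Gzip-compressed files are detected by a ``.gz`` extension.
    """
    text = _read_text(source)
    lines = text.splitlines()
    header: dict[str, float] = {}
    center_x = center_y = False
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in (
            "ncols",
            "nrows",
            "xllcorner",
            "xllcenter",
            "yllcorner",
            "yllcenter",
            "cellsize",
            "nodata_value",
        ):
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line: {line!r}")
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"malformed header line: {line!r}") from exc
            if key == "xllcenter":
                key, center_x = "xll", True
            elif key == "xllcorner":
                key = "xll"
            elif key == "yllcenter":
                key, center_y = "yll", True
            elif key == "yllcorner":
                key = "yll"
            header[key] = val
        else:
            break
    else:
        i += 1

    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"missing header keys: {', '.join(missing)}")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize <= 0:
        raise GridFormatError(f"cellsize must be positive, got {cellsize}")
    xll = header["xll"] - cellsize / 2.0 if center_x else header["xll"]
    yll = header["yll"] - cellsize / 2.0 if center_y else header["yll"]

    rows: list[np.ndarray] = []
    for j, line in enumerate(lines[i:]):
        tokens = line.split()
        if not tokens:
            continue
        try:
            row = np.array([float(t) for t in tokens])
        except ValueError as exc:
            raise GridFormatError(f"non-numeric token in data row {len(rows)}") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"data row {len(rows)} has {row.size} columns, expected {ncols}"
            )
        rows.append(row)
        if len(rows) == nrows:
            break
    if len(rows) != nrows:
        raise GridFormatError(f"expected {nrows} data rows, found {len(rows)}")

    return EnvGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        nodata_value=header["nodata_value"],
        values=np.vstack(rows),
    )


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" in s:
        return s
    if os.path.exists(s):
        if s.endswith(".gz"):
            with gzip.open(s, "rt") as fh:
                return fh.read()
        with open(s) as fh:
            return fh.read()
    # short header-less strings are not valid grids; let the parser complain
    return s


def write_ascii_grid(grid: EnvGrid, dest=None, digits: int = 6) -> str:
    """Serialise ``grid`` in the corner dialect with fixed significant digits.

    ``dest`` may be a path or file-like object; the text is returned either
    way.  NODATA cells are written as the sentinel.
    """
    bad = ~np.isfinite(grid.values) & ~grid.mask
    if bad.any():
        raise GridFormatError("refusing to write non-finite non-nodata values")
    buf = io.StringIO()
    buf.write(f"ncols {grid.ncols}\n")
    buf.write(f"nrows {grid.nrows}\n")
    buf.write(f"xllcorner {_fmt(grid.xllcorner, digits)}\n")
    buf.write(f"yllcorner {_fmt(grid.yllcorner, digits)}\n")
    buf.write(f"cellsize {_fmt(grid.cellsize, digits)}\n")
    buf.write(f"NODATA_value {_fmt(grid.nodata_value, digits)}\n")
    mask = grid.mask
    for r in range(grid.nrows):
        tokens = [
            _fmt(grid.nodata_value, digits) if mask[r, c] else _fmt(grid.values[r, c], digits)
            for c in range(grid.ncols)
        ]
        buf.write(" ".join(tokens) + "\n")
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        elif str(dest).endswith(".gz"):
            with gzip.open(dest, "wt") as fh:
                fh.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


def _fmt(v: float, digits: int) -> str:
    if v == int(v) and abs(v) < 1e15:
        return repr(float(v)) if abs(v) < 1e7 else f"{v:.{digits}g}"
    return f"{v:.{digits}g}"


@dataclass
class EnvGridStack:
    """Named raster layers sharing one geometry and one validity mask.

    Built via :func:`stack_layers`, which enforces geometry equality and
    applies the union of the per-layer NODATA masks to every layer.
    """

    layers: dict[str, EnvGrid]
    crs_mode: str = "geographic"
    label: str = ""

    def __post_init__(self) -> None:
        if self.crs_mode not in ("geographic", "planar"):
            raise ValueError(f"crs_mode must be geographic|planar, got {self.crs_mode!r}")
        if not self.layers:
            raise ValueError("stack needs at least one layer")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> EnvGrid:
        return next(iter(self.layers.values()))

    @property
    def shape(self) -> tuple[int, int]:
        g = self.template
        return (g.nrows, g.ncols)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.template.valid_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def table(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Values at valid cells, shape ``(n_valid, len(names))``.

        Rows follow C-order flattening of the grid (north-first).
        """
        names = list(names) if names is not None else self.names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layer(s): {', '.join(missing)}")
        m = self.valid_mask
        return np.column_stack([self.layers[n].values[m] for n in names])

    def valid_cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.template.cell_centers()
        m = self.valid_mask
        return x[m], y[m]

    def valid_rc(self) -> np.ndarray:
        """(n_valid, 2) array of (row, col) indices of valid cells."""
        return np.argwhere(self.valid_mask)

    def copy(self, label: str | None = None) -> "EnvGridStack":
        return EnvGridStack(
            layers={n: g.copy() for n, g in self.layers.items()},
            crs_mode=self.crs_mode,
            label=self.label if label is None else label,
        )

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> EnvGrid:
        return self.layers[name]


def stack_layers(
    grids: Iterable[tuple[str, EnvGrid]], crs_mode: str = "geographic", label: str = ""
) -> EnvGridStack:
    """Assemble layers into a stack.

    Geometry must match exactly (integer fields) / to ``GEOM_RTOL``
    (floating fields).  The validity mask of the stack is the intersection
    of the per-layer validity masks; masked-out cells are set to each
    layer's NODATA sentinel.
    """
    items = list(grids)
    if not items:
        raise ValueError("stack needs at least one layer")
    seen: dict[str, EnvGrid] = {}
    first_name, first = items[0][0], items[0][1]
    union_nodata = first.mask.copy()
    for name, g in items:
        if name in seen:
            raise ValueError(f"duplicate layer name {name!r}")
        if not g.geometry_equal(first):
            fields = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
            diffs = [
                f
                for f in fields
                if not np.isclose(getattr(g, f), getattr(first, f), rtol=GEOM_RTOL, atol=0.0)
            ]
            raise GeometryError(
                f"layer {name!r} geometry differs from {first_name!r} in: "
                + ", ".join(diffs)
            )
        seen[name] = g
        union_nodata |= g.mask
    masked = {n: g.like(g.values, nodata_mask=union_nodata) for n, g in seen.items()}
    return EnvGridStack(layers=masked, crs_mode=crs_mode, label=label)
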
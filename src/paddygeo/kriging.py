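"""Ordinary kriging: point prediction, raster maps, ESRI ASCII grids.

Ordinary kriging predicts Z at a target location s0 as a weighted sum
``sum_i lambda_i Z(x_i)`` with the weights constrained to sum to one
(unbiasedness for an unknown constant mean).  The weights solve the
covariance-form system with a Lagrange multiplier mu:

    [ C   1 ] [ lambda ]   [ c ]
    [ 1ᵀ  0 ] [   mu   ] = [ 1 ]

where ``C[i, j] = C(|x_i - x_j|)`` with ``C(0) = sill`` on the diagonal
(the nugget is treated as micro-scale variance, which makes kriging an
exact interpolator at data locations) and ``c[i] = C(|x_i - s0|)``.  The
kriging variance is ``sill - lambdaᵀ c - mu``; it depends only on the
geometry and the model, never on the observed values.

All predictions use the global neighbourhood (every sample), appropriate
for the study's 93-point datasets and free of search-neighbourhood
artefacts.  Negative weights are permitted, as is standard for ordinary
kriging, so predictions may leave the data range.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import DomainError, NumericalError, ValidationError
from .sample_io import SampleSet
from .variogram import VariogramModel, model_cov

__all__ = [
    "GridSpec",
    "KrigingGrid",
    "ok_predict",
    "krige_grid",
    "grid_from_samples",
    "write_ascii_grid",
    "read_ascii_grid",
]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular raster geometry: lower-left corner, cell size, counts."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.cell <= 0:
            raise ValidationError("cell size must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("grid must cover at least one cell")

    def cell_centers(self) -> np.ndarray:
        """(nx*ny, 2) centres, row-major with row 0 southernmost."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class KrigingGrid:
    """Raster of kriging predictions and variances.

    ``values`` and ``variances`` have shape (ny, nx); row 0 is the
    southernmost row.  Variances are clipped at zero against roundoff.
    """

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int
    values: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        shape = (self.ny, self.nx)
        if self.values.shape != shape or self.variances.shape != shape:
            raise ValidationError(f"grid arrays must have shape {shape}")
        finite = np.isfinite(self.variances)
        if (self.variances[finite] < 0).any():
            raise ValidationError("variances must be non-negative")


def _kriging_lhs(samples: SampleSet, model: VariogramModel) -> np.ndarray:
    n = samples.n
    lhs = np.empty((n + 1, n + 1))
    cov = model_cov(model, squareform(pdist(samples.coords)))
    np.fill_diagonal(cov, model.sill)
    lhs[:n, :n] = cov
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    lhs[n, n] = 0.0
    return lhs


def _target_cov(samples: SampleSet, model: VariogramModel,
                targets: np.ndarray) -> np.ndarray:
    """(n+1, m) right-hand sides for m target locations."""
    d = cdist(samples.coords, targets)
    rhs = np.empty((samples.n + 1, targets.shape[0]))
    rhs[:-1] = np.where(d == 0.0, model.sill, model_cov(model, d))
    rhs[-1] = 1.0
    return rhs


def ok_predict(samples: SampleSet, model: VariogramModel,
               target) -> tuple[float, float, np.ndarray]:
    """Ordinary-kriging prediction at one location.

    Returns ``(value, variance, weights)``; the weights sum to one by
    construction and the variance is clipped at zero.
    """
    target = np.asarray(target, dtype=float).reshape(1, 2)
    if not np.isfinite(target).all():
        raise DomainError("target coordinates must be finite")
    if samples.n < 1:
        raise ValidationError("ok_predict requires at least one sample")
    lhs = _kriging_lhs(samples, model)
    rhs = _target_cov(samples, model, target)[:, 0]
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular kriging system: {exc}") from exc
    weights, mu = sol[:-1], sol[-1]
    value = float(weights @ samples.values)
    variance = float(model.sill - weights @ rhs[:-1] - mu)
    return value, max(variance, 0.0), weights


def grid_from_samples(samples: SampleSet, cell: float = 5.0,
                      pad: float = 0.0) -> GridSpec:
    """Grid covering the sample bounding box at the given cell size."""
    xmin, xmax = samples.x.min() - pad, samples.x.max() + pad
    ymin, ymax = samples.y.min() - pad, samples.y.max() + pad
    nx = max(1, int(np.ceil((xmax - xmin) / cell)))
    ny = max(1, int(np.ceil((ymax - ymin) / cell)))
    return GridSpec(x0=float(xmin), y0=float(ymin), cell=float(cell),
                    nx=nx, ny=ny)


def krige_grid(samples: SampleSet, model: VariogramModel,
               grid: GridSpec) -> KrigingGrid:
    """Ordinary kriging at every cell centre of a regular grid.

    Equivalent to calling :func:`ok_predict` at each centre; the data
    system is factorized once and shared across cells.
    """
    lhs = _kriging_lhs(samples, model)
    try:
        factors = lu_factor(lhs)
    except Exception as exc:  # pragma: no cover - scipy raises ValueError/LinAlgError
        raise NumericalError(f"singular kriging system: {exc}") from exc
    targets = grid.cell_centers()
    rhs = _target_cov(samples, model, targets)
    sol = lu_solve(factors, rhs)
    weights, mu = sol[:-1], sol[-1]
    values = weights.T @ samples.values
    variances = model.sill - np.einsum("ij,ij->j", weights, rhs[:-1]) - mu
    variances = np.clip(variances, 0.0, None)
    return KrigingGrid(x0=grid.x0, y0=grid.y0, cell=grid.cell,
                       nx=grid.nx, ny=grid.ny,
                       values=values.reshape(grid.ny, grid.nx),
                       variances=variances.reshape(grid.ny, grid.nx))


def write_ascii_grid(grid: KrigingGrid, path: str | Path,
                     which: str = "values") -> None:
    """Write one grid field as an ESRI ASCII raster (.asc).

    Floats are written with ``repr`` so the round trip through
    :func:`read_ascii_grid` is bit-faithful; NaN cells become the
    NODATA value.
    """
    if which not in ("values", "variances"):
        raise ValidationError("which must be 'values' or 'variances'")
    data = getattr(grid, which)
    lines = [
        f"ncols {grid.nx}",
        f"nrows {grid.ny}",
        f"xllcorner {float(grid.x0)!r}",
        f"yllcorner {float(grid.y0)!r}",
        f"cellsize {float(grid.cell)!r}",
        f"NODATA_value {NODATA!r}",
    ]
    for row in data[::-1]:  # ASCII grids store the northernmost row first
        lines.append(" ".join(
            repr(NODATA) if np.isnan(v) else repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ascii_grid(path: str | Path) -> KrigingGrid:
    """Read an ESRI ASCII raster into a :class:`KrigingGrid`.

    The raster populates ``values``; ``variances`` is zero-filled (the
    format carries a single band).  NODATA cells become NaN.
    """
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if len(text) < 7:
        raise ValidationError("ASCII grid must have a 6-line header and data")
    header = {}
    for line in text[:6]:
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"malformed ASCII grid header line: {line!r}")
        header[parts[0].lower()] = parts[1]
    try:
        nx = int(header["ncols"])
        ny = int(header["nrows"])
        x0 = float(header["xllcorner"])
        y0 = float(header["yllcorner"])
        cell = float(header["cellsize"])
        nodata = float(header["nodata_value"])
    except KeyError as exc:
        raise ValidationError(f"ASCII grid header missing {exc}") from exc
    rows = [np.array(line.split(), dtype=float) for line in text[6:6 + ny]]
    if len(rows) != ny or any(r.size != nx for r in rows):
        raise ValidationError("ASCII grid data does not match header shape")
    values = np.vstack(rows)[::-1]  # back to row 0 = southernmost
    values = np.where(values == nodata, np.nan, values)
    return KrigingGrid(x0=x0, y0=y0, cell=cell, nx=nx, ny=ny,
                       values=values, variances=np.zeros((ny, nx)))
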
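"""Georeferenced point samples and the rice-field sampling layout.

A :class:`SampleSet` holds the measurements of one nutrient under one
lime treatment at one sampling date: planar coordinates in metres and
concentrations in mg kg⁻¹.  :class:`FieldLayout` describes the idealized
geometry of one 1.7-ha experimental parcel: 32 plots of 50 m × 11.9 m,
sampled on an 11.9 × 20 m lattice (three positions per plot, 96 lattice
positions in total, of which the study protocol uses the first 93).

Coordinates are local Cartesian metres with the origin at the parcel's
south-west corner; no geographic projection is attached.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CapacityError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Nutrient",
    "SampleSet",
    "FieldLayout",
    "DEFAULT_LAYOUT",
    "generate_layout_coordinates",
    "read_samples",
    "write_samples",
]


class Nutrient(str, Enum):
    """Macronutrient forms measured in the study."""

    NH4N = "NH4-N"       # ammonium nitrogen (2 M KCl extract)
    OLSEN_P = "Olsen-P"  # bicarbonate-extractable phosphorus
    MEHLICH_K = "Mehlich-K"  # Mehlich-1 double-acid extractable potassium

    @classmethod
    def parse(cls, label: str) -> "Nutrient":
        s = str(label).strip()
        for member in cls:
            if s == member.value or s == member.name:
                return member
        raise ValidationError(f"unknown nutrient label: {label!r}")


@dataclass(eq=False)
class SampleSet:
    """Point measurements of one nutrient/treatment/date dataset.

    Parameters
    ----------
    dataset_code
        Short label such as ``"NH4-10"`` (nutrient, dose index, event).
    nutrient
        One of :class:`Nutrient`.
    dose
        Dolomite rate in kg ha⁻¹ (0, 625 or 1250 in the study design).
    event
        Sampling date index (1 = before sowing, 2 = bunch formation,
        3 = flowering).
    x, y
        Coordinates in metres.
    values
        Concentrations in mg kg⁻¹; strictly positive.
    """

    dataset_code: str
    nutrient: Nutrient
    dose: float
    event: int
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.x.shape == self.y.shape == self.values.shape):
            raise ValidationError("x, y and values must have equal length")
        if self.x.ndim != 1:
            raise ValidationError("x, y and values must be 1-D")
        if self.n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                    and np.isfinite(self.values).all()):
                raise ValidationError("coordinates and values must be finite")
            if (self.values <= 0).any():
                bad = int(np.nonzero(self.values <= 0)[0][0])
                raise ValidationError(
                    f"values must be > 0 (first offending row index {bad})")
            coords = set(zip(self.x.tolist(), self.y.tolist()))
            if len(coords) != self.n:
                raise ValidationError(
                    f"duplicate (x, y) coordinates in dataset "
                    f"{self.dataset_code!r}")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) coordinate matrix."""
        return np.column_stack([self.x, self.y])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSet):
            return NotImplemented
        return (self.dataset_code == other.dataset_code
                and self.nutrient == other.nutrient
                and float(self.dose) == float(other.dose)
                and int(self.event) == int(other.event)
                and np.array_equal(self.x, other.x)
                and np.array_equal(self.y, other.y)
                and np.array_equal(self.values, other.values))

    def replace_values(self, values: Sequence[float]) -> "SampleSet":
        """Same geometry and metadata, new measurement vector."""
        return SampleSet(self.dataset_code, self.nutrient, self.dose,
                         self.event, self.x.copy(), self.y.copy(),
                         np.asarray(values, dtype=float))


@dataclass(frozen=True)
class FieldLayout:
    """Idealized geometry of one experimental parcel.

    The 32 plots (50 m × 11.9 m, separated by 1.9 m water channels) are
    arranged ``plot_columns`` across and ``n_plots / plot_columns`` along
    the parcel; each plot is one lattice column wide and contributes
    ``samples_per_plot`` lattice rows.  Sample positions are idealized to
    a uniform ``grid_dx`` × ``grid_dy`` (11.9 × 20 m) lattice, so every
    nearest-neighbour distance is exactly 11.9 or 20 m; the small
    irregularities that channels and plot margins would introduce are
    deliberately ignored (the study reports only the basic grid).
    """

    plot_length: float = 50.0
    plot_width: float = 11.9
    channel_width: float = 1.9
    n_plots: int = 32
    plot_columns: int = 8
    grid_dx: float = 11.9
    grid_dy: float = 20.0
    samples_per_plot: int = 3
    parcel_area_ha: float = 1.7

    def __post_init__(self):
        if self.n_plots % self.plot_columns:
            raise ValidationError(
                "n_plots must be a multiple of plot_columns")

    @property
    def plot_rows(self) -> int:
        return self.n_plots // self.plot_columns

    @property
    def lattice_shape(self) -> tuple[int, int]:
        """(n_columns, n_rows) of the sampling lattice."""
        return (self.plot_columns, self.plot_rows * self.samples_per_plot)

    @property
    def capacity(self) -> int:
        return self.n_plots * self.samples_per_plot

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the idealized parcel."""
        nx, ny = self.lattice_shape
        return (0.0, 0.0, nx * self.grid_dx, ny * self.grid_dy)


DEFAULT_LAYOUT = FieldLayout()


def generate_layout_coordinates(layout: FieldLayout = DEFAULT_LAYOUT,
                                n_samples: int = 93) -> np.ndarray:
    """Deterministic sampling coordinates on the parcel lattice.

    Positions are laid out row-major: rows of constant y at 20 m
    spacing, x varying fastest at 11.9 m spacing.  The first
    ``n_samples`` positions are returned, so ``n_samples=96`` is the
    full lattice and the study default 93 drops the last three
    positions of the final (northernmost) row.

    Returns an (n_samples, 2) array of (x, y) in metres.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if n_samples > layout.capacity:
        raise CapacityError(
            f"n_samples={n_samples} exceeds lattice capacity "
            f"{layout.capacity} ({layout.n_plots} plots x "
            f"{layout.samples_per_plot})")
    nx, ny = layout.lattice_shape
    xs = (np.arange(nx) + 0.5) * layout.grid_dx
    ys = (np.arange(ny) + 0.5) * layout.grid_dy
    gx, gy = np.meshgrid(xs, ys)  # rows of constant y, x fastest
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    return coords[:n_samples]


_DEFAULT_SCHEMA = {"x": "x", "y": "y", "value": "value"}
_META_COLUMNS = ("dataset_code", "nutrient", "dose", "event")


def read_samples(path: str | Path,
                 schema: Mapping[str, str] | None = None) -> SampleSet:
    """Read a point-sample CSV into a :class:`SampleSet`.

    ``schema`` maps the logical names ``x``, ``y``, ``value`` to the
    column names used in the file.  Metadata columns (``dataset_code``,
    ``nutrient``, ``dose``, ``event``) are picked up when present and
    default to an unlabelled NH4-N control otherwise.  Row order is
    preserved.
    """
    path = Path(path)
    mapping = dict(_DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path)
    for logical, col in mapping.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path.name}: required column {col!r} (for {logical!r}) "
                f"not found; columns present: {list(df.columns)}")
    numeric = {}
    for logical in ("x", "y", "value"):
        col = mapping[logical]
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            row = int(bad[0]) + 1  # 1-based data row
            raise ParseError(
                f"{path.name}: column {col!r} has a non-numeric value at "
                f"row {row}")
        numeric[logical] = parsed.to_numpy(dtype=float)

    def _meta(name, default):
        if name in df.columns and len(df):
            return df[name].iloc[0]
        return default

    code = str(_meta("dataset_code", path.stem))
    nutrient = Nutrient.parse(_meta("nutrient", Nutrient.NH4N.value))
    dose = float(_meta("dose", 0.0))
    event = int(_meta("event", 1))
    return SampleSet(code, nutrient, dose, event,
                     numeric["x"], numeric["y"], numeric["value"])


def write_samples(samples: SampleSet, path: str | Path) -> None:
    """Write a :class:`SampleSet` to CSV at full double precision.

    Columns: x, y, value, dataset_code, nutrient, dose, event.  Floats
    are written with :func:`repr`, which round-trips bit-identically.
    """
    path = Path(path)
    lines = ["x,y,value,dataset_code,nutrient,dose,event"]
    for xi, yi, vi in zip(samples.x, samples.y, samples.values):
        lines.append(
            f"{float(xi)!r},{float(yi)!r},{float(vi)!r},"
            f"{samples.dataset_code},{samples.nutrient.value},"
            f"{float(samples.dose)!r},{samples.event}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
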
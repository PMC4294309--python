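"""Empirical semivariograms and parametric variogram models.

The empirical (experimental) semivariogram of a point dataset is

    gamma(h) = 1 / (2 N(h)) * sum_{(i,j) in pairs(h)} (Z(x_i) - Z(x_j))**2,

where ``pairs(h)`` are the unordered point pairs whose separation falls
in the distance bin around lag h and ``N(h)`` is their count.  Only the
isotropic (omnidirectional) estimator is provided; the study reports no
anisotropy analysis.

Parametric models are the three classical bounded families, written with
nugget ``c0``, structural variance ``c1`` (sill ``c0 + c1``) and range
``a``.  For the exponential and Gaussian families ``a`` is the
*practical* range — the distance at which the model reaches 95 % of its
sill — so fitted ranges are directly comparable across families:

    spherical:   gamma(h) = c0 + c1 * (1.5 h/a - 0.5 (h/a)**3),  h <= a
                 gamma(h) = c0 + c1,                             h > a
    exponential: gamma(h) = c0 + c1 * (1 - exp(-3 h / a))
    gaussian:    gamma(h) = c0 + c1 * (1 - exp(-3 (h/a)**2))

By convention gamma(0) = 0 exactly, with a jump to ``c0`` as h → 0⁺: the
nugget is treated as micro-scale plus measurement variance.  The model
covariance is the usual dual ``C(h) = sill - gamma(h)``, so
``C(0) = sill``.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import DomainError, InsufficientDataError, ValidationError
from .sample_io import SampleSet

__all__ = [
    "ModelFamily",
    "SpatialDependence",
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_variogram",
    "model_gamma",
    "model_cov",
    "nugget_sill_ratio",
    "classify_dependence",
]

DEFAULT_LAG_WIDTH = 12.0  # m; just above the 11.9 m minimum grid spacing


class ModelFamily(str, Enum):
    SPHERICAL = "spherical"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"

    @classmethod
    def parse(cls, label: "str | ModelFamily") -> "ModelFamily":
        if isinstance(label, cls):
            return label
        s = str(label).strip().lower()
        for member in cls:
            if s == member.value:
                return member
        raise ValidationError(f"unknown variogram model family: {label!r}")


class SpatialDependence(str, Enum):
    """Qualitative spatial-dependence class from the nugget-to-sill ratio."""

    STRONG = "strong"      # ratio < 25 %
    MODERATE = "moderate"  # 25 % <= ratio <= 75 %
    WEAK = "weak"          # ratio > 75 %


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned isotropic sample semivariogram.

    ``lag_center`` are bin centres in metres (strictly increasing, empty
    bins dropped), ``gamma`` the semivariances in (mg kg⁻¹)² and
    ``n_pairs`` the pair count per bin.
    """

    lag_center: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    lag_width: float
    max_lag: float

    def __post_init__(self):
        object.__setattr__(self, "lag_center",
                           np.asarray(self.lag_center, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "n_pairs",
                           np.asarray(self.n_pairs, dtype=int))
        if (self.gamma < 0).any():
            raise ValidationError("semivariances must be non-negative")
        if (self.n_pairs < 1).any():
            raise ValidationError("reported bins must contain >= 1 pair")
        if (np.diff(self.lag_center) <= 0).any():
            raise ValidationError("lag centres must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.lag_center.size


@dataclass(frozen=True)
class VariogramModel:
    """Bounded variogram model: family plus (c0, c1, a).

    ``sill = c0 + c1`` and ``nugget_ratio = 100 c0 / sill`` (percent)
    are derived.  ``range_a`` is the (practical) range in metres.
    """

    family: ModelFamily
    c0: float
    c1: float
    range_a: float

    def __post_init__(self):
        object.__setattr__(self, "family", ModelFamily.parse(self.family))
        if self.c0 < 0 or self.c1 < 0:
            raise ValidationError("c0 and c1 must be non-negative")
        if self.c0 + self.c1 <= 0:
            raise ValidationError("sill c0 + c1 must be positive")
        if self.range_a <= 0:
            raise ValidationError("range_a must be positive")

    @property
    def sill(self) -> float:
        return self.c0 + self.c1

    @property
    def nugget_ratio(self) -> float:
        return nugget_sill_ratio(self)


def empirical_variogram(samples: SampleSet,
                        lag_width: float | None = None,
                        max_lag: float | None = None,
                        center: str = "mean") -> EmpiricalVariogram:
    """Isotropic binned sample semivariogram of a point dataset.

    Pairs are assigned to half-open distance intervals
    ``[k·lag_width, (k+1)·lag_width)``; bins at or beyond ``max_lag``
    are excluded and empty bins are dropped.

    Parameters
    ----------
    samples
        At least 10 points.
    lag_width
        Bin width in metres; defaults to 12 m (just above the 11.9 m
        minimum spacing of the study grid).
    max_lag
        Largest lag considered; defaults to half the maximum pairwise
        distance.
    center
        ``"mean"`` (default) reports the mean pair distance per bin;
        ``"midpoint"`` reports bin midpoints.  Mean-distance centres are
        the default because on gridded data a bin can hold pairs far
        from its midpoint (the first bin holds only 11.9 m pairs but is
        centred at 6 m), which visibly biases nugget and range
        estimates.
    """
    if samples.n < 10:
        raise InsufficientDataError(
            f"empirical_variogram requires n >= 10 (got {samples.n})")
    d = pdist(samples.coords)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if lag_width is None:
        lag_width = DEFAULT_LAG_WIDTH
    if lag_width <= 0:
        raise ValidationError("lag_width must be positive")
    if max_lag <= lag_width:
        raise ValidationError("max_lag must exceed lag_width")
    if center not in ("midpoint", "mean"):
        raise ValidationError("center must be 'midpoint' or 'mean'")
    dz2 = pdist(samples.values[:, None], metric="sqeuclidean")
    keep = d < max_lag
    if not keep.any():
        raise ValidationError("no point pairs closer than max_lag")
    d, dz2 = d[keep], dz2[keep]
    k = np.floor(d / lag_width).astype(int)
    n_bins = int(k.max()) + 1
    counts = np.bincount(k, minlength=n_bins)
    sums = np.bincount(k, weights=dz2, minlength=n_bins)
    nonempty = counts > 0
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    if center == "midpoint":
        centers = (np.nonzero(nonempty)[0] + 0.5) * lag_width
    else:
        centers = np.bincount(k, weights=d, minlength=n_bins)[nonempty] \
            / counts[nonempty]
    return EmpiricalVariogram(lag_center=centers, gamma=gamma,
                              n_pairs=counts[nonempty],
                              lag_width=float(lag_width),
                              max_lag=float(max_lag))


def model_gamma(model: VariogramModel, h):
    """Model semivariance gamma(h); gamma(0) = 0 exactly.

    ``h`` may be a scalar or array of non-negative distances in metres.
    """
    h_arr = np.asarray(h, dtype=float)
    if (h_arr < 0).any():
        raise DomainError("distances must be non-negative")
    hr = h_arr / model.range_a
    if model.family is ModelFamily.SPHERICAL:
        g = model.c0 + model.c1 * np.where(
            hr <= 1.0, 1.5 * hr - 0.5 * hr ** 3, 1.0)
    elif model.family is ModelFamily.EXPONENTIAL:
        g = model.c0 + model.c1 * (1.0 - np.exp(-3.0 * hr))
    else:  # gaussian
        g = model.c0 + model.c1 * (1.0 - np.exp(-3.0 * hr ** 2))
    g = np.where(h_arr == 0.0, 0.0, g)
    return float(g) if np.isscalar(h) or h_arr.ndim == 0 else g


def model_cov(model: VariogramModel, h):
    """Model covariance C(h) = sill - gamma(h); C(0) = sill."""
    return model.sill - model_gamma(model, h)


def nugget_sill_ratio(model: VariogramModel) -> float:
    """Nugget-to-sill ratio in percent, ``100 c0 / (c0 + c1)``."""
    sill = model.c0 + model.c1
    if sill <= 0:
        raise DomainError("nugget_sill_ratio requires a positive sill")
    return 100.0 * model.c0 / sill


def classify_dependence(ratio: float) -> SpatialDependence:
    """Spatial-dependence class from the nugget-to-sill ratio (percent).

    Strong below 25 %, moderate from 25 to 75 % inclusive, weak above.
    """
    if not (0.0 <= ratio <= 100.0):
        raise DomainError(f"ratio must lie in [0, 100], got {ratio}")
    if ratio < 25.0:
        return SpatialDependence.STRONG
    if ratio <= 75.0:
        return SpatialDependence.MODERATE
    return SpatialDependence.WEAK
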
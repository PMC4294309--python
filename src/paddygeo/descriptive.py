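"""Per-dataset descriptive statistics and classical screening tests.

Conventions
-----------
* Variance is the sample variance (divisor n − 1).
* CV is reported in percent: ``100 * sqrt(variance) / mean``.
* Skewness is the Fisher–Pearson moment coefficient g₁ and kurtosis the
  excess moment coefficient g₂ (both biased forms) by default; the
  bias-adjusted G₁/G₂ variants are available via ``adjusted=True``.
* Normality screening uses the one-sample Kolmogorov–Smirnov statistic
  with moments estimated from the data, i.e. the Lilliefors test.
* Group comparison uses pairwise Welch t-tests with Holm adjustment and
  reports a compact letter display (groups sharing a letter are not
  significantly different).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "DescriptiveStats",
    "describe",
    "cv_percent",
    "ks_normality",
    "pearson",
    "compare_groups",
    "percent_change",
]


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary of one measurement vector (units: mg kg⁻¹ where relevant).

    ``skewness``/``kurtosis`` are NaN for degenerate (constant) input;
    ``ks_stat``/``ks_p`` are NaN when the normality screen is not
    applicable (n < 8 or constant input).
    """

    n: int
    mean: float
    variance: float
    cv_percent: float
    minimum: float
    maximum: float
    skewness: float
    kurtosis: float
    ks_stat: float
    ks_p: float


def describe(values: Sequence[float], adjusted: bool = False) -> DescriptiveStats:
    """Compute the full descriptive summary of a measurement vector.

    Parameters
    ----------
    values
        At least two finite measurements.
    adjusted
        If True, report the bias-adjusted skewness G₁ and kurtosis G₂
        instead of the moment coefficients g₁ and g₂.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InsufficientDataError("describe requires at least 2 values")
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    n = int(v.size)
    mean = float(np.mean(v))
    variance = float(np.var(v, ddof=1))
    if variance == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(v, bias=not adjusted))
        kurt = float(stats.kurtosis(v, fisher=True, bias=not adjusted))
    cv = cv_percent(mean, variance) if mean > 0 else float("nan")
    if n >= 8 and variance > 0:
        ks_stat, ks_p = lilliefors(v, dist="norm", pvalmethod="table")
        ks_stat, ks_p = float(ks_stat), float(ks_p)
    else:
        ks_stat = ks_p = float("nan")
    return DescriptiveStats(n=n, mean=mean, variance=variance,
                            cv_percent=cv, minimum=float(v.min()),
                            maximum=float(v.max()), skewness=skew,
                            kurtosis=kurt, ks_stat=ks_stat, ks_p=ks_p)


def cv_percent(mean: float, variance: float) -> float:
    """Coefficient of variation in percent, ``100·sqrt(variance)/mean``."""
    if mean <= 0:
        raise DomainError("cv_percent requires mean > 0")
    if variance < 0:
        raise DomainError("variance must be >= 0")
    return 100.0 * float(np.sqrt(variance)) / float(mean)


def ks_normality(values: Sequence[float], alpha: float = 0.05
                 ) -> tuple[float, float, bool]:
    """Lilliefors-corrected Kolmogorov–Smirnov normality screen.

    The null distribution accounts for the mean and variance being
    estimated from the sample.  Returns ``(statistic, p, is_normal)``
    with ``is_normal = (p > alpha)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise InsufficientDataError("ks_normality requires n >= 8")
    if np.ptp(v) == 0:
        raise ValidationError("constant input: distribution is degenerate")
    stat, p = lilliefors(v, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p > alpha)


def pearson(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("sequences must have equal length")
    if a.size < 3:
        raise ValidationError("pearson requires length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("pearson requires non-constant input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def compare_groups(groups: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from pairwise Welch t-tests (Holm-adjusted).

    Groups that share a letter are not significantly different at level
    ``alpha``.  Letters are ordered by decreasing group mean, so the
    group with the highest mean always carries 'a'.
    """
    if len(groups) < 2:
        raise ValidationError("compare_groups requires at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
        arrays[name] = v
    names = list(arrays)
    pairs = [(names[i], names[j])
             for i in range(len(names)) for j in range(i + 1, len(names))]
    raw_p = []
    for g1, g2 in pairs:
        _, p = stats.ttest_ind(arrays[g1], arrays[g2], equal_var=False)
        raw_p.append(1.0 if np.isnan(p) else float(p))
    reject = multipletests(raw_p, alpha=alpha, method="holm")[0] if pairs else []

    # Graph whose edges join statistically indistinguishable groups;
    # maximal cliques of that graph become the letters.
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for (g1, g2), rej in zip(pairs, reject):
        if not rej:
            graph.add_edge(g1, g2)
    order = sorted(names, key=lambda g: -float(np.mean(arrays[g])))
    rank = {g: i for i, g in enumerate(order)}
    cliques = sorted((sorted(c, key=rank.get) for c in nx.find_cliques(graph)),
                     key=lambda c: rank[c[0]])
    letters = {g: "" for g in names}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in clique:
            letters[g] += ch
    return letters


def percent_change(m1: float, m2: float) -> float:
    """Relative change from ``m1`` to ``m2`` in percent."""
    if m1 <= 0:
        raise DomainError("percent_change requires m1 > 0")
    return 100.0 * (m2 - m1) / m1
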
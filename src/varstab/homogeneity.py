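"""Variance-homogeneity scores: Bartlett's statistic, robust alternatives,
and the between/within-cluster effect-size ratio.

Bartlett's likelihood-ratio statistic over ``m`` groups with sizes
``n_i`` and unbiased variances ``s_i^2`` is

    B = [(n - m) ln s_p^2 - sum (n_i - 1) ln s_i^2]
        / [1 + (1 / (3 (m - 1))) (sum 1/(n_i - 1) - 1/(n - m))]

where ``s_p^2`` is the pooled variance. Here it is used purely as a score
of homoskedasticity to minimize over transformation cofactors — never as a
hypothesis test, so no p-values are produced.

The between/within ratio is an effect-size measure of metacluster
homogeneity: the ratio of between-cluster to within-cluster variation,
computed from cluster summaries alone. It is invariant to common affine
rescalings of the underlying data and does not grow with cell count,
unlike an F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.stats
from numpy.typing import ArrayLike, NDArray

from .density import PeakSet

__all__ = [
    "Metacluster",
    "bartlett_statistic",
    "bartlett_from_summaries",
    "levene_statistic",
    "between_within_ratio",
]


@dataclass
class Metacluster:
    """Summaries of k clusters asserted to share one immunophenotype."""

    counts: NDArray[np.int64]
    means: NDArray[np.float64]
    variances: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        k = self.counts.size
        if not (self.means.size == k == self.variances.size):
            raise ValueError("counts, means and variances must have equal length")
        if k < 2:
            raise ValueError("a metacluster needs at least 2 clusters")
        if np.any(self.counts < 2):
            raise ValueError("every cluster needs at least 2 cells")
        if np.any(self.variances < 0):
            raise ValueError("cluster variances must be non-negative")

    @property
    def k(self) -> int:
        return int(self.counts.size)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def mu(self) -> float:
        """Combined (cell-weighted) mean."""
        return float(np.sum(self.counts * self.means) / self.N)


def bartlett_from_summaries(counts: ArrayLike, variances: ArrayLike) -> float:
    """Bartlett's statistic from group sizes and unbiased variances."""
    ni = np.asarray(counts, dtype=np.float64)
    vi = np.asarray(variances, dtype=np.float64)
    m = ni.size
    if m < 2:
        raise ValueError(f"Bartlett's statistic needs at least 2 groups, got {m}")
    if np.any(ni < 2):
        raise ValueError("every group needs n_i >= 2")
    if np.any(vi <= 0):
        raise ValueError("every group variance must be positive")
    n = float(ni.sum())
    pooled = float(np.sum((ni - 1) * vi) / (n - m))
    num = (n - m) * np.log(pooled) - float(np.sum((ni - 1) * np.log(vi)))
    corr = 1.0 + (np.sum(1.0 / (ni - 1)) - 1.0 / (n - m)) / (3.0 * (m - 1))
    return float(max(num / corr, 0.0))


def bartlett_statistic(ps: PeakSet) -> float:
    """Bartlett's statistic over the pooled density peaks of a channel.

    Computed from the peak summaries (n_i, s_i^2) only; raw events are
    never revisited. The value is specific to the cofactor used to build
    the :class:`PeakSet` and is the objective the cofactor search
    minimizes.
    """
    if ps.m < 2:
        raise ValueError(
            f"Bartlett's statistic undefined for {ps.m} peak(s); need at least 2"
        )
    return bartlett_from_summaries(ps.counts, ps.variances)


def levene_statistic(
    groups: Sequence[ArrayLike],
    center: Literal["mean", "median"] = "median",
) -> float:
    """Levene (center='mean') or Brown-Forsythe (center='median') statistic.

    The one-way ANOVA F statistic on absolute deviations from each group's
    center — a homogeneity score less sensitive to departures from
    normality than Bartlett's. Requires the raw group values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    stat, _ = scipy.stats.levene(*arrays, center=center)
    return float(stat)


def between_within_ratio(mc: Metacluster) -> float:
    """Between/within-cluster variation ratio of a metacluster.

    ``sum (n_i - 1) (mu_i - mu)^2 / sum (n_i - 1) s_i^2`` with ``mu`` the
    combined mean (the common ``1/(N - k)`` factors cancel). Smaller values
    mean a more homogeneous metacluster; 0 when all cluster means agree.
    """
    w = (mc.counts - 1).astype(np.float64)
    denom = float(np.sum(w * mc.variances))
    if denom <= 0:
        raise ValueError("within-cluster variation is zero; ratio undefined")
    num = float(np.sum(w * (mc.means - mc.mu) ** 2))
    return num / denom
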
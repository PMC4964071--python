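"""Selection of the variance-stabilizing cofactor per channel.

The objective ``B(c)`` — Bartlett's statistic over density peaks pooled
across samples after an ``asinh(z/c)`` transform — depends on ``c`` only
through peak detection and the peak summaries, so it is non-differentiable
and may jump wherever the peak count changes. The search therefore avoids
gradients entirely: the log-cofactor range ``[c_low, c_high]`` (defaults
-2 and 10, i.e. cofactors from exp(-2) ~ 0.135 to exp(10) ~ 22026) is cut
into unit-width log intervals, a derivative-free bounded scalar
minimization (Brent-style golden section with parabolic interpolation)
runs inside each interval on the raw cofactor scale, and the best interval
optimum wins. Splitting the domain keeps the chance of multiple local
optima inside any one interval small.

The same chosen cofactor is applied to the channel in every sample;
channels are optimized independently.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .data_io import Sample
from .density import (
    MIN_EVENTS,
    MIN_HEIGHT_FRAC,
    MIN_PROMINENCE_FRAC,
    PeakSet,
    collect_peaks,
)
from .homogeneity import bartlett_statistic, levene_statistic
from .transforms import asinh_transform

__all__ = [
    "ScanSettings",
    "CofactorScan",
    "VSResult",
    "objective",
    "minimize_interval",
    "optimize_cofactor",
    "stabilize_dataset",
    "OptimizationFailed",
    "C_LOW_DEFAULT",
    "C_HIGH_DEFAULT",
]

C_LOW_DEFAULT = -2.0
C_HIGH_DEFAULT = 10.0
TOL_DEFAULT = 1e-4

_SCATTER_RE = re.compile(r"\b(FSC|SSC)|^(FS|SS)[ -]", re.IGNORECASE)


class OptimizationFailed(RuntimeError):
    """No cofactor in the search domain ever produced >= 2 density peaks."""


@dataclass(frozen=True)
class ScanSettings:
    """Peak-filter and objective settings shared by every evaluation of a scan.

    Changing these mid-scan would make Bartlett values incomparable across
    cofactors, so they are frozen.
    """

    min_events: int = MIN_EVENTS
    bandwidth: float | None = None
    min_height_frac: float = MIN_HEIGHT_FRAC
    min_prominence_frac: float = MIN_PROMINENCE_FRAC
    objective: Literal["bartlett", "levene", "brown_forsythe"] = "bartlett"


@dataclass
class CofactorScan:
    """Full record of one per-channel cofactor search."""

    channel: str
    c_low: float
    c_high: float
    interval_optima: list[tuple[float, float, int]] = field(default_factory=list)
    c_star: float = math.nan
    b_star: float = math.inf
    trace: list[tuple[float, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.interval_optima)

    @property
    def evaluations(self) -> int:
        return len(self.trace)


@dataclass
class VSResult:
    """Chosen cofactors and the dataset transformed with them."""

    cofactors: dict[str, CofactorScan]
    transformed: list[Sample]
    failures: dict[str, str] = field(default_factory=dict)


def _score(ps: PeakSet, settings: ScanSettings) -> float:
    if ps.m < 2:
        return math.inf
    if settings.objective == "bartlett":
        return bartlett_statistic(ps)
    center = "mean" if settings.objective == "levene" else "median"
    groups = [p.events for p in ps.peaks]
    if any(g is None for g in groups):
        raise RuntimeError("robust objectives need peaks collected with keep_events=True")
    return levene_statistic(groups, center=center)


def objective(
    dataset: list[Sample],
    channel: str,
    cofactor: float,
    settings: ScanSettings = ScanSettings(),
) -> float:
    """Homogeneity score of one channel at one cofactor.

    Collects density peaks across all samples at this cofactor and scores
    their variance homogeneity. Returns ``+inf`` when fewer than 2 peaks
    survive, so the surrounding search can continue over a partially
    degenerate domain.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = collect_peaks(
            dataset,
            channel,
            cofactor,
            min_events=settings.min_events,
            bandwidth=settings.bandwidth,
            min_height_frac=settings.min_height_frac,
            min_prominence_frac=settings.min_prominence_frac,
            keep_events=settings.objective != "bartlett",
        )
    return _score(ps, settings)


def minimize_interval(
    fun: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = TOL_DEFAULT,
    coarse: int = 20,
) -> tuple[float, float]:
    """Derivative-free minimization of a black-box scalar function on [lo, hi].

    The objective may be discontinuous, flat over stretches, and may
    return ``+inf``, so a purely local method can be trapped. The search
    therefore seeds with a uniform ``coarse``-point scan (endpoints
    included), then refines around the best coarse point with a
    Brent-style bounded search (golden section with successive parabolic
    interpolation); ``tol`` is relative on the argument. A monotone
    objective yields the boundary minimizer.
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got [{lo}, {hi}]")
    xs = np.linspace(lo, hi, max(coarse, 2) + 1)
    fs = np.array([fun(float(x)) for x in xs])
    k = int(np.argmin(fs))  # ties: smallest argument wins (argmin is first)
    c_best, b_best = float(xs[k]), float(fs[k])
    blo, bhi = float(xs[max(k - 1, 0)]), float(xs[min(k + 1, xs.size - 1)])
    res = minimize_scalar(
        fun, bounds=(blo, bhi), method="bounded", options={"xatol": tol * lo}
    )
    if res.fun < b_best or (res.fun == b_best and res.x < c_best):
        c_best, b_best = float(res.x), float(res.fun)
    return c_best, b_best


def _log_intervals(c_low: float, c_high: float) -> list[tuple[float, float]]:
    """Unit-width intervals on the log scale, last one possibly shorter."""
    if not c_low < c_high:
        raise ValueError(f"need c_low < c_high, got {c_low}, {c_high}")
    edges = [c_low]
    while edges[-1] + 1.0 < c_high - 1e-12:
        edges.append(edges[-1] + 1.0)
    edges.append(c_high)
    return list(zip(edges[:-1], edges[1:]))


def optimize_cofactor(
    dataset: list[Sample],
    channel: str,
    c_low: float = C_LOW_DEFAULT,
    c_high: float = C_HIGH_DEFAULT,
    tol: float = TOL_DEFAULT,
    settings: ScanSettings = ScanSettings(),
) -> CofactorScan:
    """Piecewise search for the cofactor minimizing the homogeneity score.

    Runs :func:`minimize_interval` over the cofactor range
    ``[exp(c_i), exp(c_i + 1)]`` of each unit log interval and takes the
    best interval optimum; ties go to the smaller cofactor. Every
    objective evaluation is recorded in the returned scan's ``trace``.
    Deterministic given the dataset and settings.
    """
    scan = CofactorScan(channel=channel, c_low=float(c_low), c_high=float(c_high))

    def recorded(c: float) -> float:
        b = objective(dataset, channel, c, settings)
        scan.trace.append((float(c), float(b)))
        return b

    for a, b in _log_intervals(c_low, c_high):
        before = len(scan.trace)
        c_i, b_i = minimize_interval(recorded, math.exp(a), math.exp(b), tol=tol)
        scan.interval_optima.append((c_i, b_i, len(scan.trace) - before))

    finite = [(c, bb) for c, bb, _ in scan.interval_optima if math.isfinite(bb)]
    if not finite:
        raise OptimizationFailed(
            f"channel {channel!r}: no cofactor in [exp({c_low:g}), exp({c_high:g})] "
            "produced 2 or more density peaks; nothing to stabilize"
        )
    scan.b_star = min(bb for _, bb in finite)
    scan.c_star = min(c for c, bb in finite if bb == scan.b_star)
    return scan


def is_scatter_channel(name: str) -> bool:
    """Heuristic test for forward/side-scatter channel names."""
    return bool(_SCATTER_RE.search(name))


def stabilize_dataset(
    dataset: list[Sample],
    channels: list[str],
    c_low: float = C_LOW_DEFAULT,
    c_high: float = C_HIGH_DEFAULT,
    tol: float = TOL_DEFAULT,
    settings: ScanSettings = ScanSettings(),
) -> VSResult:
    """Optimize a cofactor per channel and transform every sample with it.

    Channels are treated as independent; each gets its own scan. Scatter
    channels are skipped with a warning (transforming them has little
    benefit). A failure on one channel is recorded and does not stop the
    others.
    """
    scans: dict[str, CofactorScan] = {}
    failures: dict[str, str] = {}
    for ch in channels:
        if is_scatter_channel(ch):
            warnings.warn(f"skipping scatter channel {ch!r}", stacklevel=2)
            continue
        try:
            scans[ch] = optimize_cofactor(dataset, ch, c_low, c_high, tol, settings)
        except (OptimizationFailed, KeyError) as exc:
            failures[ch] = str(exc)
    transformed = []
    for s in dataset:
        out = s
        for ch, scan in scans.items():
            out = out.with_channel(ch, asinh_transform(out.channel(ch), scan.c_star))
        transformed.append(out)
    return VSResult(cofactors=scans, transformed=transformed, failures=failures)
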
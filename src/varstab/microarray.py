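"""Variance stabilization for microarray expression matrices.

In flow cytometry the variance groups are density peaks; in microarrays
each gene is a group: its expressions across the N samples have a mean and
an unbiased variance, and a single asinh cofactor is chosen for the whole
matrix so that these per-gene variances are as homogeneous as Bartlett's
statistic can make them. No peak detection is involved — the grouping is
given by the array layout — so the same interval search applies unchanged
with a much cheaper objective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .density import MIN_PEAK_VARIANCE, DensityPeak, PeakSet
from .homogeneity import bartlett_statistic
from .optimize import (
    C_HIGH_DEFAULT,
    C_LOW_DEFAULT,
    TOL_DEFAULT,
    CofactorScan,
    OptimizationFailed,
    _log_intervals,
    minimize_interval,
)
from .transforms import asinh_transform

__all__ = [
    "ExpressionMatrix",
    "gene_groups",
    "optimize_cofactor_microarray",
    "mean_sd_profile",
    "read_expression_matrix",
    "write_expression_matrix",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of raw expression intensities."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")

    @property
    def m_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def drop_incomplete(self) -> "ExpressionMatrix":
        """Drop rows containing any non-finite value."""
        keep = np.all(np.isfinite(self.values), axis=1)
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} gene rows with missing values",
                stacklevel=2,
            )
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.sample_ids),
            self.values[keep],
        )


def gene_groups(mat: ExpressionMatrix, cofactor: float) -> PeakSet:
    """Make each gene a variance group on the asinh(x / cofactor) scale.

    Every gene contributes a group of size N with the mean and unbiased
    variance of its transformed row; genes with near-zero variance are
    dropped with a warning. Packaged as a :class:`PeakSet` so Bartlett's
    statistic applies unchanged.
    """
    t = asinh_transform(mat.values, cofactor)
    mu = t.mean(axis=1)
    var = t.var(axis=1, ddof=1)
    keep = var >= MIN_PEAK_VARIANCE
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} genes with near-zero variance dropped",
            stacklevel=2,
        )
    peaks = [
        DensityPeak(
            sample_id="*",
            channel=gid,
            mode=float(m),
            lo=-math.inf,
            hi=math.inf,
            n_i=mat.n_samples,
            mu_i=float(m),
            var_i=float(v),
        )
        for gid, m, v, k in zip(mat.gene_ids, mu, var, keep)
        if k
    ]
    return PeakSet(channel="genes", cofactor=float(cofactor), peaks=peaks)


def optimize_cofactor_microarray(
    mat: ExpressionMatrix,
    c_low: float = C_LOW_DEFAULT,
    c_high: float = C_HIGH_DEFAULT,
    tol: float = TOL_DEFAULT,
) -> CofactorScan:
    """Single-cofactor search over the whole matrix.

    Identical interval scheme to the flow-cytometry search, with the
    objective ``c -> Bartlett(gene_groups(mat, c))``.
    """
    scan = CofactorScan(channel="genes", c_low=float(c_low), c_high=float(c_high))

    def recorded(c: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = gene_groups(mat, c)
        b = bartlett_statistic(ps) if ps.m >= 2 else math.inf
        scan.trace.append((float(c), float(b)))
        return b

    for a, b in _log_intervals(c_low, c_high):
        before = len(scan.trace)
        c_i, b_i = minimize_interval(recorded, math.exp(a), math.exp(b), tol=tol)
        scan.interval_optima.append((c_i, b_i, len(scan.trace) - before))
    finite = [(c, bb) for c, bb, _ in scan.interval_optima if math.isfinite(bb)]
    if not finite:
        raise OptimizationFailed("no cofactor produced 2 or more usable gene groups")
    scan.b_star = min(bb for _, bb in finite)
    scan.c_star = min(c for c, bb in finite if bb == scan.b_star)
    return scan


def mean_sd_profile(
    mat: ExpressionMatrix,
    cofactor: float | None = None,
    window: int | None = None,
) -> pd.DataFrame:
    """Per-gene mean/sd table with rank of mean and a running-median sd.

    With ``cofactor`` set, means and sds are computed on the
    ``asinh(x / cofactor)`` scale; otherwise on the raw scale. Ranks of
    means are 1..m (ties broken by gene order). The running median of sd
    over a sliding rank window (default width ``max(51, m // 20)``, forced
    odd) is the diagnostic curve: flat means no mean-variance dependence.
    """
    vals = mat.values if cofactor is None else asinh_transform(mat.values, cofactor)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    m = mat.m_genes
    order = np.lexsort((np.arange(m), mu))  # stable: ties broken by gene order
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(1, m + 1)
    if window is None:
        window = max(51, m // 20)
    if window % 2 == 0:
        window += 1
    window = min(window, m if m % 2 == 1 else m - 1)
    sd_by_rank = sd[order]
    run_med = (
        pd.Series(sd_by_rank).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    running = np.empty(m)
    running[order] = run_med
    return pd.DataFrame(
        {
            "gene_id": mat.gene_ids,
            "mean": mu,
            "sd": sd,
            "rank_of_mean": rank,
            "running_median_sd": running,
        }
    )


def read_expression_matrix(path: str, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix (first column gene ids)."""
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(
            f"{path}: expression matrix needs >= 1 gene row and >= 2 sample columns, "
            f"got shape {df.shape}"
        )
    values = df.to_numpy(dtype=np.float64)
    mat = ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )
    return mat.drop_incomplete()


def write_expression_matrix(mat: ExpressionMatrix, path: str, sep: str = "\t") -> None:
    pd.DataFrame(mat.values, index=mat.gene_ids, columns=mat.sample_ids).to_csv(
        path, sep=sep, index_label="gene_id"
    )
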
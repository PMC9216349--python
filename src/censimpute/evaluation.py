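"""Reconstruction-quality criteria and their aggregation.

Four criteria compare a completed (reconstructed) dataset with the true
simulated sample of the same run: percent deviation of the mean, SD and
median, plus the two-sample Kolmogorov-Smirnov distance between the two
empirical distributions. Deviations are taken against the true *sample*
statistics rather than the theoretical distribution, so they are
well-defined per run (and for deletion, whose completed dataset is shorter).
For multiple imputation the criteria are computed per completed dataset and
averaged over the m datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError
from .imputation import ImputedDatasets

__all__ = [
    "RunMetrics",
    "AggregateMetrics",
    "METRIC_FIELDS",
    "percent_deviation",
    "ks_two_sample",
    "evaluate_reconstruction",
    "aggregate",
]

METRIC_FIELDS = ("delta_mean_pct", "delta_sd_pct", "delta_median_pct", "d_ks")


@dataclass(frozen=True)
class RunMetrics:
    """Criteria for one run: percent deviations and KS distance (in [0, 1])."""

    delta_mean_pct: float
    delta_sd_pct: float
    delta_median_pct: float
    d_ks: float

    def __post_init__(self):
        if not 0.0 <= self.d_ks <= 1.0:
            raise DomainError(f"d_ks must lie in [0, 1], got {self.d_ks}")


@dataclass(frozen=True)
class AggregateMetrics:
    """Per-method averages of the run criteria, plus mean-squared deviations.

    The averages have the shape of the study's summary tables; the ``mse_*``
    fields are the means of the squared per-run (or per-grid-cell) values,
    used to rank methods over a cutoff sweep.
    """

    delta_mean_pct: float
    delta_sd_pct: float
    delta_median_pct: float
    d_ks: float
    mse_mean: float
    mse_sd: float
    mse_median: float
    mse_ks: float
    n_runs: int


def percent_deviation(est: float, ref: float) -> float:
    """Signed percent deviation 100 * (est - ref) / ref; ref must be nonzero."""
    if ref == 0:
        raise DomainError("percent deviation undefined for a zero reference")
    return 100.0 * (est - ref) / ref


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov distance.

    The supremum over x of |ECDF_a(x) - ECDF_b(x)|, attained at a jump point
    of one of the samples, so it suffices to scan the pooled sorted values.
    """
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    if xa.size == 0 or xb.size == 0:
        raise InsufficientDataError("KS distance requires two nonempty samples")
    grid = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, grid, side="right") / xa.size
    cdf_b = np.searchsorted(xb, grid, side="right") / xb.size
    return float(np.abs(cdf_a - cdf_b).max())


def evaluate_reconstruction(
    true_values: Sequence[float], imputed: ImputedDatasets
) -> RunMetrics:
    """Score completed datasets against the true sample of the same run.

    Each of the m completed datasets is compared with ``true_values`` on all
    four criteria; the results are averaged across datasets. SDs use the
    n-1 denominator on both sides.
    """
    truth = np.asarray(true_values, dtype=float)
    if truth.size == 0:
        raise InsufficientDataError("true sample must be nonempty")
    ref_mean = truth.mean()
    ref_sd = truth.std(ddof=1)
    ref_median = float(np.median(truth))

    rows = np.array([
        (
            percent_deviation(d.mean(), ref_mean),
            percent_deviation(d.std(ddof=1), ref_sd),
            percent_deviation(float(np.median(d)), ref_median),
            ks_two_sample(truth, d),
        )
        for d in imputed.datasets
    ])
    means = rows.mean(axis=0)
    return RunMetrics(
        delta_mean_pct=float(means[0]),
        delta_sd_pct=float(means[1]),
        delta_median_pct=float(means[2]),
        d_ks=float(means[3]),
    )


def aggregate(runs: Sequence[RunMetrics]) -> AggregateMetrics:
    """Average run criteria and their squares over runs or grid cells."""
    if len(runs) == 0:
        raise InsufficientDataError("aggregate requires at least one run")
    table = np.array([
        [r.delta_mean_pct, r.delta_sd_pct, r.delta_median_pct, r.d_ks] for r in runs
    ])
    avg = table.mean(axis=0)
    msq = (table**2).mean(axis=0)
    return AggregateMetrics(
        delta_mean_pct=float(avg[0]),
        delta_sd_pct=float(avg[1]),
        delta_median_pct=float(avg[2]),
        d_ks=float(avg[3]),
        mse_mean=float(msq[0]),
        mse_sd=float(msq[1]),
        mse_median=float(msq[2]),
        mse_ks=float(msq[3]),
        n_runs=len(runs),
    )
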
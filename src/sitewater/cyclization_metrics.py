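"""Cyclization-competence metrics from C1-C10 distance series.

The first ring closure of the farnesyl chain requires C1 and C10 to come
close; a substrate conformation with a large C1-C10 separation cannot
cyclize.  These functions turn a trajectory into a per-frame distance
series, bin it into fixed-width histograms, and estimate the fraction of
frames beyond an "extended" threshold (default 8.0 Å, strict >) together
with a Wilson 95% confidence interval.  Replica sets are pooled by frame
concatenation, with the per-replica spread reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import SiteSpecError
from .trajectory_io import (
    ResolvedSite,
    SiteSpec,
    Trajectory,
    minimum_image_distance,
)

__all__ = [
    "DistanceSeries",
    "Histogram",
    "FractionAbove",
    "CyclizationSummary",
    "distance_series",
    "distance_histogram",
    "fraction_above",
    "aggregate_cyclization",
]

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_THRESHOLD = 8.0
REPORT_RANGE = (3.0, 12.0)  # fixed report range for cross-variant comparability


@dataclass
class DistanceSeries:
    """Per-frame distances in Å with a variant/replica label."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distance series must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Histogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class FractionAbove:
    fraction: float
    ci_low: float
    ci_high: float
    n: int
    n_above: int
    threshold: float


@dataclass
class CyclizationSummary:
    pooled_histogram: Histogram
    pooled: FractionAbove
    per_replica: list[FractionAbove]
    across_replica_sd: float
    labels: list[str] = field(default_factory=list)


def distance_series(
    traj: Trajectory,
    site: SiteSpec,
    role_a: str = "c1",
    role_b: str = "c10",
) -> DistanceSeries:
    """One minimum-image distance per frame between two single-atom roles."""
    rs = ResolvedSite(traj.topology, site)
    ia, ib = rs.single(role_a), rs.single(role_b)
    values = np.array(
        [minimum_image_distance(f, ia, ib) for f in traj.frames], dtype=float
    )
    return DistanceSeries(values=values, label=traj.label)


def distance_histogram(
    series: DistanceSeries,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] | None = None,
) -> Histogram:
    """Fixed-width histogram with half-open bins [lo, lo + w).

    The default range is [floor(min), ceil(max)], widened by one bin when the
    maximum lands exactly on the upper edge, so counts always conserve the
    series length.  With an explicit range, out-of-range values are dropped.
    """
    if len(series) == 0:
        raise ValueError("cannot histogram an empty distance series")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = series.values
    if range is None:
        lo = math.floor(values.min())
        hi = math.ceil(values.max())
        if hi <= values.max():
            hi += bin_width
    else:
        lo, hi = range
        if hi <= lo:
            raise ValueError("range upper bound must exceed lower bound")
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((values - lo) / bin_width).astype(int)
    keep = (idx >= 0) & (idx < n_bins) & (values >= lo)
    counts = np.bincount(idx[keep], minlength=n_bins)
    return Histogram(bin_edges=edges, counts=counts)


def fraction_above(
    series: DistanceSeries, threshold: float = DEFAULT_THRESHOLD
) -> FractionAbove:
    """Fraction of frames with distance strictly above *threshold*, with a
    Wilson 95% confidence interval."""
    if len(series) == 0:
        raise ValueError("cannot compute a fraction over an empty series")
    n = len(series)
    n_above = int((series.values > threshold).sum())
    lo, hi = proportion_confint(n_above, n, alpha=0.05, method="wilson")
    return FractionAbove(
        fraction=n_above / n,
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_above=n_above,
        threshold=threshold,
    )


def aggregate_cyclization(
    replicas: Sequence[DistanceSeries],
    threshold: float = DEFAULT_THRESHOLD,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] | None = REPORT_RANGE,
) -> CyclizationSummary:
    """Pool replicas by frame concatenation and report per-replica spread.

    The pooled fraction therefore weights replicas by frame count; the
    across-replica standard deviation (ddof=1, 0 for a single replica)
    quantifies replicate-to-replicate variability.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    labels = [s.label for s in replicas]
    if len(set(labels)) != len(labels):
        import warnings

        warnings.warn("replica labels are not unique", stacklevel=2)
    pooled_series = DistanceSeries(
        values=np.concatenate([s.values for s in replicas]), label="pooled"
    )
    per_replica = [fraction_above(s, threshold) for s in replicas]
    fractions = [f.fraction for f in per_replica]
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0
    return CyclizationSummary(
        pooled_histogram=distance_histogram(pooled_series, bin_width, range),
        pooled=fraction_above(pooled_series, threshold),
        per_replica=per_replica,
        across_replica_sd=sd,
        labels=labels,
    )
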
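"""Population statistics over ensembles and the inference distance metrics.

Histograms use unit-width bins anchored at zero by default, matching the
molecule-equivalent units of the probe signals; the Wasserstein (earth
mover's) distance between two histograms on a shared grid is the sum of
absolute CDF differences times the bin width, which for one-dimensional
distributions coincides with the optimal-transport cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import EnsembleData


@dataclass(frozen=True)
class SignalHistogram:
    """Histogram of per-cell signals (molecule equivalents)."""

    edges: np.ndarray   # strictly increasing, length n_bins + 1
    counts: np.ndarray  # non-negative, length n_bins

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        if counts.shape != (edges.size - 1,) or np.any(counts < 0):
            raise ValueError("counts must be non-negative, one per bin")
        if counts.sum() == 0:
            raise ValueError("empty histogram")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def cdf(self) -> np.ndarray:
        """Empirical CDF evaluated at the right edge of each bin; ends at 1."""
        return np.cumsum(self.counts) / self.n

    @classmethod
    def from_samples(
        cls,
        values: Sequence[float],
        bin_width: float = 1.0,
        upper: float | None = None,
    ) -> "SignalHistogram":
        """Bin samples into unit-width (by default) bins anchored at 0."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("no samples")
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        hi = float(values.max()) if upper is None else upper
        n_bins = max(1, int(math.floor(hi / bin_width)) + 1)
        edges = np.arange(n_bins + 1, dtype=float) * bin_width
        counts, _ = np.histogram(values, bins=edges)
        return cls(edges=edges, counts=counts.astype(float))


def _common_grid(a: SignalHistogram, b: SignalHistogram):
    """Pad two zero-anchored, equal-width histograms onto one grid."""
    wa, wb = a.bin_widths, b.bin_widths
    if not (
        np.allclose(wa, wa[0]) and np.allclose(wb, wb[0]) and np.isclose(wa[0], wb[0])
        and np.isclose(a.edges[0], b.edges[0])
    ):
        raise ValueError("histograms must share bin width and anchor for resampling")
    width = wa[0]
    n = max(a.counts.size, b.counts.size)
    ca = np.zeros(n)
    cb = np.zeros(n)
    ca[: a.counts.size] = a.counts
    cb[: b.counts.size] = b.counts
    return ca, cb, width


def wasserstein_distance(a: SignalHistogram, b: SignalHistogram) -> float:
    """Earth mover's distance between two histograms.

    Computed as sum over bins of |CDF_a - CDF_b| * bin_width on a shared
    grid (histograms with the same width and anchor are padded to a common
    length).  Symmetric; zero iff the two CDFs agree on the grid.
    """
    ca, cb, width = _common_grid(a, b)
    cdf_a = np.cumsum(ca) / ca.sum()
    cdf_b = np.cumsum(cb) / cb.sum()
    return float(np.abs(cdf_a - cdf_b).sum() * width)


def wasserstein_from_samples(
    a: Sequence[float], b: Sequence[float], bin_width: float = 1.0
) -> float:
    """Convenience: bin two sample sets onto one grid and compare."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    upper = max(a.max(), b.max()) if a.size and b.size else 0.0
    ha = SignalHistogram.from_samples(a, bin_width=bin_width, upper=upper)
    hb = SignalHistogram.from_samples(b, bin_width=bin_width, upper=upper)
    return wasserstein_distance(ha, hb)


def mean_trace(ensemble: EnsembleData, channel: str) -> pd.Series:
    """Arithmetic mean of one signal channel per sample time."""
    from .engine import _channel_column

    col = _channel_column(channel)
    if ensemble.df.empty:
        raise ValueError("empty ensemble")
    return ensemble.df.groupby("time_min")[col].mean()


def fano_trace(ensemble: EnsembleData, channel: str) -> pd.Series:
    """Population variance over mean per sample time; NaN where the mean is 0."""
    from .engine import _channel_column

    col = _channel_column(channel)
    grouped = ensemble.df.groupby("time_min")[col]
    mean = grouped.mean()
    var = grouped.var(ddof=0)
    out = var / mean
    out[mean == 0] = np.nan
    return out


def mean_squared_error(trace_a, trace_b) -> float:
    """MSE between two time-indexed mean traces on identical time grids."""
    a = pd.Series(trace_a)
    b = pd.Series(trace_b)
    if len(a) != len(b) or not np.allclose(a.index.to_numpy(dtype=float),
                                           b.index.to_numpy(dtype=float)):
        raise ValueError("time grids do not match")
    diff = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    return float(np.mean(diff**2))


def weighted_time_aggregate(
    distances, weighting: str = "uniform", tau: float | None = None
) -> float:
    """Aggregate per-timepoint distances into one scalar.

    uniform: plain average.  exponential: weights w_t = exp(-t / tau),
    emphasizing early timepoints (where the activation rate shapes the first
    nascent distributions); tau must be positive.
    """
    series = pd.Series(distances)
    t = series.index.to_numpy(dtype=float)
    d = series.to_numpy(dtype=float)
    if weighting == "uniform":
        w = np.ones_like(d)
    elif weighting == "exponential":
        if tau is None or tau <= 0:
            raise ValueError("exponential weighting requires tau > 0")
        w = np.exp(-t / tau)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.sum(w * d) / np.sum(w))
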
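"""Statistics pipeline for flashed-target reaction times.

Mirrors the analysis applied to the recorded sessions: erratic strikes
below 200 ms are screened out (no other filter), summary statistics
and 5 ms histograms are computed, empirical CDFs carry a pointwise 95%
bootstrap band, and the horizontal lag between two conditions is read
off as the median of per-quantile shifts.  Diagnostics cover the
residual gap bias (longer preceding gaps give shorter RTs) and the
stability of session means over days.

Quantiles use linear interpolation of order statistics (the type-7
convention, numpy's default), stated here for cross-language
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .chain_sim import TrialRecord

__all__ = [
    "SCREEN_THRESHOLD_MS",
    "CdfWithCi",
    "LagEstimate",
    "SummaryStats",
    "GapBias",
    "StabilityResult",
    "screen",
    "summarize",
    "histogram",
    "ecdf_ci",
    "lag_between",
    "gap_bias",
    "session_stability",
]

#: Responses at or below this are treated as erratic strikes.
SCREEN_THRESHOLD_MS = 200.0


class SummaryStats(NamedTuple):
    mean_ms: float
    sd_ms: float
    n: int


@dataclass(frozen=True)
class CdfWithCi:
    """Empirical CDF with a pointwise bootstrap confidence band."""

    grid_ms: np.ndarray
    cdf: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: int
    level: float = 0.95


@dataclass(frozen=True)
class LagEstimate:
    """Horizontal shift of condition B relative to condition A."""

    lag_ms: float
    quantile_grid: np.ndarray
    per_quantile_ms: np.ndarray


class GapBias(NamedTuple):
    slope: float           # ms of RT per ms of preceding gap
    intercept: float
    contrast_ms: float     # mean RT at shortest gap minus at longest gap
    stderr: float


class StabilityResult(NamedTuple):
    slope_ms_per_session: float
    flagged: bool
    threshold_ms: float


def _as_array(rts) -> np.ndarray:
    return np.asarray(rts, dtype=float)


def screen(rts, threshold_ms: float = SCREEN_THRESHOLD_MS) -> np.ndarray:
    """Drop erratic strikes: keep rts strictly above the threshold,
    order preserved."""
    if threshold_ms < 0:
        raise ValueError("threshold_ms must be non-negative")
    arr = _as_array(rts)
    return arr[arr > threshold_ms]


def summarize(rts) -> SummaryStats:
    """Arithmetic mean and sample (ddof=1) standard deviation."""
    arr = _as_array(rts)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    return SummaryStats(mean_ms=float(arr.mean()),
                        sd_ms=float(arr.std(ddof=1)), n=int(arr.size))


def histogram(rts, bin_ms: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Counts over bins aligned to multiples of ``bin_ms``.

    Edges span the data range; counts always sum to n (the maximum
    lands in the last bin even when it sits on the right edge).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    arr = _as_array(rts)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty sample")
    lo = np.floor(arr.min() / bin_ms) * bin_ms
    hi = np.ceil(arr.max() / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    nbins = int(round((hi - lo) / bin_ms))
    edges = lo + bin_ms * np.arange(nbins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return edges, counts


def _ecdf_on_grid(sorted_sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_sample, grid, side="right") / \
        sorted_sample.size


def ecdf_ci(rts, n_boot: int = 1000, seed: int = 0, *,
            grid_ms: np.ndarray | None = None,
            level: float = 0.95) -> CdfWithCi:
    """Empirical CDF with a pointwise percentile-bootstrap band.

    Resamples the data ``n_boot`` times with replacement and takes the
    (1-level)/2 and (1+level)/2 pointwise percentiles of the bootstrap
    CDFs; a final isotonic pass keeps the band monotone and bracketing
    the point estimate.  Seeded and deterministic.
    """
    arr = np.sort(_as_array(rts))
    if arr.size < 20:
        raise ValueError("need at least 20 samples for a bootstrap band")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    grid = np.unique(arr) if grid_ms is None else _as_array(grid_ms)
    cdf = _ecdf_on_grid(arr, grid)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        resample = np.sort(arr[rng.integers(0, arr.size, arr.size)])
        boot[b] = _ecdf_on_grid(resample, grid)
    alpha = 0.5 * (1.0 - level)
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    lo = np.clip(np.minimum(np.maximum.accumulate(lo), cdf), 0.0, 1.0)
    hi = np.clip(np.maximum(np.maximum.accumulate(hi), cdf), 0.0, 1.0)
    return CdfWithCi(grid_ms=grid, cdf=cdf, lo=lo, hi=hi, n=int(arr.size),
                     level=level)


def lag_between(a, b, q_lo: float = 0.10, q_hi: float = 0.90,
                n_q: int = 33) -> LagEstimate:
    """Horizontal CDF shift of sample ``b`` relative to ``a``.

    Per-quantile shift = Q_b(p) - Q_a(p) on an even grid of ``n_q``
    probabilities in [q_lo, q_hi]; the lag is the median of the shifts.
    Inputs are expected to be screened (strictly positive) RTs.
    """
    a = _as_array(a)
    b = _as_array(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must hold at least 2 values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("inputs must be screened, strictly positive RTs")
    if not (0.0 < q_lo < q_hi < 1.0):
        raise ValueError("need 0 < q_lo < q_hi < 1")
    grid = np.linspace(q_lo, q_hi, n_q)
    shifts = np.quantile(b, grid) - np.quantile(a, grid)
    return LagEstimate(lag_ms=float(np.median(shifts)), quantile_grid=grid,
                       per_quantile_ms=shifts)


def _gaps_and_rts(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        return (trials["gap_ms"].to_numpy(dtype=float),
                trials["rt_ms"].to_numpy(dtype=float))
    if len(trials) and isinstance(trials[0], TrialRecord):
        return (np.array([t.gap_ms for t in trials], dtype=float),
                np.array([t.rt_ms for t in trials], dtype=float))
    gaps, rts = trials
    return _as_array(gaps), _as_array(rts)


def gap_bias(trials) -> GapBias:
    """Least-squares RT-on-gap slope plus the extreme-gap contrast.

    ``contrast_ms`` is the mean RT at the shortest admissible gap minus
    the mean at the longest one (positive when longer waits speed the
    response, the residual anticipation bias).
    """
    gaps, rts = _gaps_and_rts(trials)
    if np.unique(gaps).size < 2:
        raise ValueError("need at least 2 distinct gap values")
    res = _stats.linregress(gaps, rts)
    contrast = float(rts[gaps == gaps.min()].mean()
                     - rts[gaps == gaps.max()].mean())
    return GapBias(slope=float(res.slope), intercept=float(res.intercept),
                   contrast_ms=contrast, stderr=float(res.stderr))


def session_stability(session_means: Sequence[float],
                      threshold_ms: float = 5.0) -> StabilityResult:
    """Least-squares trend of session means against session index.

    Flags a drift (habituation / boredom) when the absolute slope
    exceeds ``threshold_ms`` per session.
    """
    means = _as_array(session_means)
    if means.size < 3:
        raise ValueError("need at least 3 sessions")
    idx = np.arange(means.size, dtype=float)
    res = _stats.linregress(idx, means)
    slope = float(res.slope)
    return StabilityResult(slope_ms_per_session=slope,
                           flagged=abs(slope) > threshold_ms,
                           threshold_ms=threshold_ms)
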
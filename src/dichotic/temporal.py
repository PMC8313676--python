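"""Percent-of-sentence warping and surrogate-tested cross-correlation.

Because sentences differ in length, per-trial neural time courses are
mapped onto a common axis of 100 bins covering 1% increments of sentence
presentation, lightly smoothed with a centred 3-bin rectangular window.
Group-average warped time courses of the two neural measures are then
related by a normalized cross-correlation whose chance level is calibrated
with independently permuted surrogate time courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "warp_to_percent",
    "final_word_mean",
    "group_timecourse",
    "crosscorrelate",
    "surrogate_band",
    "lag_to_ms",
    "CrossCorrelation",
]

logger = logging.getLogger(__name__)


def warp_to_percent(series: np.ndarray, start: int, end: int,
                    n_bins: int = 100, smooth_bins: int = 3) -> np.ndarray:
    """Map ``series[start:end]`` onto ``n_bins`` percent-of-sentence bins.

    Each sample is assigned to the bin covering its relative position in
    the sentence; bin values are (NaN-aware) means, then smoothed with a
    centred ``smooth_bins``-wide rectangular window evaluated at every bin
    (edge bins average over the available neighbours).
    """
    x = np.asarray(series, dtype=float)[start:end]
    n = len(x)
    if n < n_bins:
        raise ValueError(
            f"sentence has {n} samples, fewer than {n_bins} bins: "
            "bins would be empty"
        )
    # sample i (i = 0..n-1) sits at relative position (i + 0.5)/n
    bins = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1).astype(int)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    good = ~np.isnan(x)
    np.add.at(sums, bins[good], x[good])
    np.add.at(counts, bins[good], 1)
    with np.errstate(invalid="ignore"):
        binned = sums / np.where(counts > 0, counts, np.nan)
    return _smooth(binned, smooth_bins)


def _smooth(binned: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return binned
    half = width // 2
    n = len(binned)
    out = np.empty(n)
    for b in range(n):
        lo, hi = max(0, b - half), min(n, b + half + 1)
        seg = binned[lo:hi]
        out[b] = np.nanmean(seg) if np.any(~np.isnan(seg)) else np.nan
    return out


def final_word_mean(warped: np.ndarray, final_fraction: float = 0.35) -> float:
    """Mean of the final ``final_fraction`` of a warped series.

    With 100 bins and the default fraction this is the mean of bins 66-100,
    the interval covering final-word presentation.  Missing bins are
    skipped with a logged count.
    """
    warped = np.asarray(warped, dtype=float)
    n = len(warped)
    k = int(round(final_fraction * n))
    seg = warped[n - k:]
    n_missing = int(np.isnan(seg).sum())
    if n_missing:
        logger.info("final-word mean: %d of %d bins missing", n_missing, k)
    if n_missing == k:
        return float("nan")
    return float(np.nanmean(seg))


def group_timecourse(warped: np.ndarray, subjects: np.ndarray,
                     mask: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average warped time course: subject means, then mean +/- SEM.

    ``warped`` is (n_trials, n_bins); ``subjects`` labels each trial; an
    optional boolean ``mask`` selects trials (e.g. one attention
    condition).  The SEM is the between-subject standard error, NaN when
    only one subject contributes.
    """
    warped = np.asarray(warped, dtype=float)
    subjects = np.asarray(subjects)
    if mask is not None:
        warped, subjects = warped[mask], subjects[mask]
    uniq = np.unique(subjects)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
        per_subject = np.vstack([
            np.nanmean(warped[subjects == s], axis=0) for s in uniq
        ])
        grand = np.nanmean(per_subject, axis=0)
        if len(uniq) > 1:
            sem = np.nanstd(per_subject, axis=0, ddof=1) / np.sqrt(len(uniq))
        else:
            sem = np.full(warped.shape[1], np.nan)
    return grand, sem


def crosscorrelate(x: np.ndarray, y: np.ndarray,
                   max_lag: int = 50) -> np.ndarray:
    """Normalized cross-correlation of two equal-length series.

    Both series are mean-removed; values are scaled by the product of the
    full-series standard deviations and the overlap length, so they are
    comparable across lags and bounded by [-1, 1] at lag 0 for identical
    inputs.  A positive peak lag means ``x`` leads ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d series")
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("cross-correlation undefined: zero-variance input")
    xm, ym = x - x.mean(), y - y.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = xm[: n - k], ym[k:]
        else:
            a, b = xm[-k:], ym[: n + k]
        out[i] = np.dot(a, b) / (len(a) * sx * sy)
    return out


@dataclass
class CrossCorrelation:
    """Cross-correlation values with surrogate percentile bands."""

    lags: np.ndarray            # lag in bins; positive = first series leads
    values: np.ndarray
    lo: np.ndarray | None = None   # 2.5th surrogate percentile per lag
    hi: np.ndarray | None = None   # 97.5th surrogate percentile per lag

    @property
    def peak_lag(self) -> int:
        return int(self.lags[int(np.argmax(self.values))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))


def surrogate_band(x: np.ndarray, y: np.ndarray, max_lag: int = 50,
                   n_permutations: int = 5000,
                   rng: np.random.Generator | None = None,
                   percentiles: tuple[float, float] = (2.5, 97.5),
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag percentile band of cross-correlations under permutation.

    Each surrogate independently permutes the bin order of ``x`` and of
    ``y`` and recomputes the normalized cross-correlation; the band is the
    per-lag percentile envelope over surrogates.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("surrogates undefined: zero-variance input")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    surr = np.empty((n_permutations, 2 * max_lag + 1))
    for i in range(n_permutations):
        xs = x[rng.permutation(len(x))]
        ys = y[rng.permutation(len(y))]
        surr[i] = crosscorrelate(xs, ys, max_lag=max_lag)
    lo = np.percentile(surr, percentiles[0], axis=0)
    hi = np.percentile(surr, percentiles[1], axis=0)
    return lo, hi


def lag_to_ms(lag_bins: float, mean_sentence_duration_ms: float) -> float:
    """Convert a percent-bin lag to milliseconds of mean sentence time."""
    return lag_bins * mean_sentence_duration_ms / 100.0
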
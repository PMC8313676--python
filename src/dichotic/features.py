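"""Spectral features: onset envelopes, alpha power and its lateralization.

The alpha route mirrors the standard single-trial analysis chain for
spatial-attention EEG work: Morlet wavelet power in the 8-12 Hz band,
variance-stabilizing Box-Cox transform, whole-trial normalization per
parcel and frequency, and a robust (inverse-logit based) lateralization
index computed after averaging over the region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet
from scipy.signal import resample_poly

from .config import FeatureConfig
from .synthetic import Dataset
from .temporal import final_word_mean, warp_to_percent

__all__ = [
    "onset_envelope",
    "morlet_alpha_power",
    "boxcox_transform",
    "normalize_whole_trial",
    "alpha_lateralization_index",
    "roi_window_summaries",
    "ali_features",
]


def onset_envelope(broadband: np.ndarray, fs_in: float,
                   fs_out: float = 125.0, smooth_ms: float = 20.0) -> np.ndarray:
    """Onset (rate-of-change) envelope of a non-negative amplitude envelope.

    The amplitude envelope is smoothed with a short moving average, first-
    differenced, half-wave rectified and resampled to ``fs_out``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sample rates must be positive")
    x = np.asarray(broadband, dtype=float)
    if np.any(x < 0):
        raise ValueError("amplitude envelope must be non-negative")
    w = max(int(round(smooth_ms / 1000.0 * fs_in)), 1)
    if w > 1:
        from scipy.ndimage import uniform_filter1d
        x = uniform_filter1d(x, w, mode="nearest")
    d = np.diff(x, prepend=x[0])
    d[d < 0] = 0.0
    if fs_in == fs_out:
        return d
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return np.clip(resample_poly(d, frac.numerator, frac.denominator), 0.0, None)


def morlet_alpha_power(epochs: np.ndarray, sfreq: float,
                       freqs=(8.0, 9.0, 10.0, 11.0, 12.0),
                       n_cycles: float = 6.0) -> np.ndarray:
    """Single-trial wavelet power (trials, parcels, freqs, times).

    Power is the squared magnitude of Morlet wavelet coefficients with a
    fixed number of cycles per frequency.
    """
    epochs = np.atleast_3d(np.asarray(epochs, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    min_len = int(np.ceil(n_cycles / freqs.min() * sfreq))
    if epochs.shape[-1] < min_len:
        raise ValueError(
            f"epoch too short for the wavelet support: need at least "
            f"{min_len} samples at {sfreq:g} Hz (= {n_cycles:g} cycles of "
            f"{freqs.min():g} Hz), got {epochs.shape[-1]}"
        )
    return tfr_array_morlet(epochs, sfreq=sfreq, freqs=freqs,
                            n_cycles=n_cycles, output="power", zero_mean=False)


def boxcox_transform(power: np.ndarray, exponent: float = 0.5) -> np.ndarray:
    """Box-Cox transform (x**p - 1)/p; monotone, reduces right skew."""
    if exponent == 0:
        return np.log(power)
    return (np.power(power, exponent) - 1.0) / exponent


def normalize_whole_trial(power: np.ndarray) -> np.ndarray:
    """Subtract, per parcel and frequency, the grand mean over trials and time.

    ``power`` is (trials, parcels, freqs, times); the output has zero mean
    over the (trials x times) plane for every parcel-frequency pair.
    """
    power = np.asarray(power, dtype=float)
    mean = np.nanmean(power, axis=(0, 3), keepdims=True)
    return power - mean


def alpha_lateralization_index(power_ipsi: np.ndarray,
                               power_contra: np.ndarray) -> np.ndarray:
    """Robust alpha lateralization index of two (normalized) power series.

    Both inputs are mapped through the inverse-logit (logistic) function
    into (0, 1) and contrasted as (a - b)/(a + b), bounding the index to
    (-1, 1).  Positive values mean more alpha power ipsilateral than
    contralateral to the probed ear.
    """
    a = np.asarray(power_ipsi, dtype=float)
    b = np.asarray(power_contra, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ipsi and contra series must have the same shape")
    la = 1.0 / (1.0 + np.exp(-a))
    lb = 1.0 / (1.0 + np.exp(-b))
    return (la - lb) / (la + lb)


def roi_window_summaries(ali: np.ndarray, times: np.ndarray,
                         sentence_start_s: float, sentence_end_s: float,
                         final_fraction: float = 0.35,
                         n_bins: int = 100,
                         window_s: tuple[float, float] | None = None,
                         ) -> tuple[float, float]:
    """Sentence-window mean and warped final-interval mean of an ALI series.

    The sentence mean is taken over ``window_s`` (defaults to the sentence
    bounds); the final summary warps the actual sentence interval onto the
    percent axis and averages its last ``final_fraction``.  Missing samples
    (e.g. wavelet edge exclusion) are ignored.
    """
    ali = np.asarray(ali, dtype=float)
    if window_s is None:
        window_s = (sentence_start_s, sentence_end_s)
    in_win = (times >= window_s[0]) & (times < window_s[1])
    seg_win = ali[in_win]
    sentence_mean = (float(np.nanmean(seg_win))
                     if np.any(~np.isnan(seg_win)) else np.nan)
    in_sent = (times >= sentence_start_s) & (times < sentence_end_s)
    seg = ali[in_sent]
    warped = warp_to_percent(seg, 0, len(seg), n_bins=n_bins)
    final_mean = final_word_mean(warped, final_fraction=final_fraction)
    return sentence_mean, final_mean


@dataclass
class AlphaFeatures:
    """Per-trial ALI summaries plus the warped per-trial time courses."""

    table: pd.DataFrame          # subject, trial, ali_sentence, ali_final
    warped: np.ndarray           # (n_trials, n_bins) percent-of-sentence ALI
    ali_series: np.ndarray       # (n_trials, n_times) ALI at the analysis rate
    times: np.ndarray


def ali_features(dataset: Dataset, config: FeatureConfig | None = None) -> AlphaFeatures:
    """Full alpha-lateralization feature chain for a synthetic dataset.

    Per subject: wavelet power -> Box-Cox -> whole-trial normalization per
    parcel/frequency -> average over frequencies and ROI parcels per
    hemisphere -> robust ALI with hemispheres assigned ipsi/contra by the
    probed ear -> sentence and final-interval summaries.
    """
    config = config or FeatureConfig()
    sfreq = dataset.config.epoch_rate
    if not np.isclose(sfreq, config.analysis_rate):
        raise ValueError(
            f"alpha analysis expects epochs at {config.analysis_rate:g} Hz, "
            f"got {sfreq:g} Hz"
        )
    times = dataset.epoch_times
    trials = dataset.trials
    n_trials = len(trials)

    left = dataset.parcel_hemi == "left"
    right = dataset.parcel_hemi == "right"

    ali_all = np.full((n_trials, len(times)), np.nan)
    # half the support of the longest wavelet, used for edge exclusion
    half_support = config.n_cycles / (2.0 * min(config.freqs))
    valid = np.ones(len(times), bool)
    if config.edge_exclusion:
        valid = ((times >= times[0] + half_support)
                 & (times <= times[-1] - half_support))

    for _, idx in trials.groupby("subject").indices.items():
        power = morlet_alpha_power(dataset.epochs[idx], sfreq,
                                   freqs=config.freqs, n_cycles=config.n_cycles)
        power = boxcox_transform(power, config.boxcox_exponent)
        power = normalize_whole_trial(power)
        # ROI average: mean over frequencies, then over parcels per hemisphere
        hemi_power = {
            "left": power[:, left].mean(axis=(1, 2)),
            "right": power[:, right].mean(axis=(1, 2)),
        }
        ears = trials["probed_ear"].to_numpy()[idx]
        for j, (row, ear) in enumerate(zip(idx, ears)):
            ipsi, contra = hemi_power[ear][j], hemi_power["left" if ear == "right" else "right"][j]
            ali = alpha_lateralization_index(ipsi, contra)
            ali[~valid] = np.nan
            ali_all[row] = ali

    fs_env = dataset.config.sample_rate
    rows, warped_rows = [], []
    for i, row in enumerate(trials.itertuples()):
        start_s = row.sentence_start / fs_env + dataset.config.epoch_start
        end_s = row.sentence_end / fs_env + dataset.config.epoch_start
        sent_mean, final_mean = roi_window_summaries(
            ali_all[i], times, start_s, end_s,
            final_fraction=config.final_fraction,
            window_s=config.sentence_window)
        in_sent = (times >= start_s) & (times < end_s)
        seg = ali_all[i][in_sent]
        warped_rows.append(warp_to_percent(seg, 0, len(seg)))
        rows.append({"subject": row.subject, "trial": row.trial,
                     "ali_sentence": sent_mean, "ali_final": final_mean})
    return AlphaFeatures(table=pd.DataFrame(rows),
                         warped=np.vstack(warped_rows),
                         ali_series=ali_all, times=times)
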
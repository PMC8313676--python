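"""Synthetic dichotic-listening dataset with recorded ground truth.

The generator emulates the study design every downstream stage expects:

* a 2 x 2 cue design (spatial x semantic, informative vs. uninformative)
  with a fixed number of trials per cell and balanced probed ears;
* pairs of five-word "sentences" represented as non-negative onset-envelope
  pulse trains, temporally aligned at final-word onset so that sentence
  onsets differ by a controlled asynchrony;
* bilateral source-parcel time series containing (i) lag-structured
  envelope encoding that is stronger for the attended than the ignored
  stream and stronger contralateral to each ear's input, (ii) ~10 Hz alpha
  oscillations whose ipsi/contralateral power ratio depends on the spatial
  cue, and (iii) 1/f background noise;
* behavioural outcomes (accuracy category, reaction time) drawn from a
  logistic / linear model with planted cue and neural-state effects.

All randomness flows through a single :class:`numpy.random.Generator`
derived from the configured seed, so a dataset is a pure function of its
configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "StimulusPair",
    "Dataset",
    "simulate_stimulus_pair",
    "simulate_source_epoch",
    "simulate_behaviour",
    "generate_dataset",
]

SIDES = ("left", "right")


@dataclass
class StimulusPair:
    """Two onset envelopes at the envelope rate, aligned at final-word onset.

    ``envelopes[side]`` holds the full-epoch series (zeros outside the
    sentence); ``start[side]``/``end[side]`` are sample indices of sentence
    start/end; ``final_onset`` is the shared final-word onset sample.
    """

    envelopes: dict
    start: dict
    end: dict
    final_onset: int
    sample_rate: float

    def duration_ms(self, side: str) -> float:
        return (self.end[side] - self.start[side]) / self.sample_rate * 1000.0

    def asynchrony_ms(self) -> float:
        return abs(self.start["left"] - self.start["right"]) / self.sample_rate * 1000.0


@dataclass
class Dataset:
    """In-memory synthetic dataset: design table, stimuli, epochs, truth."""

    config: SimulationConfig
    trials: pd.DataFrame          # one row per trial (design + behaviour)
    envelopes: dict               # {"left"|"right": (n_trials, n_env_samples)} at 125 Hz
    epochs: np.ndarray            # (n_trials, n_parcels, n_epoch_samples) at epoch_rate
    truth: pd.DataFrame           # planted per-trial ground truth
    parcel_hemi: np.ndarray       # hemisphere label per parcel row ("left"/"right")
    epoch_times: np.ndarray       # seconds relative to cue onset, epoch rate
    env_times: np.ndarray         # seconds relative to cue onset, envelope rate


def _pulse_train(duration_s: float, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One sentence as a train of two-syllable Hann word pulses.

    Each word is a primary pulse (stressed syllable, jittered amplitude)
    followed by a weaker secondary pulse at a jittered offset, so the two
    streams of a pair differ in within-word fine structure even where word
    onsets coincide — as the envelopes of different words do.  Word-onset
    gaps are drawn quasi-regularly and rescaled so the final word ends
    exactly at ``duration_s``.  Returns the series (length =
    ceil(duration * fs)) and the sample index of the final-word onset.
    """
    fs = config.sample_rate
    width = config.word_width_ms / 1000.0
    n_words = config.n_words
    amp1 = rng.uniform(0.85, 1.15, n_words)
    off2 = rng.uniform(0.16, 0.24, n_words)      # secondary-syllable offset, s
    off2[-1] = 0.20   # fixed final-word extent so every pair fits its window
    width2 = 0.10
    amp2 = rng.uniform(0.25, 0.45, n_words) * amp1

    gaps = rng.uniform(*config.word_gap_range_ms, size=n_words - 1) / 1000.0
    final_extent = max(width, off2[-1] + width2)
    span = duration_s - final_extent          # first-word onset to final-word onset
    onsets = np.concatenate([[0.0], np.cumsum(gaps)])
    onsets *= span / onsets[-1]

    n = int(np.ceil(duration_s * fs))
    t = np.arange(n) / fs
    env = np.zeros(n)

    def add(onset, w, a):
        x = (t - onset - w / 2) / w
        inside = np.abs(x) <= 0.5
        env[inside] += a * np.cos(np.pi * x[inside]) ** 2

    for k, onset in enumerate(onsets):
        add(onset, width, amp1[k])
        add(onset + off2[k], width2, amp2[k])
    return env, int(round(onsets[-1] * fs))


def simulate_stimulus_pair(config: SimulationConfig, rng: np.random.Generator,
                           asynchrony_ms: float | None = None,
                           probed_first: bool | None = None,
                           probed_side: str = "left") -> StimulusPair:
    """Draw one dichotic sentence pair aligned at final-word onset.

    Sentence durations are uniform over the configured range and the onset
    asynchrony uniform over [0, asynchrony_max_ms], with either stream
    leading with equal probability.  The asynchrony is realized by giving
    the two sentences pre-final-word spans that differ by exactly the drawn
    asynchrony: both onsets are then fixed by the shared final-word onset.
    Durations are drawn symmetrically around a common base value so each
    sentence's duration stays inside the configured range.
    """
    fs = config.sample_rate
    lo, hi = (d / 1000.0 for d in config.duration_range_ms)
    if asynchrony_ms is None:
        asynchrony_ms = float(rng.uniform(0.0, config.asynchrony_max_ms))
    if probed_first is None:
        probed_first = bool(rng.random() < 0.5)
    asyn = asynchrony_ms / 1000.0
    base = float(rng.uniform(lo + asyn / 2, hi - asyn / 2))
    dur = {probed_side: base + asyn / 2 if probed_first else base - asyn / 2}
    other = "right" if probed_side == "left" else "left"
    dur[other] = 2 * base - dur[probed_side]

    window_start = int(round(config.sentence_window[0] * fs))
    epoch_len = int(round((config.epoch_end - config.epoch_start) * fs))
    t0 = int(round(-config.epoch_start * fs))  # sample index of cue onset time 0

    series, final_rel = {}, {}
    for side in SIDES:
        series[side], final_rel[side] = _pulse_train(dur[side], config, rng)

    # place the pair: earliest sentence onset at the start of the
    # presentation window; both final-word onsets coincide
    span = {s: final_rel[s] for s in SIDES}
    final_onset = t0 + window_start + max(span.values())
    envelopes, start, end = {}, {}, {}
    for side in SIDES:
        s0 = final_onset - span[side]
        env = np.zeros(epoch_len)
        seg = series[side]
        if s0 < 0 or s0 + len(seg) > epoch_len:
            raise ValueError("sentence placement exceeds the epoch window")
        env[s0:s0 + len(seg)] = seg
        envelopes[side] = env
        start[side], end[side] = s0, s0 + len(seg)
    if max(end.values()) > t0 + int(round(config.sentence_window[1] * fs)):
        raise ValueError("sentence placement exceeds the presentation window")
    return StimulusPair(envelopes=envelopes, start=start, end=end,
                        final_onset=final_onset, sample_rate=fs)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit variance."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _kernel_on_grid(config: SimulationConfig) -> np.ndarray:
    """Interpolate the configured (lag, weight) kernel onto the epoch rate."""
    pairs = np.asarray(config.trf_kernel, dtype=float)
    lag_max = pairs[:, 0].max()
    grid = np.arange(0, int(np.ceil(lag_max * config.epoch_rate)) + 1) / config.epoch_rate
    return np.interp(grid, pairs[:, 0], pairs[:, 1], left=0.0, right=0.0)


def _upsample_hold(x: np.ndarray, factor: int) -> np.ndarray:
    """Zero-order-hold upsampling (exact at original sample points)."""
    return np.repeat(x, factor)


def simulate_source_epoch(pair: StimulusPair, attended_side: str,
                          alpha_ratio: float, gain_attended: float,
                          gain_ignored: float, config: SimulationConfig,
                          rng: np.random.Generator,
                          noise_scale: float = 1.0) -> np.ndarray:
    """Simulate one trial's (parcels x time) source epoch at the epoch rate.

    Parcels are ordered left hemisphere first.  Each parcel carries the
    kernel-convolved mixture of the two streams' envelopes (attended gain
    vs. ignored gain; contralateral vs. ipsilateral routing), a sinusoid at
    the alpha frequency whose ipsi/contra (relative to the attended ear)
    power ratio equals ``alpha_ratio``, and 1/f plus white noise scaled to
    the configured envelope SNR.  ``noise_scale`` multiplies the noise SD
    (0 gives noise-free epochs).
    """
    if attended_side not in SIDES:
        raise ValueError(f"unknown side {attended_side!r}")
    fs_env, fs_ep = config.sample_rate, config.epoch_rate
    factor = int(round(fs_ep / fs_env))
    if not np.isclose(factor * fs_env, fs_ep):
        raise ValueError("epoch_rate must be an integer multiple of sample_rate")

    n_hemi = config.n_parcels_per_hemisphere
    n_parcels = 2 * n_hemi
    n_times = int(round((config.epoch_end - config.epoch_start) * fs_ep))
    kernel = _kernel_on_grid(config)
    ignored_side = "right" if attended_side == "left" else "left"

    # envelope-driven component per hemisphere
    drive = {}
    for hemi in SIDES:
        total = np.zeros(n_times)
        for side, gain in ((attended_side, gain_attended), (ignored_side, gain_ignored)):
            lat = config.contra_gain if hemi != side else config.ipsi_gain
            env = _upsample_hold(pair.envelopes[side], factor)[:n_times]
            total += gain * lat * np.convolve(env, kernel)[:n_times]
        drive[hemi] = total

    # reference amplitude for SNR scaling: attended stream's contralateral drive
    contra_hemi = ignored_side  # hemisphere contralateral to the attended ear
    ref_env = _upsample_hold(pair.envelopes[attended_side], factor)[:n_times]
    ref = gain_attended * config.contra_gain * np.convolve(ref_env, kernel)[:n_times]
    ref_sd = ref[pair.start[attended_side] * factor:pair.end[attended_side] * factor].std()
    noise_sd = noise_scale * (ref_sd / config.snr_envelope if config.snr_envelope > 0 else 0.0)

    # alpha amplitudes: ipsi/contra power ratio (re: attended ear) = alpha_ratio
    amp = {
        attended_side: config.alpha_amplitude * np.sqrt(alpha_ratio),  # ipsilateral hemisphere
        ignored_side: config.alpha_amplitude,
    }
    t = (np.arange(n_times) / fs_ep) + config.epoch_start
    epoch = np.empty((n_parcels, n_times))
    for p in range(n_parcels):
        hemi = SIDES[p // n_hemi]
        phase = rng.uniform(0, 2 * np.pi)
        alpha = amp[hemi] * np.sin(2 * np.pi * config.alpha_freq * t + phase)
        noise = np.zeros(n_times)
        if noise_sd > 0:
            pink = _pink_noise(n_times, config.noise_exponent, rng)
            white = rng.standard_normal(n_times) * config.white_noise_fraction
            mix = pink + white
            noise = noise_sd * mix / mix.std()
        epoch[p] = drive[hemi] + alpha + noise
    return epoch


def _logistic(x):
    from scipy.special import expit
    return expit(x)


def simulate_behaviour(trials: pd.DataFrame, tracking_state: np.ndarray,
                       config: SimulationConfig,
                       rng: np.random.Generator,
                       tracking_trait: np.ndarray | None = None) -> pd.DataFrame:
    """Draw accuracy categories and reaction times for a design table.

    ``trials`` must carry deviation-coded columns (``spatial_code`` etc.),
    z-scored ``age_z``/``pta_z`` and a ``subject_idx`` column;
    ``tracking_state`` is the per-trial latent attention state (z-scaled,
    within-subject) that also modulates the planted envelope gains, and
    ``tracking_trait`` the per-trial (subject-constant) trait level.
    Returns a copy of the table with ``correct``, ``accuracy`` (category),
    ``rt`` and ``speed`` columns filled in.
    """
    if tracking_trait is None:
        tracking_trait = np.zeros(len(trials))
    coefs_a = config.behaviour_coefs["accuracy"]
    coefs_s = config.behaviour_coefs["speed"]
    out = trials.copy()
    n = len(out)
    n_sub = out["subject_idx"].max() + 1
    n_item = out["item"].max() + 1

    u_a = rng.normal(0, coefs_a["subject_sd"], n_sub)
    v_a = rng.normal(0, coefs_a["item_sd"], n_item)
    linpred = (coefs_a["intercept"]
               + coefs_a["spatial_cue"] * out["spatial_code"].to_numpy()
               + coefs_a["semantic_cue"] * out["semantic_code"].to_numpy()
               + coefs_a["tracking_within"] * tracking_state
               + coefs_a["probed_ear"] * out["ear_code"].to_numpy()
               + coefs_a["age"] * out["age_z"].to_numpy()
               + coefs_a["pta"] * out["pta_z"].to_numpy()
               + u_a[out["subject_idx"].to_numpy()]
               + v_a[out["item"].to_numpy()])
    correct = rng.random(n) < _logistic(linpred)

    u_s = rng.normal(0, coefs_s["subject_sd"], n_sub)
    v_s = rng.normal(0, coefs_s["item_sd"], n_item)
    speed_z = (coefs_s["intercept"]
               + coefs_s["spatial_cue"] * out["spatial_code"].to_numpy()
               + coefs_s["semantic_cue"] * out["semantic_code"].to_numpy()
               + coefs_s["tracking_between"] * tracking_trait
               + coefs_s["probed_ear"] * out["ear_code"].to_numpy()
               + coefs_s["age"] * out["age_z"].to_numpy()
               + coefs_s["pta"] * out["pta_z"].to_numpy()
               + u_s[out["subject_idx"].to_numpy()]
               + v_s[out["item"].to_numpy()]
               + rng.normal(0, coefs_s["residual_sd"], n))
    speed = coefs_s["mean_speed"] + coefs_s["speed_scale"] * speed_z
    speed = np.clip(speed, 0.26, None)   # keep reaction times inside the response window
    rt = 1.0 / speed

    timeout = rng.random(n) < config.timeout_fraction
    accuracy = np.where(correct, "correct", "error")
    # split errors into spatial confusions vs. random errors (2:1, echoing
    # the dominance of stream confusions in dichotic presentation)
    err = ~correct & ~timeout
    confusion = rng.random(n) < 2.0 / 3.0
    accuracy = np.where(err & confusion, "spatial_confusion", accuracy)
    accuracy = np.where(err & ~confusion, "random_error", accuracy)
    accuracy = np.where(timeout, "timeout", accuracy)
    rt = np.where(timeout, 4.0, rt)

    out["linpred_accuracy"] = linpred
    out["correct"] = np.where(timeout, False, correct)
    out["accuracy"] = accuracy
    out["rt"] = rt
    out["speed"] = 1.0 / rt
    return out


def _design_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced 2x2 design table with probed ear balanced within cell."""
    rows = []
    n_cell = config.n_trials_per_cell
    if n_cell % 2:
        ears = ["left", "right"] * (n_cell // 2) + ["left"]
    else:
        ears = ["left", "right"] * (n_cell // 2)
    ages = rng.uniform(39, 80, config.n_subjects)
    ptas = np.clip(rng.normal(15, 8, config.n_subjects), -5, None)
    for s in range(config.n_subjects):
        trial_rows = []
        for spatial in ("informative", "uninformative"):
            for semantic in ("specific", "general"):
                for ear in ears:
                    trial_rows.append((spatial, semantic, ear))
        order = rng.permutation(len(trial_rows))
        for t, idx in enumerate(order):
            spatial, semantic, ear = trial_rows[idx]
            rows.append({
                "subject": f"S{s + 1:03d}", "subject_idx": s, "trial": t,
                "item": int(idx),
                "spatial_cue": spatial, "semantic_cue": semantic,
                "probed_ear": ear,
                "age": ages[s], "pta": ptas[s],
            })
    df = pd.DataFrame(rows)
    df["spatial_code"] = np.where(df["spatial_cue"] == "informative", 0.5, -0.5)
    df["semantic_code"] = np.where(df["semantic_cue"] == "specific", 0.5, -0.5)
    df["ear_code"] = np.where(df["probed_ear"] == "right", 0.5, -0.5)
    for col, zcol in (("age", "age_z"), ("pta", "pta_z")):
        vals = df.groupby("subject")[col].first()
        sd = vals.std(ddof=1) if len(vals) > 1 else 1.0
        sd = sd if sd > 0 else 1.0
        df[zcol] = (df[col] - vals.mean()) / sd
    return df


def generate_behaviour_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Design table plus simulated behaviour, without stimuli or epochs.

    Useful for studying the behavioural model machinery at full sample
    sizes where simulating source epochs would be wasteful.  The latent
    tracking state/trait values are attached as columns.
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set for reproducibility")
    rng = np.random.default_rng(config.seed)
    trials = _design_table(config, rng)
    state = rng.standard_normal(len(trials))
    trait = rng.standard_normal(config.n_subjects)[trials["subject_idx"].to_numpy()]
    trials["probed_first"] = rng.random(len(trials)) < 0.5
    trials["probed_first_code"] = np.where(trials["probed_first"], 0.5, -0.5)
    out = simulate_behaviour(trials, state, config, rng, tracking_trait=trait)
    out["tracking_state"] = state
    out["tracking_trait"] = trait
    return out


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate the full synthetic dataset (stimuli, epochs, behaviour, truth).

    Deterministic given ``config.seed``; refuses to run without a seed so
    that every dataset is reproducible from its configuration alone.
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set for reproducibility")
    rng = np.random.default_rng(config.seed)

    trials = _design_table(config, rng)
    n_trials = len(trials)
    fs_env, fs_ep = config.sample_rate, config.epoch_rate
    n_env = int(round((config.epoch_end - config.epoch_start) * fs_env))
    n_ep = int(round((config.epoch_end - config.epoch_start) * fs_ep))
    n_parcels = 2 * config.n_parcels_per_hemisphere

    envelopes = {s: np.zeros((n_trials, n_env)) for s in SIDES}
    epochs = np.zeros((n_trials, n_parcels, n_ep))
    truth_rows = []
    tracking_state = rng.standard_normal(n_trials)        # within-subject state
    trait_by_subject = rng.standard_normal(config.n_subjects)
    tracking_trait = trait_by_subject[trials["subject_idx"].to_numpy()]
    latent = tracking_state + 0.5 * tracking_trait        # modulates planted gains

    for i, row in enumerate(trials.itertuples()):
        selective = row.spatial_cue == "informative"
        attended = row.probed_ear
        probed_first = bool(rng.random() < 0.5)
        pair = simulate_stimulus_pair(config, rng, probed_first=probed_first,
                                      probed_side=attended)
        if selective:
            g_att = config.gain_attended * (1.0 + config.tracking_state_sd * latent[i])
            g_att = max(g_att, 0.0)
            g_ign = config.gain_ignored
            ratio = config.alpha_power_ratio_selective
        else:
            g_att = g_ign = 0.5 * (config.gain_attended + config.gain_ignored)
            ratio = config.alpha_power_ratio_divided
        epochs[i] = simulate_source_epoch(pair, attended, ratio, g_att, g_ign,
                                          config, rng)
        for side in SIDES:
            envelopes[side][i] = pair.envelopes[side]
        truth_rows.append({
            "subject": row.subject, "trial": row.trial,
            "attended_side": attended,
            "asynchrony_ms": pair.asynchrony_ms(),
            "probed_first": probed_first,
            "alpha_ratio": ratio,
            "gain_attended": g_att, "gain_ignored": g_ign,
            "tracking_state": tracking_state[i],
            "tracking_trait": tracking_trait[i],
            "sentence_start": pair.start[attended],
            "sentence_end": pair.end[attended],
            "final_onset": pair.final_onset,
        })
    truth = pd.DataFrame(truth_rows)

    trials = trials.copy()
    trials["probed_first"] = truth["probed_first"].to_numpy()
    trials["probed_first_code"] = np.where(trials["probed_first"], 0.5, -0.5)
    trials["asynchrony_ms"] = truth["asynchrony_ms"].to_numpy()
    trials["sentence_start"] = truth["sentence_start"].to_numpy()
    trials["sentence_end"] = truth["sentence_end"].to_numpy()
    trials = simulate_behaviour(trials, tracking_state, config, rng,
                                tracking_trait=tracking_trait)
    truth["linpred_accuracy"] = trials["linpred_accuracy"].to_numpy()
    trials = trials.drop(columns=["linpred_accuracy"])

    epoch_times = np.arange(n_ep) / fs_ep + config.epoch_start
    env_times = np.arange(n_env) / fs_env + config.epoch_start
    hemi = np.array(["left"] * config.n_parcels_per_hemisphere
                    + ["right"] * config.n_parcels_per_hemisphere)
    return Dataset(config=config, trials=trials, envelopes=envelopes,
                   epochs=epochs, truth=truth, parcel_hemi=hemi,
                   epoch_times=epoch_times, env_times=env_times)
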
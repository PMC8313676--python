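"""Configuration objects for the simulation and analysis pipeline.

Every stage of the pipeline is parameterized by a small dataclass; the
:class:`PipelineConfig` bundles them and round-trips through YAML so that a
run is fully described by one file plus a master seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "FeatureConfig",
    "DecodingConfig",
    "TemporalConfig",
    "StatsConfig",
    "PipelineConfig",
    "default_trf_kernel",
    "default_behaviour_coefs",
]


def default_trf_kernel() -> tuple[tuple[float, float], ...]:
    """Default envelope-encoding kernel as (lag_s, weight) pairs.

    A smooth N1/P2-like impulse response: a negative deflection around
    100 ms followed by a larger positive deflection around 220 ms, sampled
    on an 8-ms lag grid over 0-352 ms.  Component widths are >= 120 ms so
    the kernel's energy sits in the slow (<8 Hz) band that the decoding
    route analyses.
    """
    lags = np.arange(0, 45) * 0.008

    def bump(center: float, width: float) -> np.ndarray:
        x = (lags - center) / width  # bump support: [center-width/2, center+width/2]
        out = np.zeros_like(lags)
        inside = np.abs(x) <= 0.5
        out[inside] = np.cos(np.pi * x[inside]) ** 2
        return out

    k = -0.9 * bump(0.10, 0.12) + 1.0 * bump(0.22, 0.18)
    return tuple((float(l), float(w)) for l, w in zip(lags, k))


def default_behaviour_coefs() -> dict:
    """Planted behavioural model coefficients.

    Accuracy coefficients are log-odds for deviation-coded (+/-0.5)
    predictors, so ``exp(coef)`` is the full-range odds ratio.  Speed
    coefficients are on the z-scored response-speed scale; the variance
    components are chosen so the total variance of simulated speed is ~1,
    which keeps planted slopes directly comparable to standardized betas
    estimated after z-scoring.
    """
    return {
        "accuracy": {
            "intercept": 2.1,
            "spatial_cue": math.log(3.5),
            "semantic_cue": math.log(1.1),
            "tracking_within": math.log(1.06),
            "probed_ear": math.log(1.25),
            "age": math.log(0.80),
            "pta": math.log(0.75),
            "subject_sd": 0.7,
            "item_sd": 0.3,
        },
        "speed": {
            "intercept": 0.0,
            "spatial_cue": 0.57,
            "semantic_cue": 0.20,
            "tracking_between": 0.08,
            "probed_ear": 0.08,
            "age": -0.15,
            "pta": -0.05,
            "subject_sd": 0.35,
            "item_sd": 0.10,
            "residual_sd": 0.85,
            "mean_speed": 0.62,
            "speed_scale": 0.17,
        },
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic dichotic-listening dataset."""

    n_subjects: int = 1
    n_trials_per_cell: int = 60          # trials per cue-cue cell (2x2 design)
    sample_rate: float = 125.0           # envelope rate, Hz
    epoch_rate: float = 250.0            # source-epoch rate, Hz
    n_parcels_per_hemisphere: int = 5
    trf_kernel: tuple[tuple[float, float], ...] = field(default_factory=default_trf_kernel)
    gain_attended: float = 1.0
    gain_ignored: float = 0.3
    contra_gain: float = 1.0             # envelope gain, hemisphere contralateral to the ear
    ipsi_gain: float = 0.5               # envelope gain, ipsilateral hemisphere
    alpha_freq: float = 10.0
    alpha_power_ratio_selective: float = 1.5   # ipsi/contra alpha power, informative cue
    alpha_power_ratio_divided: float = 1.0
    alpha_amplitude: float = 1.0         # alpha amplitude in the contralateral hemisphere
    noise_exponent: float = 1.0          # 1/f^exponent background
    snr_envelope: float = 2.0            # attended-envelope signal SD / noise SD
    white_noise_fraction: float = 0.2    # extra white noise, as fraction of pink noise SD
    tracking_state_sd: float = 0.2       # per-trial multiplicative jitter of the attended gain
    timeout_fraction: float = 0.02
    behaviour_coefs: dict = field(default_factory=default_behaviour_coefs)
    seed: int | None = None

    # epoch layout, seconds relative to spatial-cue onset
    epoch_start: float = -0.5
    epoch_end: float = 6.5
    sentence_window: tuple[float, float] = (3.5, 6.5)
    duration_range_ms: tuple[float, float] = (2183.0, 2963.0)
    asynchrony_max_ms: float = 580.0
    n_words: int = 5
    word_width_ms: float = 150.0
    word_gap_range_ms: tuple[float, float] = (350.0, 550.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_cell < 1:
            raise ValueError("subject and trial counts must be positive")
        if self.n_parcels_per_hemisphere < 1:
            raise ValueError("need at least one parcel per hemisphere")
        if not (self.gain_attended >= self.gain_ignored >= 0):
            raise ValueError("expected gain_attended >= gain_ignored >= 0")
        if self.alpha_power_ratio_selective <= 0 or self.alpha_power_ratio_divided <= 0:
            raise ValueError("alpha power ratios must be positive")
        if self.epoch_end <= self.epoch_start:
            raise ValueError("empty epoch window")
        lo, hi = self.duration_range_ms
        if not (0 < lo <= hi):
            raise ValueError("invalid sentence duration range")
        win = (self.sentence_window[1] - self.sentence_window[0]) * 1000.0
        if hi > win:
            raise ValueError(
                f"sentences up to {hi:.0f} ms cannot fit the "
                f"{win:.0f} ms presentation window"
            )

    @property
    def n_trials_per_subject(self) -> int:
        return 4 * self.n_trials_per_cell


@dataclass
class FeatureConfig:
    """Alpha-power / lateralization feature extraction parameters."""

    freqs: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0, 12.0)
    n_cycles: float = 6.0
    analysis_rate: float = 250.0        # required epoch rate for wavelet analysis
    boxcox_exponent: float = 0.5
    sentence_window: tuple[float, float] = (3.5, 6.5)
    final_fraction: float = 0.35        # final-word interval: last 35% of the sentence
    roi: str = "auditory"
    edge_exclusion: bool = True         # mask samples within half the wavelet support of epoch edges


@dataclass
class DecodingConfig:
    """Backward-model (stimulus reconstruction) parameters."""

    sample_rate: float = 125.0
    lag_min_s: float = -0.1
    lag_max_s: float = 0.5
    lambda_grid: tuple[float, ...] = tuple(10.0 ** e for e in range(-5, 11))
    sliding_window_s: float = 0.248
    pad_s: float = 0.6                  # zero padding between concatenated training trials
    n_folds_lambda: int = 5
    denominator_tol: float = 1e-6       # tracking index: |r_att + r_ign| below this -> missing
    lowpass_hz: float | None = 8.0      # speech-band isolation of the neural response
    attended_only_index: bool = False   # control variant: index from the attended decoder only

    @property
    def lags(self) -> np.ndarray:
        """Integer sample lags covering the configured lag range."""
        # floor at both ends keeps half-sample bounds (e.g. -100 ms at 8 ms
        # steps) to the stated lag count while integer bounds stay inclusive
        lo = int(np.floor(self.lag_min_s * self.sample_rate))
        hi = int(np.floor(self.lag_max_s * self.sample_rate)) + 1
        return np.arange(lo, hi)

    @property
    def window_samples(self) -> int:
        return int(round(self.sliding_window_s * self.sample_rate))


@dataclass
class TemporalConfig:
    """Percent-of-sentence warping and cross-correlation parameters."""

    n_bins: int = 100
    smooth_bins: int = 3
    max_lag_bins: int = 50
    n_permutations: int = 5000
    permute_unit: str = "bins"          # "bins" | "trials" | "subjects"


@dataclass
class StatsConfig:
    """Mixed-effects model specifications and testing conventions.

    ``formulas`` maps a model name to a dict with keys ``formula`` (lme4
    syntax; random effects in parentheses), ``family`` (``binomial`` or
    ``gaussian``) and optionally ``data`` (``accuracy`` or ``speed`` table).
    """

    q: float = 0.05
    formulas: dict = field(default_factory=lambda: {
        "accuracy": {
            "formula": "correct ~ spatial_cue * semantic_cue + probed_ear"
                       " + probed_first + age_z + pta_z"
                       " + nti_within + nti_between"
                       " + (1 | subject) + (1 | item)",
            "family": "binomial",
            "data": "accuracy",
        },
        "speed": {
            "formula": "speed_z ~ spatial_cue * semantic_cue + probed_ear"
                       " + probed_first + age_z + pta_z"
                       " + nti_within + nti_between"
                       " + (1 | subject) + (1 | item)",
            "family": "gaussian",
            "data": "speed",
        },
    })


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus the master seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int | None = None

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["trf_kernel"] = [list(p) for p in self.simulation.trf_kernel]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, block):
            if block is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in block.items() if k in names}
            return klass(**_coerce(klass, kwargs))

        def _coerce(klass, kwargs):
            out = dict(kwargs)
            for key in ("trf_kernel",):
                if key in out and out[key] is not None:
                    out[key] = tuple(tuple(p) for p in out[key])
            for f in dataclasses.fields(klass):
                if f.name in out and isinstance(out[f.name], list):
                    if f.name != "trf_kernel":
                        out[f.name] = tuple(out[f.name])
            return out

        return cls(
            simulation=build(SimulationConfig, d.get("simulation")),
            features=build(FeatureConfig, d.get("features")),
            decoding=build(DecodingConfig, d.get("decoding")),
            temporal=build(TemporalConfig, d.get("temporal")),
            stats=build(StatsConfig, d.get("stats")),
            seed=d.get("seed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
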
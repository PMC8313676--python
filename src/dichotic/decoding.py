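"""Backward (stimulus-reconstruction) models of speech-envelope tracking.

A linear decoder maps time-lagged multiparcel neural responses onto the
onset envelope of one speech stream:

    s_hat(t) = sum_n sum_tau g(tau, n) r(t + tau, n)

with lags tau spanning -100..500 ms (neural activity lagging the
stimulus).  Weights are the closed-form ridge solution

    g = (R'R + lambda * m * I)^-1 R's,

where m is the mean of the trace of R'R, making the ridge grid comparable
across subjects.  Separate attended/ignored decoders are trained per
attend-side on selective-attention trials; every trial is then decoded by
leave-one-out, time-resolved reconstruction accuracy is a 248-ms sliding
Pearson correlation, and the tracking index contrasts attended vs. ignored
accuracy.  Backward weights are made neurophysiologically interpretable
through the covariance-based backward-to-forward transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.signal import filtfilt, firwin

from .config import DecodingConfig
from .synthetic import Dataset
from .temporal import final_word_mean, warp_to_percent

__all__ = [
    "build_lag_design",
    "train_decoder",
    "select_lambda",
    "loo_reconstruct",
    "sliding_correlation",
    "tracking_index",
    "forward_transform",
    "validate_decoder_specificity",
    "Decoder",
    "decode_dataset",
]

logger = logging.getLogger(__name__)
SIDES = ("left", "right")


def build_lag_design(response: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Time-lagged design matrix from a (n_times, n_parcels) response.

    Column block ``n`` holds parcel ``n`` shifted by every lag; entry
    ``[t, n * n_lags + j]`` equals ``response[t + lags[j], n]`` with
    out-of-range samples zero-filled.
    """
    r = np.asarray(response, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    n_times, n_parcels = r.shape
    lags = np.asarray(lags, dtype=int)
    out = np.zeros((n_times, n_parcels * len(lags)))
    for n in range(n_parcels):
        for j, lag in enumerate(lags):
            col = n * len(lags) + j
            if lag >= 0:
                span = max(n_times - lag, 0)
                out[:span, col] = r[lag:lag + span, n]
            else:
                span = max(n_times + lag, 0)
                out[-lag:-lag + span, col] = r[:span, n]
    return out


@dataclass
class Decoder:
    """Ridge decoder weights with training metadata."""

    weights: np.ndarray          # (n_lags * n_parcels,) flat weight vector
    lags: np.ndarray
    n_parcels: int
    lam: float                   # ridge parameter
    m: float                     # mean trace of R'R (per-subject scalar)
    attend_side: str | None = None
    role: str | None = None      # "attended" | "ignored"
    column_mean: np.ndarray | None = None
    target_mean: float = 0.0

    @property
    def weight_matrix(self) -> np.ndarray:
        """Weights as (n_lags, n_parcels)."""
        return self.weights.reshape(self.n_parcels, len(self.lags)).T

    def predict(self, design: np.ndarray) -> np.ndarray:
        x = design - (self.column_mean if self.column_mean is not None else 0.0)
        return x @ self.weights + self.target_mean


def _concat_padded(blocks: list[np.ndarray], pad: int) -> np.ndarray:
    """Concatenate along time with ``pad`` zero rows/samples between blocks."""
    out = []
    shape_tail = blocks[0].shape[1:]
    for i, b in enumerate(blocks):
        if i:
            out.append(np.zeros((pad,) + shape_tail))
        out.append(b)
    return np.concatenate(out, axis=0)


def train_decoder(designs: list[np.ndarray], envelopes: list[np.ndarray],
                  lam: float, lags: np.ndarray, n_parcels: int,
                  pad: int = 75, attend_side: str | None = None,
                  role: str | None = None) -> Decoder:
    """Closed-form ridge decoder from concatenated training trials.

    Trials are zero-padded before concatenation to suppress boundary
    artefacts; design columns and the target envelope are mean-centered
    over the training set (the model carries no intercept column).
    """
    if len(designs) < 2:
        raise ValueError("need at least two training trials")
    R = _concat_padded(designs, pad)
    s = _concat_padded([np.asarray(e, dtype=float) for e in envelopes], pad)
    col_mean = R.mean(axis=0)
    s_mean = s.mean()
    Rc = R - col_mean
    sc = s - s_mean
    G = Rc.T @ Rc
    m = np.trace(G) / G.shape[0]
    A = G + lam * m * np.eye(G.shape[0])
    try:
        w = cho_solve(cho_factor(A), Rc.T @ sc)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(G)
        raise np.linalg.LinAlgError(
            f"ridge system singular at lambda={lam:g}: R'R has rank "
            f"{rank} < {G.shape[0]}"
        )
    return Decoder(weights=w, lags=np.asarray(lags), n_parcels=n_parcels,
                   lam=lam, m=m, attend_side=attend_side, role=role,
                   column_mean=col_mean, target_mean=s_mean)


def sliding_correlation(reconstructed: np.ndarray, actual: np.ndarray,
                        window: int = 31) -> np.ndarray:
    """Pearson correlation in a centred sliding window, stepped by 1 sample.

    Output has the input length; positions whose window extends past the
    series bounds, or where either windowed segment has zero variance, are
    NaN (missing, never imputed as 0).
    """
    x = np.asarray(reconstructed, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = len(x)
    out = np.full(n, np.nan)
    if n < window:
        return out
    half = window // 2
    # rolling first/second moments via cumulative sums
    def roll(v):
        c = np.concatenate([[0.0], np.cumsum(v)])
        return c[window:] - c[:-window]
    sx, sy = roll(x), roll(y)
    sxx, syy, sxy = roll(x * x), roll(y * y), roll(x * y)
    cov = sxy - sx * sy / window
    vx = sxx - sx * sx / window
    vy = syy - sy * sy / window
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    tol = 1e-12 * window
    r[(vx <= tol) | (vy <= tol)] = np.nan
    out[half:half + len(r)] = np.clip(r, -1.0, 1.0)
    return out


def tracking_index(r_attended: np.ndarray, r_ignored: np.ndarray,
                   denom_tol: float = 1e-6) -> np.ndarray:
    """Neural tracking index (r_att - r_ign)/(r_att + r_ign), elementwise.

    Missing where either input is missing or the denominator magnitude
    falls below ``denom_tol``.  Values are stored unclipped: the index is
    unbounded when one correlation is negative.
    """
    a = np.asarray(r_attended, dtype=float)
    b = np.asarray(r_ignored, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    den = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a - b) / den
    out[np.abs(den) < denom_tol] = np.nan
    return out


def forward_transform(decoder: Decoder, design_cov: np.ndarray,
                      recon_var: float) -> np.ndarray:
    """Backward-to-forward transformation of decoder weights.

    Forward (encoding) weights are ``Cov(R) @ g / Var(s_hat)`` — the
    covariance-scaled backward weights, normalized by the variance of the
    reconstructed stimulus.  Returned as (n_lags, n_parcels).
    """
    a = design_cov @ decoder.weights
    if recon_var > 0:
        a = a / recon_var
    return a.reshape(decoder.n_parcels, len(decoder.lags)).T


@dataclass
class SubjectDecoding:
    """Per-trial tracking results for one subject."""

    table: pd.DataFrame          # per-trial summaries
    warped_nti: np.ndarray       # (n_trials, 100) percent-of-sentence index
    decoders: dict               # (side, role) -> Decoder trained on all trials
    lam: float


def _prepare_responses(dataset: Dataset, config: DecodingConfig) -> np.ndarray:
    """Epochs resampled to the decoding rate, optionally low-passed.

    The source epochs are simulated at an integer multiple of the decoding
    rate; after an optional zero-phase FIR low-pass (speech-band isolation)
    they are decimated by slicing, which is exact for noise-free inputs.
    """
    fs_ep = dataset.config.epoch_rate
    fs = config.sample_rate
    factor = int(round(fs_ep / fs))
    if not np.isclose(factor * fs, fs_ep):
        raise ValueError(
            f"decoding requires epochs at a multiple of {fs:g} Hz, "
            f"got {fs_ep:g} Hz"
        )
    x = dataset.epochs
    if config.lowpass_hz is not None and config.lowpass_hz < fs_ep / 2:
        numtaps = int(2 * fs_ep / config.lowpass_hz) | 1
        taps = firwin(numtaps, config.lowpass_hz, fs=fs_ep)
        x = filtfilt(taps, [1.0], x, axis=-1)
    return x[..., ::factor]


def _trial_grams(designs, envs_att, envs_ign, pad):
    """Per-trial padded Gram contributions (G_i, b_att_i, b_ign_i, counts)."""
    out = []
    for X, sa, si in zip(designs, envs_att, envs_ign):
        # zero padding adds zero rows only; it affects counts, not sums
        out.append((X.T @ X, X.T @ sa, X.T @ si, X.sum(axis=0),
                    sa.sum(), si.sum(), len(sa)))
    return out


class _RidgeSet:
    """Pooled ridge systems over a set of trials with cheap leave-one-out.

    Centering statistics and Gram matrices are accumulated once; holding
    out a trial subtracts its contribution (padding rows are zeros and
    contribute only to the sample count).
    """

    def __init__(self, designs, envs_att, envs_ign, pad):
        self.designs = designs
        self.envs = {"attended": envs_att, "ignored": envs_ign}
        self.pad = pad
        self.grams = _trial_grams(designs, envs_att, envs_ign, pad)
        p = designs[0].shape[1]
        self.G = np.zeros((p, p))
        self.b = {"attended": np.zeros(p), "ignored": np.zeros(p)}
        self.col = np.zeros(p)
        self.ssum = {"attended": 0.0, "ignored": 0.0}
        self.n = 0
        k = len(designs)
        for (G, ba, bi, cs, sa, si, nt) in self.grams:
            self.G += G
            self.b["attended"] += ba
            self.b["ignored"] += bi
            self.col += cs
            self.ssum["attended"] += sa
            self.ssum["ignored"] += si
            self.n += nt
        self.n += (k - 1) * pad  # padding rows between trials

    def solve(self, lam, exclude=()):
        """Centered ridge solutions for both roles, optionally holding out trials.

        Returns dict role -> (weights, column_mean, target_mean, m).
        """
        G = self.G.copy()
        b = {r: self.b[r].copy() for r in self.b}
        col = self.col.copy()
        ssum = dict(self.ssum)
        n = self.n
        for i in exclude:
            Gi, bai, bii, csi, sai, sii, nti = self.grams[i]
            G -= Gi
            b["attended"] -= bai
            b["ignored"] -= bii
            col -= csi
            ssum["attended"] -= sai
            ssum["ignored"] -= sii
            n -= nti + self.pad
        col_mean = col / n
        # center: Gc = G - n mu mu', bc = b - n mu sbar
        Gc = G - n * np.outer(col_mean, col_mean)
        m = np.trace(Gc) / Gc.shape[0]
        A = Gc + lam * m * np.eye(Gc.shape[0])
        fac = cho_factor(A)
        out = {}
        for role in ("attended", "ignored"):
            s_mean = ssum[role] / n
            bc = b[role] - n * col_mean * s_mean
            w = cho_solve(fac, bc)
            out[role] = (w, col_mean, s_mean, m)
        return out


def select_lambda(ridge_sets: list["_RidgeSet"], grid, window: int,
                  n_folds: int = 5) -> float:
    """Choose one global ridge parameter over the candidate grid.

    For every lambda, decoders are refit with each cross-validation fold of
    trials held out and the held-out envelopes reconstructed; the selected
    lambda maximizes the mean sliding-window correlation pooled over
    trials, roles and subjects, with mean squared error breaking ties.
    """
    grid = list(grid)
    if len(grid) == 1:
        return float(grid[0])
    scores = np.zeros(len(grid))
    mses = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    for rs in ridge_sets:
        k = len(rs.designs)
        folds = [list(range(k))[f::n_folds] for f in range(min(n_folds, k))]
        for fold in folds:
            if len(fold) == k:
                continue
            for gi, lam in enumerate(grid):
                sols = rs.solve(lam, exclude=fold)
                for i in fold:
                    X = rs.designs[i]
                    for role in ("attended", "ignored"):
                        w, cm, sm, _ = sols[role]
                        pred = (X - cm) @ w + sm
                        actual = rs.envs[role][i]
                        r = sliding_correlation(pred, actual, window)
                        if np.any(~np.isnan(r)):
                            scores[gi] += np.nanmean(r)
                            mses[gi] += np.mean((pred - actual) ** 2)
                            counts[gi] += 1
    with np.errstate(invalid="ignore"):
        mean_r = scores / counts
        mean_mse = mses / counts
    mean_r[~np.isfinite(mean_r)] = -np.inf
    best = np.max(mean_r)
    tied = np.flatnonzero(mean_r >= best - 1e-12)
    if len(tied) > 1:
        tied = tied[np.argsort(mean_mse[tied], kind="stable")]
    choice = float(grid[int(tied[0])])
    logger.info("selected lambda=%g (mean r=%.4f)", choice, best)
    return choice


def loo_reconstruct(dataset: Dataset, config: DecodingConfig | None = None,
                    lam: float | None = None,
                    subjects: list[str] | None = None) -> pd.DataFrame:
    """Leave-one-out tracking series for every trial of every subject.

    Returns the concatenated per-trial summary table (see
    :func:`decode_dataset` for the full result object).
    """
    return decode_dataset(dataset, config, lam=lam, subjects=subjects).table


@dataclass
class DecodingResult:
    table: pd.DataFrame
    warped_nti: np.ndarray
    per_subject: dict
    lam: float


def decode_dataset(dataset: Dataset, config: DecodingConfig | None = None,
                   lam: float | None = None,
                   subjects: list[str] | None = None) -> DecodingResult:
    """Train decoders, reconstruct every trial, and summarize tracking.

    Selective-attention trials are decoded leave-one-out within their
    attend side; divided-attention trials are decoded with the decoders of
    the side that was probed (probed-left trials use attend-left models,
    probed-right trials attend-right models).  If ``lam`` is None, one
    global ridge parameter is selected on the configured grid first.
    """
    config = config or DecodingConfig()
    lags = config.lags
    window = config.window_samples
    pad = int(round(config.pad_s * config.sample_rate))
    responses = _prepare_responses(dataset, config)
    trials = dataset.trials
    n_parcels = responses.shape[1]

    all_subjects = list(dict.fromkeys(trials["subject"]))
    if subjects is not None:
        all_subjects = [s for s in all_subjects if s in set(subjects)]

    # assemble per-subject, per-side ridge systems over selective trials
    subject_sets: dict[str, dict[str, _RidgeSet]] = {}
    subject_trials: dict[str, dict[str, list[int]]] = {}
    for subj in all_subjects:
        mask = (trials["subject"] == subj).to_numpy()
        sets, sel_idx = {}, {}
        for side in SIDES:
            sel = np.flatnonzero(
                mask
                & (trials["spatial_cue"] == "informative").to_numpy()
                & (trials["probed_ear"] == side).to_numpy())
            if len(sel) < 2:
                logger.warning(
                    "subject %s: only %d selective attend-%s trials; skipped",
                    subj, len(sel), side)
                continue
            designs, ea, ei = [], [], []
            for i in sel:
                row = trials.iloc[i]
                s0, s1 = int(row["sentence_start"]), int(row["sentence_end"])
                att = row["probed_ear"]
                ign = "left" if att == "right" else "right"
                X = build_lag_design(responses[i].T, lags)[s0:s1]
                designs.append(X)
                ea.append(dataset.envelopes[att][i, s0:s1])
                ei.append(dataset.envelopes[ign][i, s0:s1])
            sets[side] = _RidgeSet(designs, ea, ei, pad)
            sel_idx[side] = list(sel)
        subject_sets[subj] = sets
        subject_trials[subj] = sel_idx

    if lam is None:
        pooled = [s for subj in all_subjects for s in subject_sets[subj].values()]
        lam = select_lambda(pooled, config.lambda_grid, window,
                            n_folds=config.n_folds_lambda)

    rows = []
    warped = []
    per_subject = {}
    for subj in all_subjects:
        sets = subject_sets[subj]
        decoders = {}
        solutions_full = {}
        for side, rs in sets.items():
            sols = rs.solve(lam)
            solutions_full[side] = sols
            for role in ("attended", "ignored"):
                w, cm, sm, m = sols[role]
                decoders[(side, role)] = Decoder(
                    weights=w, lags=lags, n_parcels=n_parcels, lam=lam, m=m,
                    attend_side=side, role=role, column_mean=cm, target_mean=sm)
        mask = np.flatnonzero((trials["subject"] == subj).to_numpy())
        for i in mask:
            row = trials.iloc[i]
            side = row["probed_ear"]
            if side not in sets:
                continue
            rs = sets[side]
            selective = row["spatial_cue"] == "informative"
            s0, s1 = int(row["sentence_start"]), int(row["sentence_end"])
            att = side
            ign = "left" if att == "right" else "right"
            X = build_lag_design(responses[i].T, lags)[s0:s1]
            if selective:
                pos = subject_trials[subj][side].index(i)
                sols = rs.solve(lam, exclude=[pos])
            else:
                sols = solutions_full[side]
            series = {}
            for role, env_side in (("attended", att), ("ignored", ign)):
                w, cm, sm, _ = sols[role]
                pred = (X - cm) @ w + sm
                actual = dataset.envelopes[env_side][i, s0:s1]
                series[role] = sliding_correlation(pred, actual, window)
            if config.attended_only_index:
                # control variant: contrast one decoder's similarity to the
                # attended vs. the ignored envelope
                w, cm, sm, _ = sols["attended"]
                pred = (X - cm) @ w + sm
                r_att = sliding_correlation(pred, dataset.envelopes[att][i, s0:s1], window)
                r_ign = sliding_correlation(pred, dataset.envelopes[ign][i, s0:s1], window)
                nti = tracking_index(r_att, r_ign, config.denominator_tol)
            else:
                nti = tracking_index(series["attended"], series["ignored"],
                                     config.denominator_tol)
            wnti = warp_to_percent(nti, 0, len(nti))
            warped.append(wnti)
            rows.append({
                "subject": subj, "trial": int(row["trial"]),
                "r_att_mean": float(np.nanmean(series["attended"]))
                if np.any(~np.isnan(series["attended"])) else np.nan,
                "r_ign_mean": float(np.nanmean(series["ignored"]))
                if np.any(~np.isnan(series["ignored"])) else np.nan,
                "nti_sentence": float(np.nanmean(nti))
                if np.any(~np.isnan(nti)) else np.nan,
                "nti_final": final_word_mean(wnti),
            })
        per_subject[subj] = SubjectDecoding(
            table=None, warped_nti=None, decoders=decoders, lam=lam)
    table = pd.DataFrame(rows)
    return DecodingResult(table=table,
                          warped_nti=np.vstack(warped) if warped else np.empty((0, 100)),
                          per_subject=per_subject, lam=lam)


def validate_decoder_specificity(dataset: Dataset,
                                 result: DecodingResult,
                                 config: DecodingConfig | None = None,
                                 ) -> pd.DataFrame:
    """Per-subject similarity of each reconstruction to both envelopes.

    For every subject and decoder role, reports the mean correlation of the
    reconstructed envelope with the to-be-attended and to-be-ignored
    envelopes, plus their contrast.  A working attended decoder has a
    positive contrast (its output resembles the attended sentence more),
    and conversely for the ignored decoder.
    """
    config = config or DecodingConfig()
    lags = config.lags
    window = config.window_samples
    responses = _prepare_responses(dataset, config)
    trials = dataset.trials
    rows = []
    for subj, sd in result.per_subject.items():
        mask = np.flatnonzero(
            (trials["subject"] == subj).to_numpy()
            & (trials["spatial_cue"] == "informative").to_numpy())
        acc = {("attended", "att"): [], ("attended", "ign"): [],
               ("ignored", "att"): [], ("ignored", "ign"): []}
        for i in mask:
            row = trials.iloc[i]
            side = row["probed_ear"]
            if (side, "attended") not in sd.decoders:
                continue
            s0, s1 = int(row["sentence_start"]), int(row["sentence_end"])
            att = side
            ign = "left" if att == "right" else "right"
            X = build_lag_design(responses[i].T, lags)[s0:s1]
            envs = {"att": dataset.envelopes[att][i, s0:s1],
                    "ign": dataset.envelopes[ign][i, s0:s1]}
            for role in ("attended", "ignored"):
                pred = sd.decoders[(side, role)].predict(X)
                for key, env in envs.items():
                    r = sliding_correlation(pred, env, window)
                    if np.any(~np.isnan(r)):
                        acc[(role, key)].append(np.nanmean(r))
        for role in ("attended", "ignored"):
            r_att = float(np.mean(acc[(role, "att")])) if acc[(role, "att")] else np.nan
            r_ign = float(np.mean(acc[(role, "ign")])) if acc[(role, "ign")] else np.nan
            contrast = r_att - r_ign if role == "attended" else r_ign - r_att
            rows.append({"subject": subj, "role": role,
                         "r_with_attended": r_att, "r_with_ignored": r_ign,
                         "contrast": contrast})
    return pd.DataFrame(rows)
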
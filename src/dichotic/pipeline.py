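"""Stage-wise analysis pipeline over the dataset container.

Stages (each consumes the previous stage's on-disk artifacts and is
deterministic given identical inputs):

``simulate``   dataset.h5 + trials.csv
``features``   alpha_features.csv + warped ALI (features.h5)
``decode``     tracking.csv + warped tracking index (tracking.h5)
``warp``       group_timecourses.csv (grand-average warped series)
``crosscorr``  crosscorr.csv + crosscorr.json (peak lag, surrogate band)
``stats``      model_*.csv coefficient tables + error_breakdown.json
``report``     report.json summarizing the run

A single master seed is expanded into independent per-stage substreams so
rerunning one stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as dec
from . import features as feat
from . import stats as st
from . import temporal as tmp
from .config import PipelineConfig
from .io import read_dataset, validate_container, write_dataset
from .synthetic import generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "decode", "warp", "crosscorr", "stats", "report")

# fixed substream indices per stage
_STREAM = {"simulate": 0, "crosscorr": 1, "stats": 2}


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAM.get(stage, 9),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _require(path: Path, stage: str, producer: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing input {path.name}; "
            f"run the {producer!r} stage first")
    return path


def run_stage(stage: str, config: PipelineConfig, out_dir, seed: int | None = None):
    """Run one pipeline stage, writing its artifacts under ``out_dir``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or --seed)")
    t0 = time.time()
    result = _DISPATCH[stage](config, out, seed)
    logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    return result


def _simulate(config: PipelineConfig, out: Path, seed: int):
    sim = dataclasses.replace(config.simulation, seed=_stage_seed(seed, "simulate"))
    ds = generate_dataset(sim)
    write_dataset(ds, out / "dataset.h5", out / "trials.csv")
    config.to_yaml(out / "config_used.yaml")
    return ds


def _load(out: Path, stage: str):
    _require(out / "dataset.h5", stage, "simulate")
    _require(out / "trials.csv", stage, "simulate")
    problems = validate_container(out / "dataset.h5", out / "trials.csv")
    if problems:
        raise ValueError("invalid dataset container: " + "; ".join(problems))
    return read_dataset(out / "dataset.h5", out / "trials.csv")


def _features(config: PipelineConfig, out: Path, seed: int):
    ds = _load(out, "features")
    res = feat.ali_features(ds, config.features)
    res.table.to_csv(out / "alpha_features.csv", index=False)
    import h5py
    with h5py.File(out / "features.h5", "w") as f:
        f.create_dataset("warped_ali", data=res.warped, track_times=False)
    return res


def _decode(config: PipelineConfig, out: Path, seed: int):
    ds = _load(out, "decode")
    res = dec.decode_dataset(ds, config.decoding)
    res.table.to_csv(out / "tracking.csv", index=False)
    import h5py
    with h5py.File(out / "tracking.h5", "w") as f:
        f.create_dataset("warped_nti", data=res.warped_nti, track_times=False)
        f.attrs["lambda"] = res.lam
        for (side, role), d in next(iter(res.per_subject.values())).decoders.items():
            f.create_dataset(f"decoder_{side}_{role}/weights", data=d.weight_matrix,
                             track_times=False)
    return res


def _warp(config: PipelineConfig, out: Path, seed: int):
    ds = _load(out, "warp")
    import h5py
    _require(out / "features.h5", "warp", "features")
    _require(out / "tracking.h5", "warp", "decode")
    with h5py.File(out / "features.h5", "r") as f:
        warped_ali = f["warped_ali"][()]
    with h5py.File(out / "tracking.h5", "r") as f:
        warped_nti = f["warped_nti"][()]
    subj = ds.trials["subject"].to_numpy()
    sel = (ds.trials["spatial_cue"] == "informative").to_numpy()
    rows = {}
    for name, arr in (("ali", warped_ali), ("nti", warped_nti)):
        for cond, mask in (("selective", sel), ("divided", ~sel)):
            mean, sem = tmp.group_timecourse(arr, subj, mask)
            rows[f"{name}_{cond}_mean"] = mean
            rows[f"{name}_{cond}_sem"] = sem
    df = pd.DataFrame(rows)
    df.insert(0, "bin", np.arange(1, len(df) + 1))
    df.to_csv(out / "group_timecourses.csv", index=False)
    return df


def _joint_finite(x: np.ndarray, y: np.ndarray):
    """Trim both series to the range where both are observed.

    Interior missing values (rare, e.g. near-zero tracking denominators)
    are linearly interpolated; leading/trailing missing bins are dropped.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no jointly observed bins")
    first, last = np.flatnonzero(ok)[[0, -1]]
    xs, ys = x[first:last + 1].copy(), y[first:last + 1].copy()
    idx = np.arange(len(xs))
    for v in (xs, ys):
        bad = ~np.isfinite(v)
        if bad.any():
            v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return xs, ys, int(first)


def _crosscorr(config: PipelineConfig, out: Path, seed: int):
    path = _require(out / "group_timecourses.csv", "crosscorr", "warp")
    df = pd.read_csv(path)
    ds = _load(out, "crosscorr")
    x = df["nti_selective_mean"].to_numpy()   # neural tracking leads ...
    y = df["ali_selective_mean"].to_numpy()   # ... alpha lateralization?
    # sliding-window margins leave missing bins at the sentence edges: use
    # the jointly observed range, interpolating isolated interior gaps
    x, y, bin_offset = _joint_finite(x, y)
    tcfg = config.temporal
    cc = tmp.crosscorrelate(x, y, max_lag=tcfg.max_lag_bins)
    rng = np.random.default_rng(_stage_seed(seed, "crosscorr"))
    lo, hi = tmp.surrogate_band(x, y, max_lag=tcfg.max_lag_bins,
                                n_permutations=tcfg.n_permutations, rng=rng)
    lags = np.arange(-tcfg.max_lag_bins, tcfg.max_lag_bins + 1)
    result = tmp.CrossCorrelation(lags=lags, values=cc, lo=lo, hi=hi)
    pd.DataFrame({"lag_bins": lags, "cc": cc, "lo": lo, "hi": hi}).to_csv(
        out / "crosscorr.csv", index=False)
    mean_dur = float(np.mean(
        (ds.trials["sentence_end"] - ds.trials["sentence_start"])
        / ds.config.sample_rate * 1000.0))
    summary = {
        "peak_lag_bins": result.peak_lag,
        "peak_value": result.peak_value,
        "peak_lag_ms": tmp.lag_to_ms(result.peak_lag, mean_dur),
        "mean_sentence_duration_ms": mean_dur,
        "outside_band": bool(result.peak_value > hi[int(np.argmax(cc))]),
    }
    (out / "crosscorr.json").write_text(json.dumps(summary, indent=2))
    return result


def _merge_tables(ds, out: Path, stage: str) -> pd.DataFrame:
    alpha = pd.read_csv(_require(out / "alpha_features.csv", stage, "features"))
    track = pd.read_csv(_require(out / "tracking.csv", stage, "decode"))
    t = ds.trials.merge(alpha, on=["subject", "trial"]).merge(
        track, on=["subject", "trial"])
    for measure in ("nti_final", "nti_sentence", "ali_final", "ali_sentence"):
        w, b = st.decompose_within_between(
            t[measure].fillna(t[measure].mean()).to_numpy(),
            t["subject"].to_numpy())
        pre = measure.split("_")[0]
        t[f"{pre}_within"], t[f"{pre}_between"] = w, b
    return t


def _stats(config: PipelineConfig, out: Path, seed: int):
    ds = _load(out, "stats")
    t = _merge_tables(ds, out, "stats")
    t = t.rename(columns={"spatial_code": "spatial_cue_c",
                          "semantic_code": "semantic_cue_c"})
    # deviation-coded columns under the names the default formulas use
    t["spatial_cue"] = t["spatial_cue_c"]
    t["semantic_cue"] = t["semantic_cue_c"]
    t["probed_ear"] = t["ear_code"]
    t["probed_first"] = t["probed_first_code"]
    acc, speed = st.preprocess_behaviour(t)
    if not speed.empty:
        v = speed["speed"].to_numpy()
        speed["speed_z"] = (v - v.mean()) / v.std(ddof=1)
    jobs = []
    for name, spec in config.stats.formulas.items():
        data = speed if spec.get("data") == "speed" else acc
        jobs.append({"name": name, "data": data, "formula": spec["formula"],
                     "family": spec["family"]})
    fits = st.fit_mixed_models(jobs, q=config.stats.q)
    for name, fit in fits.items():
        fit.table.to_csv(out / f"model_{name}.csv", index=False)
    breakdown = st.error_breakdown(t)
    (out / "error_breakdown.json").write_text(json.dumps(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in breakdown.items()}, indent=2))
    return fits


def _report(config: PipelineConfig, out: Path, seed: int):
    report = {}
    t = pd.read_csv(_require(out / "trials.csv", "report", "simulate"))
    valid = t[t["accuracy"] != "timeout"]
    report["behaviour"] = {
        "n_trials": int(len(t)),
        "mean_accuracy_pct": float(100 * valid["correct"].mean()),
        "mean_rt_ms": float(1000 * valid.loc[valid["correct"], "rt"].mean()),
        "mean_speed": float((1 / valid.loc[valid["correct"], "rt"]).mean()),
    }
    cc_path = out / "crosscorr.json"
    if cc_path.exists():
        report["crosscorr"] = json.loads(cc_path.read_text())
    for model in sorted(out.glob("model_*.csv")):
        tab = pd.read_csv(model)
        report[model.stem] = tab.to_dict(orient="records")
    eb = out / "error_breakdown.json"
    if eb.exists():
        b = json.loads(eb.read_text())
        report["error_breakdown"] = {"t": b["t"], "p": b["p"], "df": b["df"]}
    track = out / "tracking.csv"
    if track.exists():
        tr = pd.read_csv(track)
        report["tracking"] = {
            "mean_nti_final": float(tr["nti_final"].mean()),
            "mean_r_attended": float(tr["r_att_mean"].mean()),
            "mean_r_ignored": float(tr["r_ign_mean"].mean()),
        }
    alpha = out / "alpha_features.csv"
    if alpha.exists():
        al = pd.read_csv(alpha)
        report["alpha"] = {"mean_ali_sentence": float(al["ali_sentence"].mean()),
                           "mean_ali_final": float(al["ali_final"].mean())}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


_DISPATCH = {
    "simulate": _simulate,
    "features": _features,
    "decode": _decode,
    "warp": _warp,
    "crosscorr": _crosscorr,
    "stats": _stats,
    "report": _report,
}


def run_all(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run every stage in order; returns the final report dict."""
    for stage in STAGES:
        result = run_stage(stage, config, out_dir, seed=seed)
    return result
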
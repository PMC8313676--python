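"""HDF5 + CSV dataset container.

A simulated dataset is stored as one HDF5 file (epochs, envelopes, truth
arrays, configuration echo) plus one CSV trial table.  Dataset creation
disables HDF5 object timestamps so identical runs produce byte-identical
files.

Layout of ``dataset.h5``::

    /epochs                (n_trials, n_parcels, n_epoch_samples)  @ epoch_rate
    /envelopes/left        (n_trials, n_env_samples)               @ sample_rate
    /envelopes/right       idem
    /truth/<column>        per-trial ground-truth arrays
    attrs: schema_version, epoch_rate, sample_rate, epoch_start,
           epoch_end, parcel_hemi, config_yaml, n_trials
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, SimulationConfig
from .synthetic import Dataset

SCHEMA_VERSION = 1

__all__ = ["write_dataset", "read_dataset", "validate_container"]


def _create(group, name, data):
    return group.create_dataset(name, data=data, track_times=False)


def write_dataset(dataset: Dataset, h5_path, csv_path) -> None:
    """Write a dataset to its HDF5 + CSV container."""
    h5_path, csv_path = Path(h5_path), Path(csv_path)
    cfg_yaml = yaml.safe_dump(
        PipelineConfig(simulation=dataset.config).to_dict()["simulation"],
        sort_keys=True)
    with h5py.File(h5_path, "w", track_order=False) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["epoch_rate"] = dataset.config.epoch_rate
        f.attrs["sample_rate"] = dataset.config.sample_rate
        f.attrs["epoch_start"] = dataset.config.epoch_start
        f.attrs["epoch_end"] = dataset.config.epoch_end
        f.attrs["n_trials"] = len(dataset.trials)
        f.attrs["parcel_hemi"] = [h.encode() for h in dataset.parcel_hemi]
        f.attrs["config_yaml"] = cfg_yaml
        _create(f, "epochs", dataset.epochs)
        env = f.create_group("envelopes")
        for side, arr in dataset.envelopes.items():
            _create(env, side, arr)
        tr = f.create_group("truth")
        for col in dataset.truth.columns:
            vals = dataset.truth[col].to_numpy()
            if vals.dtype == object:
                vals = np.array([str(v).encode() for v in vals])
            _create(tr, col, vals)
    dataset.trials.to_csv(csv_path, index=False)


def read_dataset(h5_path, csv_path) -> Dataset:
    """Load a dataset container written by :func:`write_dataset`."""
    h5_path, csv_path = Path(h5_path), Path(csv_path)
    trials = pd.read_csv(csv_path)
    with h5py.File(h5_path, "r") as f:
        config = SimulationConfig(**_config_kwargs(f.attrs["config_yaml"]))
        epochs = f["epochs"][()]
        envelopes = {side: f["envelopes"][side][()] for side in f["envelopes"]}
        truth = pd.DataFrame({
            col: _decode(f["truth"][col][()]) for col in f["truth"]
        })
        hemi = np.array([h.decode() if isinstance(h, bytes) else str(h)
                         for h in f.attrs["parcel_hemi"]])
        fs_ep = float(f.attrs["epoch_rate"])
        fs_env = float(f.attrs["sample_rate"])
        t0 = float(f.attrs["epoch_start"])
    n_ep = epochs.shape[-1]
    n_env = next(iter(envelopes.values())).shape[-1]
    return Dataset(config=config, trials=trials, envelopes=envelopes,
                   epochs=epochs, truth=truth, parcel_hemi=hemi,
                   epoch_times=np.arange(n_ep) / fs_ep + t0,
                   env_times=np.arange(n_env) / fs_env + t0)


def _config_kwargs(cfg_yaml: str) -> dict:
    d = yaml.safe_load(cfg_yaml)
    if "trf_kernel" in d:
        d["trf_kernel"] = tuple(tuple(p) for p in d["trf_kernel"])
    for key in ("sentence_window", "duration_range_ms", "word_gap_range_ms"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return d


def _decode(vals: np.ndarray):
    if vals.dtype.kind == "S" or vals.dtype == object:
        return np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
    return vals


def validate_container(h5_path, csv_path,
                       required_decoding_rate: float = 125.0) -> list[str]:
    """Consistency diagnostics for a dataset container.

    Returns a list of problems (empty = valid): schema version, trial-count
    agreement between the HDF5 arrays and the CSV table, and the envelope
    sample-rate requirement of the decoding stage.
    """
    problems = []
    h5_path, csv_path = Path(h5_path), Path(csv_path)
    if not h5_path.exists():
        return [f"missing HDF5 container {h5_path} (produced by the simulate stage)"]
    if not csv_path.exists():
        return [f"missing trial table {csv_path} (produced by the simulate stage)"]
    trials = pd.read_csv(csv_path)
    with h5py.File(h5_path, "r") as f:
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            problems.append(
                f"schema version {f.attrs.get('schema_version')} != {SCHEMA_VERSION}")
        n_h5 = int(f.attrs.get("n_trials", -1))
        if n_h5 != len(trials):
            problems.append(
                f"trial-count mismatch: HDF5 holds {n_h5} trials, "
                f"CSV table {len(trials)} rows")
        if f["epochs"].shape[0] != len(trials):
            problems.append(
                f"epoch array has {f['epochs'].shape[0]} trials, "
                f"CSV table {len(trials)} rows")
        fs = float(f.attrs.get("sample_rate", 0.0))
        if not np.isclose(fs, required_decoding_rate):
            problems.append(
                f"envelope sample rate {fs:g} Hz != {required_decoding_rate:g} Hz "
                "required by the decoding stage")
    return problems
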
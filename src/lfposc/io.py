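"""Reading and writing cohorts, spectrograms, maps, tables and configs.

HDF5 layout for cohorts: one dataset per ``/<group>/<mouse>/<session>``
path with attributes ``fs``, ``units`` and (when generated) ``seed``.
Spectrograms and inference maps each live in their own HDF5 file with
grids, matrices and parameters as attributes.  Band tables and region
summaries are CSV; probability densities and manifests are JSON; cohort
configs round-trip through YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import Signal
from .inference import InferenceMap
from .multitaper import MultitaperParams, Spectrogram
from .synthgen import (
    AperiodicSpec,
    CohortConfig,
    CohortDataset,
    EffectSchedule,
    LineNoiseSpec,
    OscComponent,
    SharedEnvelopeSpec,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_signal_csv",
    "write_signal_csv",
    "write_spectrogram",
    "read_spectrogram",
    "write_inference_map",
    "read_inference_map",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
]


# ---------------------------------------------------------------- cohorts

def write_cohort(dataset: CohortDataset, path) -> None:
    """Write a cohort to HDF5 plus its ground-truth table as CSV.

    ``path`` is the HDF5 file; the truth table goes to the same stem
    with suffix ``_truth.csv``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = dataset.config.fs
        for (group, mouse, session), sig in dataset.signals.items():
            ds = f.create_dataset(f"{group}/{mouse:04d}/{session}", data=sig.samples)
            ds.attrs["fs"] = sig.fs
            ds.attrs["units"] = "a.u."
            if "seed" in sig.meta:
                ds.attrs["seed"] = sig.meta["seed"]
    if dataset.truth is not None and len(dataset.truth):
        dataset.truth.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)


def read_cohort(path) -> dict:
    """Read an HDF5 cohort into ``{(group, mouse, session): Signal}``."""
    signals = {}
    with h5py.File(path, "r") as f:
        for group in f:
            for mouse in f[group]:
                for session in f[group][mouse]:
                    ds = f[group][mouse][session]
                    sig = Signal(
                        ds[()], float(ds.attrs["fs"]),
                        meta={"group": group, "mouse": int(mouse), "session": session},
                    )
                    if "seed" in ds.attrs:
                        sig.meta["seed"] = int(ds.attrs["seed"])
                    signals[(group, int(mouse), session)] = sig
    return signals


def write_signal_csv(signal: Signal, path) -> None:
    """Write one signal as CSV with columns time_s, voltage."""
    t = signal.t0 + np.arange(signal.n_samples) / signal.fs
    pd.DataFrame({"time_s": t, "voltage": signal.samples}).to_csv(path, index=False)


def read_signal_csv(path, fs: float | None = None) -> Signal:
    """Read a (time_s, voltage) CSV; fs inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    if not {"time_s", "voltage"}.issubset(df.columns):
        raise ValueError("signal CSV needs columns time_s and voltage")
    t = df["time_s"].to_numpy()
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        fs = 1.0 / dt[0]
    return Signal(df["voltage"].to_numpy(), float(fs), t0=float(t[0]) if t.size else 0.0)


# ----------------------------------------------------------- spectrograms

def write_spectrogram(spec: Spectrogram, path, include_stack: bool = True) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=spec.times)
        f.create_dataset("freqs", data=spec.freqs)
        f.create_dataset("mean_power", data=spec.mean_power)
        if include_stack:
            f.create_dataset("stack", data=spec.stack, compression="gzip", compression_opts=4)
        f.attrs["n_epochs"] = spec.n_epochs
        for k, v in dataclasses.asdict(spec.params).items():
            if v is not None:
                f.attrs[f"param_{k}"] = v


def read_spectrogram(path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        if "stack" not in f:
            raise ValueError(f"{path}: no estimate stack stored; cannot rebuild spectrogram")
        params = MultitaperParams(
            T=float(f.attrs["param_T"]),
            W=float(f.attrs["param_W"]),
            K=int(f.attrs["param_K"]) if "param_K" in f.attrs else None,
            dt=float(f.attrs["param_dt"]),
            fmin=float(f.attrs["param_fmin"]),
            fmax=float(f.attrs["param_fmax"]),
        )
        return Spectrogram(
            times=f["times"][()],
            freqs=f["freqs"][()],
            stack=f["stack"][()],
            params=params,
            n_epochs=int(f.attrs["n_epochs"]),
        )


def write_inference_map(imap: InferenceMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=imap.times)
        f.create_dataset("freqs", data=imap.freqs)
        f.create_dataset("types", data=imap.types)
        f.attrs["alpha"] = imap.alpha
        f.attrs["dof"] = imap.dof


def read_inference_map(path) -> InferenceMap:
    with h5py.File(path, "r") as f:
        return InferenceMap(
            times=f["times"][()], freqs=f["freqs"][()], types=f["types"][()],
            alpha=float(f.attrs["alpha"]), dof=int(f.attrs["dof"]),
        )


# ----------------------------------------------------------------- config

def config_to_dict(config: CohortConfig) -> dict:
    """Serialize a CohortConfig to a plain, YAML/JSON-safe mapping."""
    d = {
        "n_mice_per_group": config.n_mice_per_group,
        "group_labels": list(config.group_labels),
        "session_labels": list(config.session_labels),
        "fs": config.fs,
        "duration": config.duration,
        "base_seed": config.base_seed,
        "aperiodic": dataclasses.asdict(config.aperiodic),
        "line_noise": dataclasses.asdict(config.line_noise),
        "components": [dataclasses.asdict(c) for c in config.components],
        "effects": [
            {"group": g, "session": s, "band": b, "multiplier": m}
            for (g, s, b), m in sorted(config.effects.multipliers.items())
        ],
    }
    if config.envelope is not None:
        d["envelope"] = dataclasses.asdict(config.envelope)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    effects = EffectSchedule(
        {(e["group"], e["session"], e["band"]): float(e["multiplier"]) for e in d.get("effects", [])}
    )
    return CohortConfig(
        n_mice_per_group=int(d.get("n_mice_per_group", 10)),
        group_labels=tuple(d.get("group_labels", ("vehicle", "treated"))),
        session_labels=tuple(d.get("session_labels", ("PRE", "D-1", "D-3", "D-12"))),
        fs=float(d.get("fs", 5000.0)),
        duration=float(d.get("duration", 300.0)),
        aperiodic=AperiodicSpec(**d.get("aperiodic", {})),
        components=tuple(OscComponent(**c) for c in d.get("components", [])),
        line_noise=LineNoiseSpec(**d.get("line_noise", {})),
        effects=effects,
        envelope=SharedEnvelopeSpec(**d["envelope"]) if "envelope" in d else None,
        base_seed=int(d.get("base_seed", 0)),
    )


def save_config(config: CohortConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> CohortConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(d)
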
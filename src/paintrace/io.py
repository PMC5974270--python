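"""Session container I/O (HDF5) and configuration files (YAML/JSON).

Layout: one file per session with groups ``/trials/<id>/{lfp, spikes/<unit>,
denoised}``, per-trial attributes for intensity, condition and withdrawal
latency, root attributes for fs / t_range / class pair / seed, and the full
generator config embedded as a JSON attribute so a session is reproducible
from its own file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synth import Session, StimulusIntensity, SynthConfig, Trial

__all__ = ["write_session", "read_session", "load_config", "dump_config"]


def _config_to_json(config: SynthConfig) -> str:
    d = dataclasses.asdict(config)
    d["t_range"] = list(d["t_range"])
    d["latency_params"] = {k: list(v) for k, v in d["latency_params"].items()}
    return json.dumps(d, sort_keys=True)


def _config_from_json(s: str) -> SynthConfig:
    d = json.loads(s)
    d["t_range"] = tuple(d["t_range"])
    d["latency_params"] = {k: tuple(v) for k, v in d["latency_params"].items()}
    return SynthConfig(**d)


def write_session(session: Session, path) -> Path:
    """Write a session to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = session.config.fs
        f.attrs["t_range"] = list(session.config.t_range)
        f.attrs["class_pair"] = "-".join(i.label for i in session.class_pair)
        f.attrs["condition"] = session.condition
        f.attrs["seed"] = session.seed
        f.attrs["config_json"] = _config_to_json(session.config)
        trials = f.create_group("trials")
        for t in session.trials:
            g = trials.create_group(str(t.trial_id))
            g.attrs["intensity"] = t.intensity.label
            g.attrs["condition"] = t.condition
            g.attrs["withdrawal_latency"] = np.nan if t.withdrawal_latency is None else t.withdrawal_latency
            g.create_dataset("lfp", data=t.lfp)
            sp = g.create_group("spikes")
            for u, st in enumerate(t.spikes):
                sp.create_dataset(str(u), data=np.asarray(st, dtype=float))
            if t.denoised is not None:
                g.create_dataset("denoised", data=t.denoised)
    return path


def read_session(path) -> Session:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        config = _config_from_json(f.attrs["config_json"])
        pair = tuple(StimulusIntensity.parse(p) for p in f.attrs["class_pair"].split("-"))
        trials = []
        ids = sorted(f["trials"], key=int)
        for tid in ids:
            g = f["trials"][tid]
            lat = float(g.attrs["withdrawal_latency"])
            sp_group = g["spikes"]
            spikes = [sp_group[str(u)][()] for u in sorted(map(int, sp_group))]
            trials.append(
                Trial(
                    trial_id=int(tid),
                    intensity=StimulusIntensity.parse(g.attrs["intensity"]),
                    condition=str(g.attrs["condition"]),
                    lfp=g["lfp"][()],
                    spikes=spikes,
                    withdrawal_latency=None if np.isnan(lat) else lat,
                    denoised=g["denoised"][()] if "denoised" in g else None,
                )
            )
        return Session(
            trials=trials,
            class_pair=pair,
            condition=str(f.attrs["condition"]),
            config=config,
            seed=int(f.attrs["seed"]),
        )


def load_config(path) -> SynthConfig:
    """Load a generator config from a YAML (or JSON) file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "t_range" in d:
        d["t_range"] = tuple(d["t_range"])
    if "latency_params" in d:
        d["latency_params"] = {k: tuple(v) for k, v in d["latency_params"].items()}
    return SynthConfig(**d)


def dump_config(config: SynthConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(_config_to_json(config)), fh, sort_keys=True)
    return path
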
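"""Delimited-text and config file handling.

Trial tables are plain CSV with a mandatory header; responses are encoded
"with"/"against". Traces are two- or three-column CSV (time, value
[, confidence]) with a JSON sidecar declaring the sample rate and channel.
Every simulation output gets a sidecar recording the config hash and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .kinematics import Channel, Trace
from .synthetic_data import ObserverParams

TRIAL_COLUMNS = [
    "participant_id", "modality", "audio_jitter", "visual_jitter",
    "gain", "response", "head_velocity", "sweep_index",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    df["audio_jitter"] = df["audio_jitter"].astype(bool)
    df["visual_jitter"] = df["visual_jitter"].astype(bool)
    bad = set(df["response"].unique()) - {"with", "against"}
    if bad:
        raise ValidationError(f"unrecognized response codes: {bad}")
    return df


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    cols = {"time": trace.time, "value": trace.value}
    if trace.confidence is not None:
        cols["confidence"] = trace.confidence
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {"rate": trace.rate, "channel": trace.channel.value}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"trace sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    conf = df["confidence"].to_numpy() if "confidence" in df.columns else None
    return Trace(df["time"].to_numpy(), df["value"].to_numpy(),
                 float(meta["rate"]), Channel(meta["channel"]), conf)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "observer" not in cfg:
        raise ValidationError("config must be a mapping with an 'observer' block")
    return cfg


def observer_from_config(cfg: Mapping) -> ObserverParams:
    return ObserverParams(**cfg["observer"])


def config_gains(cfg: Mapping) -> np.ndarray:
    from .synthetic_data import canonical_gain_grid

    gains = cfg.get("gains", "canonical")
    if isinstance(gains, str) and gains == "canonical":
        return canonical_gain_grid()
    return np.asarray([float(g) for g in gains])


def write_sidecar(path: str | Path, config: Mapping, seed: int) -> None:
    from .evaluation import config_hash

    Path(path).write_text(json.dumps(
        {"config_hash": config_hash(config), "seed": seed}, indent=2))
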
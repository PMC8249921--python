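"""YAML/JSON configuration for the simulators and analyses.

A config file is a plain mapping with optional blocks ``eeg`` (per-rhythm
neural-mass parameters, intention schedule, RP), ``nmj`` (per-ion branches,
capacitance, temperature, stimulus), ``muscle``/``firing``/``electrode``
(EMG generation) and ``wavelet`` (coherence). Anything omitted falls back
to the package defaults, so ``{}`` is a valid config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from . import coherence, emg, nmj, nmm

__all__ = [
    "load_config",
    "default_config",
    "nmm_models_from_config",
    "schedule_from_config",
    "rp_from_config",
    "membrane_from_config",
    "muscle_from_config",
    "firing_from_config",
    "electrode_from_config",
    "wavelet_from_config",
]


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _build(cls, block: dict | None, **extra):
    """Instantiate a dataclass from a config block, ignoring unknown keys."""
    block = dict(block or {})
    block.update(extra)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def nmm_models_from_config(cfg: dict) -> dict[str, nmm.NMMParams]:
    eeg = cfg.get("eeg", {})
    defaults = {"L": nmm.NMMParams.low(), "M": nmm.NMMParams.medium(),
                "H": nmm.NMMParams.high()}
    conn = dict(nmm.CONNECTIVITY)
    conn.update(eeg.get("connectivity", {}))
    models = {}
    for name, default in defaults.items():
        block = dict(eeg.get("models", {}).get(name, {}))
        base = dataclasses.asdict(default)
        base.update(block)
        base["C"] = conn
        models[name] = _build(nmm.NMMParams, base)
    return models


def schedule_from_config(cfg: dict) -> nmm.IntentionSchedule:
    block = dict(cfg.get("eeg", {}).get("schedule", {}))
    block.setdefault("total_duration", 10.0)
    block.setdefault("task_window", [5.0, 8.0])
    block["task_window"] = tuple(block["task_window"])
    for key in ("rest_input", "task_input"):
        if block.get(key) is not None:
            block[key] = tuple(block[key])
    return _build(nmm.IntentionSchedule, block)


def rp_from_config(cfg: dict) -> nmm.RPConfig:
    return _build(nmm.RPConfig, cfg.get("eeg", {}).get("rp"))


def membrane_from_config(cfg: dict) -> nmj.MembraneModel:
    block = cfg.get("nmj", {})
    if "ions" not in block:
        model = nmj.default_membrane()
        if "capacitance" in block:
            model.capacitance = float(block["capacitance"])
        if "temperature" in block:
            model.temperature = float(block["temperature"])
        return model
    branches = [
        _build(nmj.IonBranch, dict(spec_, species=species))
        for species, spec_ in block["ions"].items()
    ]
    return nmj.MembraneModel(
        branches=branches,
        capacitance=float(block.get("capacitance", 1.0)),
        temperature=float(block.get("temperature", 310.0)),
    )


def muscle_from_config(cfg: dict) -> emg.MuscleModel:
    return _build(emg.MuscleModel, cfg.get("muscle"))


def firing_from_config(cfg: dict) -> emg.FiringModel:
    block = dict(cfg.get("firing", {}))
    if "burst_window" in block:
        block["burst_window"] = tuple(block["burst_window"])
    return _build(emg.FiringModel, block)


def electrode_from_config(cfg: dict) -> emg.ElectrodePoint:
    return _build(emg.ElectrodePoint, cfg.get("electrode"))


def wavelet_from_config(cfg: dict) -> coherence.WaveletParams:
    return _build(coherence.WaveletParams, cfg.get("wavelet"))


def default_config() -> dict:
    """Full default configuration as a plain serializable mapping."""
    models = {name: dataclasses.asdict(m) for name, m in
              nmm_models_from_config({}).items()}
    for m in models.values():
        m.pop("C")
    return {
        "eeg": {
            "models": models,
            "connectivity": dict(nmm.CONNECTIVITY),
            "schedule": {"total_duration": 10.0, "task_window": [5.0, 8.0],
                         "task_gain": 2.0},
            "rp": dataclasses.asdict(nmm.RPConfig()),
            "fs": 1000.0,
        },
        "nmj": {
            "ions": {
                b.species: {"conc_out": b.conc_out, "conc_in": b.conc_in,
                            "conductance": b.conductance,
                            "permeability": b.permeability}
                for b in nmj.default_membrane().branches
            },
            "capacitance": 1.0,
            "temperature": 310.0,
            "stimulus": {"onset": 0.005, "duration": 0.004, "peak": 30.0},
            "fs": 10000.0,
        },
        "muscle": dataclasses.asdict(emg.MuscleModel()),
        "firing": {k: v for k, v in dataclasses.asdict(emg.FiringModel()).items()},
        "electrode": dataclasses.asdict(emg.ElectrodePoint()),
        "wavelet": dataclasses.asdict(coherence.WaveletParams()),
    }
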
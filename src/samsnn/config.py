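"""Experiment configuration, seed fan-out, and JSON-lines metrics.

Configurations are plain YAML with five optional blocks -- ``neuron``,
``network``, ``task``, ``training``, ``seeds`` -- plus ``out_dir``.  Values
merge over the documented defaults (the reference neuron parameter set);
unknown keys and type mismatches are rejected with the offending key named.

One global seed fans out to named sub-seeds (topology, data, policy, env, ...)
through :func:`derive_seed`, so components can be re-seeded independently and
a saved config reproduces an experiment exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, IO, Iterable, Optional

import numpy as np
import yaml

from .learning import TrainConfig
from .neuron import SAMParams

__all__ = [
    "NetworkConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "derive_seed",
    "write_metrics",
    "write_metrics_record",
]


@dataclass
class NetworkConfig:
    n_in: int = 80
    n_hidden: int = 220
    n_out: int = 5
    connectivity: float = 0.12
    frac_inhibitory: float = 0.2
    input_to_soma: bool = False


@dataclass
class ExperimentConfig:
    neuron: SAMParams = field(default_factory=SAMParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    task: Dict[str, Any] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=lambda: {"global": 0})
    out_dir: str = "."

    def seed_for(self, name: str) -> int:
        """Named sub-seed: explicit entry in the seeds block, else derived."""
        if name in self.seeds:
            return int(self.seeds[name])
        return derive_seed(int(self.seeds.get("global", 0)), name)


def derive_seed(global_seed: int, name: str) -> int:
    """Deterministic named sub-seed below 2**31.

    The derivation mixes the global seed with the CRC-32 of the component
    name through numpy's SeedSequence, so sub-streams are independent and
    stable across runs and platforms.
    """
    ss = np.random.SeedSequence(entropy=int(global_seed),
                                spawn_key=(zlib.crc32(name.encode()) & 0x7FFFFFFF,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _merge_dataclass(cls, defaults, data: Dict[str, Any], block: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {f: getattr(defaults, f) for f in valid}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown key {block}.{key}")
        expected = valid[key].type
        if isinstance(value, bool) and expected in ("int", "float"):
            raise ValueError(f"type mismatch for {block}.{key}: got bool")
        if expected == "float" and not isinstance(value, (int, float)):
            raise ValueError(f"type mismatch for {block}.{key}: expected number, got {type(value).__name__}")
        if expected == "int" and not isinstance(value, int):
            raise ValueError(f"type mismatch for {block}.{key}: expected int, got {type(value).__name__}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid value in block '{block}': {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Load a YAML experiment configuration, merged over the defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"neuron", "network", "training", "task", "seeds", "out_dir"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown key {key}")
    defaults = ExperimentConfig()
    cfg = ExperimentConfig(
        neuron=_merge_dataclass(SAMParams, defaults.neuron, raw.get("neuron") or {}, "neuron"),
        network=_merge_dataclass(NetworkConfig, defaults.network, raw.get("network") or {}, "network"),
        training=_merge_dataclass(TrainConfig, defaults.training, raw.get("training") or {}, "training"),
        task=dict(raw.get("task") or {}),
        seeds={k: int(v) for k, v in (raw.get("seeds") or {"global": 0}).items()},
        out_dir=str(raw.get("out_dir", ".")),
    )
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    data = {
        "neuron": dataclasses.asdict(cfg.neuron),
        "network": dataclasses.asdict(cfg.network),
        "training": dataclasses.asdict(cfg.training),
        "task": cfg.task,
        "seeds": cfg.seeds,
        "out_dir": cfg.out_dir,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_metrics_record(fh: IO[str], record: Dict[str, Any]) -> None:
    """Append one flat scalar record as a JSON line and flush immediately."""
    fh.write(json.dumps({k: _jsonable(v) for k, v in record.items()}) + "\n")
    fh.flush()


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def write_metrics(records: Iterable[Dict[str, Any]], path) -> None:
    """Stream records to a JSON-lines file, one per line, flushed per record."""
    with open(path, "w") as fh:
        for record in records:
            write_metrics_record(fh, record)
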
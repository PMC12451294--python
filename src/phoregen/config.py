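"""Layered run configuration and run manifests.

Precedence: built-in defaults < YAML config file < explicit CLI overrides.
Unknown keys are rejected so typos fail loudly, and every run dumps the
effective configuration (plus its hash, the seed and package version) into
a manifest JSON next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

DEFAULTS: dict[str, dict[str, Any]] = {
    "fixtures": {
        "n_sites": 6,
        "jitter_sd": 0.2,
        "n_train": 2000,
        "n_actives": 20,
        "n_decoys": 180,
        "conformers_per_molecule": 3,
        "n_shell": 48,
    },
    "train": {
        "epochs": 80,
        "batch_size": 24,
        "lr": 1e-4,
        "T": 1000,
        "schedule_power": 2.0,
        "grad_clip": 1.0,
        "k": 8,
        "protein_cutoff": 4.5,
        "n_layers": 4,
        "hidden": 64,
        "n_vec": 16,
        "n_rbf": 16,
    },
    "generate": {
        "T": 1000,
        "schedule_power": 2.0,
        "init_spread": 2.0,
        "k": 8,
        "protein_cutoff": 4.5,
        "rewire": True,
        "pocket_radius": 8.0,
        "sizes": "3-8",
        "reps": 5,
    },
    "screen": {"rmsd_tol": 1.0},
    "eval": {"max_hits_fraction": 0.01},
}


class ConfigError(ValueError):
    pass


def load_config(
    command: str,
    yaml_path: Optional[str] = None,
    overrides: Optional[dict[str, Any]] = None,
) -> dict[str, Any]:
    """Resolve the effective config for one command."""
    if command not in DEFAULTS:
        raise ConfigError(f"unknown command {command!r}")
    cfg = dict(DEFAULTS[command])
    layers = []
    if yaml_path:
        with open(yaml_path) as fh:
            raw = yaml.safe_load(fh) or {}
        layers.append(raw.get(command, raw))
    if overrides:
        layers.append({k: v for k, v in overrides.items() if v is not None})
    for layer in layers:
        for key, value in layer.items():
            if key not in cfg:
                raise ConfigError(f"unknown config key {key!r} for command {command!r}")
            cfg[key] = value
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir: Path, command: str, cfg: dict[str, Any], seed: int) -> Path:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def seed_substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible substream derived from one integer seed."""
    digest = hashlib.sha256(name.encode()).digest()
    salt = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))
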
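"""Experiment configuration: YAML loading, defaults, manifests.

An experiment config bundles the metabolic rule, food preset, drive weights,
reward constants, arena geometry, policy choice, session counts and the base
seed.  Every run writes a manifest (config snapshot, seed, package version,
config hash) next to its artifacts so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .arena import ArenaConfig
from .metabolism import MetabolicRule
from .ngf import DEFAULT_BETA_GRID
from .reward import DriveWeights, RewardConfig

__all__ = ["ExperimentConfig", "load_config", "write_manifest"]


@dataclass
class ExperimentConfig:
    rule: MetabolicRule = MetabolicRule.CD
    beta: Optional[float] = None  # None -> training foods
    drive_weights: DriveWeights = field(default_factory=DriveWeights)
    reward: RewardConfig = field(default_factory=RewardConfig)
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    policy: str = "oracle"  # oracle | train | load:PATH
    n_sessions: int = 20
    n_steps: int = 8_000
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID
    base_seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rule"] = self.rule.value
        return d


def load_config(path: Optional[str | Path]) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file (or defaults if None)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = ExperimentConfig()
    if "rule" in raw:
        cfg.rule = MetabolicRule(str(raw["rule"]).lower())
    if "beta" in raw:
        cfg.beta = raw["beta"]
    if "drive_weights" in raw:
        cfg.drive_weights = DriveWeights(**raw["drive_weights"])
    if "reward" in raw:
        cfg.reward = RewardConfig(**raw["reward"])
    if "arena" in raw:
        cfg.arena = ArenaConfig(**raw["arena"])
    for key in ("policy", "n_sessions", "n_steps", "base_seed", "out_dir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "beta_grid" in raw:
        cfg.beta_grid = tuple(float(b) for b in raw["beta_grid"])
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: ExperimentConfig, out_dir: str | Path, seed: int) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": seed,
        "package_version": __version__,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
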
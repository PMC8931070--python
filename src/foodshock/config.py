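"""Run configuration and the reproducibility manifest.

A :class:`RunConfig` collects every tunable of the pipeline; it can be read
from a YAML key-value file (unknown keys are rejected) and is hashed into
every output manifest together with the network hash and the seed, so any
output file can be traced back to the exact inputs that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    shock_fraction: float = 0.3
    alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    tolerance_rel: float = 1e-6  # cascade tolerance relative to the shock
    max_steps: int = 10_000
    percentile: float = 95.0
    thresholds: tuple[float, ...] = (250.0, 500.0)  # kcal/person/day
    pop_min: float = 1e6
    seed: int = 0
    days_per_year: int = 365
    n_countries: int = 172
    shock_transform: str = "log"  # "log" or "level" shock covariate

    def __post_init__(self) -> None:
        if not 0 < self.shock_fraction <= 1:
            raise ValueError("shock_fraction must be in (0, 1]")
        if any(not 0 <= a <= 1 for a in self.alphas):
            raise ValueError("alphas must lie in [0, 1]")
        if self.shock_transform not in ("log", "level"):
            raise ValueError("shock_transform must be 'log' or 'level'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("alphas", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kwargs) -> "RunConfig":
        d = asdict(self)
        d.update(kwargs)
        for key in ("alphas", "thresholds"):
            d[key] = tuple(d[key])
        return RunConfig(**d)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def package_version() -> str:
    try:
        return version("foodshock")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def write_manifest(
    out_dir, config: RunConfig, network_hash: str, extra: dict | None = None
) -> Path:
    """Write manifest.json binding outputs to inputs; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "foodshock",
        "version": package_version(),
        "network_hash": network_hash,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "config": json.loads(
            json.dumps(asdict(config), sort_keys=True, default=list)
        ),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
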
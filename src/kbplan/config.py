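"""Run configuration: three-layer precedence (CLI flags > config file >
defaults), a stable digest for provenance, and the run manifest.

The config file is TOML.  Every artifact a CLI run writes is accompanied by a
manifest JSON embedding the digest of the effective configuration, the seeds,
and the package version, so that reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "config_digest", "write_manifest"]

DEFAULT_PRESCRIPTIONS = {"pgtv": 70.0, "ptv1": 60.0, "ptv2": 54.0}


@dataclass
class RunConfig:
    prescriptions_gy: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESCRIPTIONS)
    )
    score_table: str = "default"  # or a path to a table JSON
    dvh_bin_gy: float = 0.1
    dth_bin_mm: float = 1.0
    dth_signed: bool = True
    svr_c: float = 10.0
    svr_epsilon: float = 0.01
    svr_kernel: str = "rbf"
    variance_target: float = 0.97  # DTH embedding selection rule
    max_components: int = 4
    seed: int = 0
    strategy_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.prescriptions_gy.values()):
            raise ValueError("prescriptions must be positive")
        if self.dvh_bin_gy <= 0 or self.dth_bin_mm <= 0:
            raise ValueError("bin widths must be positive")


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, optionally a TOML file, then keyword
    overrides (the CLI flag layer).  Overrides with value None are ignored."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data.update(tomllib.load(fh))
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def config_digest(config: RunConfig) -> str:
    """Stable short digest of the effective configuration."""
    canon = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir, command: str, outputs: list[str]) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "config": asdict(config),
        "config_digest": config_digest(config),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    path = Path(out_dir) / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
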
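"""Pipeline configuration: one YAML-serializable record of every knob.

Defaults follow the analysis constants: 500 Hz sampling, 4-s epochs,
VAR order 10 (fixed), conditional GC estimated epoch-by-epoch, alpha 0.05,
strict 0.95 consistency cut, IQR winsorizing factor 1.5.  Unknown YAML
keys are errors; the seed must be set in the config or on the command
line.  A stable hash of the effective config is embedded in every output
artifact so results are traceable to their settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    srate: float = 500.0
    epoch_duration: float = 4.0
    order: int = 10
    order_criterion: str = "fixed"     # fixed | BIC | AIC | HQC
    max_order: int = 10
    conditioning: str = "full"         # full | bivariate
    estimation: str = "per_epoch"      # per_epoch | pooled
    combine: str = "fisher"            # fisher | proportion
    alpha: float = 0.05
    robust_cut: float = 0.95
    fdr_scope: str = "subject"         # subject | none
    winsorize_k: float = 1.5
    adf_regression: str = "constant"   # constant | none | trend
    adf_lag_policy: str | int = "aic"
    max_diff: int = 2
    montage_path: str | None = None
    out_dir: str = "cueconn_out"
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {self.schema_version}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.robust_cut <= 1:
            raise ValueError("robust_cut must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        if "seed" not in raw:
            raise ValueError("seed is mandatory (config file or --seed flag)")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
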
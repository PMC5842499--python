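"""Run configuration and reproducibility manifests.

Every stochastic component of the pipeline carries an explicit seed in the
configuration, and each pipeline output directory receives a JSON manifest
(config hash, seeds, stage record counts) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Serialisable settings for the full pipeline."""

    window_s: float = 3.0
    wavelet_bins: int = 25
    wavelet_f_lo: float = 0.2
    wavelet_f_hi: float = 10.0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    learner_seed: int = 0
    macro_f_floor: float = 0.0
    best_weight: float = 3.0
    filter_min_run_s: int = 2
    tide_lag_h: float = 1.0
    df_hour: int = 8
    gvif_threshold: float = 3.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def write_manifest(out_dir, config: RunConfig, stages: dict) -> Path:
    """Write the reproducibility manifest for a pipeline run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": stages,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
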
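"""Pipeline configuration: one YAML file driving every stage.

Unknown keys are rejected so typos fail loudly, and the fully-resolved
config is echoed into every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import TrainConfig
from .simulate import SimulationConfig
from .subpathways import SAConfig


@dataclass
class PipelineConfig:
    omics_paths: dict[str, str] = field(default_factory=dict)
    labels_path: str = ""
    pathways_path: str = ""
    output_dir: str = "pathdrp_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    aggregation: str = "mean"
    pool_stride: int = 1
    n_folds: int = 5
    seed: int = 0
    screen_mode: str = "per-fold"

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        self.sa.validate()
        self.train.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, val in raw.items():
            if key in ("simulation", "sa", "train") and isinstance(val, dict):
                sub_cls = {"simulation": SimulationConfig, "sa": SAConfig,
                           "train": TrainConfig}[key]
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(val) - sub_known
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in val.items()
                }
                kwargs[key] = sub_cls(**coerced)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("simulation", "sa", "train"):
            d[key] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d[key].items()
            }
        return d

    def echo(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = outdir / "config_resolved.yaml"
        p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return p
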
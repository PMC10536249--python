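"""Run configuration shared by the pipeline, CLI and evaluation harness."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .gcn import TrainConfig
from .kernels import GipConfig
from .semantics import SemanticConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a full run needs: inputs, per-stage tunables, output dir."""

    assoc_path: str = ""
    hierarchy_path: str = ""
    out_dir: str = "midra_out"
    semantic: SemanticConfig = field(default_factory=SemanticConfig)
    gip: GipConfig = field(default_factory=GipConfig)
    snf_k: int = 10
    snf_t: int = 20
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"]["layer_sizes"] = list(self.train.layer_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sem = d.pop("semantic", {})
        gip = d.pop("gip", {})
        tr = dict(d.pop("train", {}))
        if "layer_sizes" in tr:
            tr["layer_sizes"] = tuple(tr["layer_sizes"])
        return cls(
            semantic=SemanticConfig(**sem),
            gip=GipConfig(**gip),
            train=TrainConfig(**tr),
            **d,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
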
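"""Run-configuration schema shared by the command-line entry points.

JSON configs are validated with pydantic before any work starts; unknown keys
are rejected and every run writes its resolved configuration next to its
outputs for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DatagenBlock(_Block):
    n: int = Field(default=20_000, ge=1)
    n_synthetic_nnaa: int = Field(default=200, ge=1)
    nnaa_library: str | None = None
    length_range: tuple[int, int] = (6, 18)
    topology_quota: dict[str, float] = Field(
        default_factory=lambda: {
            "linear": 0.40,
            "head_to_tail": 0.20,
            "sidechain_to_tail": 0.20,
            "disulfide": 0.20,
        }
    )
    nnaa_fraction_range: tuple[float, float] = (0.0, 0.3)
    stereo_fraction_range: tuple[float, float] = (0.0, 0.25)
    nmethyl_fraction_range: tuple[float, float] = (0.0, 0.25)
    pairs_per_peptide: int = Field(default=1, ge=1)

    @field_validator("topology_quota")
    @classmethod
    def _quota_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"topology quotas must sum to 1, got {sum(v.values())}")
        return v


class ModelBlock(_Block):
    embed_dim: int = 64
    enc_hidden: int = 64
    dec_hidden: int = 128
    max_len: int = 500


class TrainBlock(_Block):
    pairs: str
    validation_pairs: str | None = None
    epochs: int = Field(default=20, ge=1)
    batch_size: int = Field(default=16, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0)
    warmup_steps: int | None = None
    model: ModelBlock = Field(default_factory=ModelBlock)


class SampleBlock(_Block):
    checkpoint: str
    source: str | None = None
    source_file: str | None = None
    n: int = Field(default=100, ge=1)
    method: Literal["multinomial", "beam"] = "multinomial"
    max_len: int = 300


class EvaluateBlock(_Block):
    samples: str
    sources: str
    n_synthetic_nnaa: int = 200
    nnaa_library: str | None = None


class ScoringComponentBlock(_Block):
    name: Literal["largest_ring", "custom_alerts", "solubility", "permeability"]
    weight: float = Field(default=1.0, ge=0)
    shape: Literal["sigmoid", "reverse_sigmoid", "double_sigmoid", "none"] = "none"
    low: float = 0.0
    high: float = 1.0
    k: float | None = None
    patterns: list[str] | None = None


class RLBlock(_Block):
    checkpoint: str
    scenario: Literal["topology", "mpo", "custom"] = "custom"
    objective: Literal["maximize", "macrocycle_window", "minimize"] = "maximize"
    source: str | None = None
    components: list[ScoringComponentBlock] = Field(default_factory=list)
    aggregation: Literal["geometric_mean", "weighted_average"] = "geometric_mean"
    n_steps: int = Field(default=100, ge=1)
    batch_size: int = Field(default=32, ge=1)
    sigma: float = Field(default=120.0, gt=0)
    learning_rate: float = Field(default=1e-4, gt=0)
    diversity_threshold: float = 0.4
    diversity_bucket_size: int = 25


class RunConfig(_Block):
    run_type: Literal["datagen", "train", "sample", "evaluate", "rl"]
    seed: int = 0
    output_dir: str = "pepfill_run"
    datagen: DatagenBlock | None = None
    train: TrainBlock | None = None
    sample: SampleBlock | None = None
    evaluate: EvaluateBlock | None = None
    rl: RLBlock | None = None

    def block(self):
        blk = getattr(self, self.run_type)
        if blk is None:
            raise ValueError(f"config is missing its {self.run_type!r} block")
        if self.run_type == "rl" and blk.scenario == "custom" and not blk.components:
            raise ValueError("custom rl run needs at least one scoring component")
        return blk


def validate_config(payload: dict | str | Path) -> RunConfig:
    """Parse and validate a JSON config (dict, JSON text, or file path)."""
    if isinstance(payload, (str, Path)) and Path(payload).exists():
        payload = json.loads(Path(payload).read_text())
    elif isinstance(payload, str):
        payload = json.loads(payload)
    config = RunConfig.model_validate(payload)
    config.block()  # force presence of the type-specific block
    return config


def write_resolved(config: RunConfig, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "resolved_config.json").write_text(
        config.model_dump_json(indent=2)
    )
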
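"""Schema-validated run configuration (YAML) and run reports (JSON).

Unknown keys are rejected before any computation starts, so a typo in a
config file fails fast instead of silently using a default.
"""

from __future__ import annotations

import json
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "RunReport"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    anchor: Literal["segment_midpoint", "face_center"] = "segment_midpoint"
    nose_point: int = 29


class HogSection(_Strict):
    gamma: float = 2.2
    gamma_mode: Literal["compressive", "expansive"] = "compressive"
    cell_px: int = 6
    n_bins: int = 8
    bin_width_deg: float = 45.0
    block_cells: int = 2
    block_stride_cells: int = 1


class WeightSection(_Strict):
    value: float = 4.0
    grid: int = 6
    membership: Literal["intersect", "center"] = "intersect"


class TrainSection(_Strict):
    model_kind: Literal["bp", "adaboost", "extratree", "rf", "xgboost", "knn"] = "bp"
    hidden_units: int = 64
    activation: str = "logistic"
    learning_rate: float = 0.01
    rounds: int = 50
    batch: int = 32
    n_folds: int = 5
    features: Literal["ocular", "face_minus_eyes", "weighted", "unweighted", "full"] = "weighted"
    pca_variance: float = 0.95


class EvalSection(_Strict):
    bootstrap_B: int = 1000
    ci_level: float = 0.95


class SimulateSection(_Strict):
    n: int = 200
    effect_size: float = 0.3
    noise_sd: float = 0.05
    target_r: float = 0.8
    image_side: int = 320


class RunConfig(_Strict):
    seed: int = 0
    workspace: str = "workspace"
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    hog: HogSection = Field(default_factory=HogSection)
    weight: WeightSection = Field(default_factory=WeightSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


class RunReport(dict):
    """JSON-serializable run record: config snapshot, seeds, metrics.

    Deterministic given the same config and seed (no timestamps by
    default), so repeated runs produce byte-identical files.
    """

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=2, sort_keys=True)
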
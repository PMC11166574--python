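"""Schema-validated configuration for the pipeline stages.

Every tunable of the pipeline lives here with its default; unknown keys
are rejected.  Config files are YAML with blocks mirroring the stages
(``simulate``, ``kernels``, ``fit``, ``dynamics``, ``pathways``) plus a
single top-level ``seed`` from which all stage randomness derives.
"""

from __future__ import annotations

from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    circuit: str = "toggle"            # "toggle" | "emt"
    n_cells: int = 2000
    dt: float = 0.01
    burn_in_steps: int = 500
    record_every: int = 50
    signal_levels: List[float] = [0.0, 1.0, 1.8, 2.5, 4.0]


class KernelsConfig(_Strict):
    w1: float = 0.5
    w2: float = 0.3
    n_neighbors: int = 30
    n_pcs: int = 30
    n_neighbors_spatial: int = 8

    @model_validator(mode="after")
    def _weights(self):
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 > 1:
            raise ValueError(
                f"kernel weights must satisfy w1,w2 >= 0 and w1+w2 <= 1; "
                f"got w1={self.w1}, w2={self.w2}"
            )
        return self


class FitConfig(_Strict):
    k: Optional[int] = None
    lam: float = 0.01
    score_threshold: float = 0.5
    max_iter: int = 20
    tolerance: float = 1e-3
    train_fraction: float = 0.8
    min_genes: int = 3
    refilter_every_round: bool = True


class DynamicsConfig(_Strict):
    grid_size: int = 200
    membership_cutoff: float = 0.2
    streamline_mode: str = "nonlinear"


class PathwaysConfig(_Strict):
    min_overlap: int = 3
    max_k: int = 10


class Config(_Strict):
    seed: int = 42
    simulate: SimulateConfig = SimulateConfig()
    kernels: KernelsConfig = KernelsConfig()
    fit: FitConfig = FitConfig()
    dynamics: DynamicsConfig = DynamicsConfig()
    pathways: PathwaysConfig = PathwaysConfig()

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
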
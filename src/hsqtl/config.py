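"""Run configuration: schema-validated YAML/JSON with explicit seeds.

Unknown keys are rejected everywhere (typos fail loudly), and every
stochastic stage draws its seed deterministically from the single master
``seed`` so a config file fully determines a run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QTLSpec(_Strict):
    marker_index: int = Field(ge=0)
    # explicit per-founder additive effects, or "snp" to use the founder
    # allele pattern at the marker (a fully SNP-taggable QTL)
    effects: list[float] | Literal["snp"] = "snp"
    fraction: float = Field(ge=0.0, lt=1.0, default=0.2)


class SimulateBlock(_Strict):
    n_animals: int = Field(ge=2)
    chromosomes: list[tuple[str, float, int]]
    n_founders: int = Field(ge=2, default=8)
    n_generations: float = Field(ge=0.0, default=70.0)
    genotyping_error: float = Field(ge=0.0, le=1.0, default=0.01)
    missing_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    h2: float = Field(ge=0.0, lt=1.0, default=0.4)
    qtl: QTLSpec | None = None
    expression_scenario: str | None = None


class InputsBlock(_Strict):
    panel: Path
    genotypes: Path
    phenotypes: Path
    trait: str
    expression: Path | None = None
    annotations: Path | None = None


class HMMBlock(_Strict):
    generations: float = Field(ge=0.0, default=70.0)
    epsilon: float = Field(ge=0.0, le=0.5, default=0.01)


class ScanBlock(_Strict):
    B: int = Field(ge=50, default=1000)
    alpha: float = Field(gt=0.0, le=1.0, default=0.05)
    r2_min: float = Field(ge=0.0, le=1.0, default=0.5)
    grid_size: int = Field(ge=5, default=41)


class H2Block(_Strict):
    n_iter: int = Field(ge=100, default=10_000)
    burn_in: int = Field(ge=0, default=1_000)


class EffectsBlock(_Strict):
    n_importance: int = Field(ge=10, default=200)
    n_iter: int = Field(ge=100, default=1000)
    burn_in: int = Field(ge=0, default=200)


class MediationBlock(_Strict):
    fdr: float = Field(gt=0.0, le=1.0, default=0.1)
    full_mediation_alpha: float = Field(gt=0.0, lt=1.0, default=0.05)


class RunConfig(_Strict):
    out_dir: Path
    seed: int
    simulate: SimulateBlock | None = None
    inputs: InputsBlock | None = None
    hmm: HMMBlock = HMMBlock()
    scan: ScanBlock = ScanBlock()
    h2: H2Block = H2Block()
    effects: EffectsBlock = EffectsBlock()
    mediation: MediationBlock = MediationBlock()

    @model_validator(mode="after")
    def _one_data_source(self) -> "RunConfig":
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")
        return self

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        order = ["simulate", "impute", "phenotype", "h2", "scan",
                 "threshold", "effects", "mediate", "expression"]
        if stage not in order:
            raise KeyError(f"unknown stage {stage!r}")
        import numpy as np

        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0])


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(raw)
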
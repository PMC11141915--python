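"""Run configuration: scenario parameters and calling thresholds.

Defaults encode the pipeline's published operating points: somatic VAF
call threshold 0.15, WGD fraction 0.5, arm-call fraction 0.5, purity
exclusion 0.3, BH alpha 0.05 and copy-number fold-change 2.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .ascn import DEFAULT_CRITICAL_COARSE, DEFAULT_CRITICAL_FINE
from .genome import CLASSIC_MONOSOMY_CHROMS

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    # scenario
    seed: int = 0
    purity: float = Field(0.7, gt=0.0, le=1.0)
    coverage: float = Field(100.0, gt=0.0)
    classic_rate: float = Field(28.0, ge=0.0)
    dediff_extra_rate: float = Field(12.0, ge=0.0)
    synonymous_fraction: float = Field(0.5, ge=0.0)
    monosomies: tuple[str, ...] = CLASSIC_MONOSOMY_CHROMS
    with_metastasis: bool = False
    error_rate: float = Field(0.0, ge=0.0, lt=0.5)
    snp_sites_per_chrom: int = Field(500, gt=1)
    # thresholds
    vaf_threshold: float = Field(0.15, ge=0.0, le=1.0)
    wgd_fraction: float = Field(0.5, ge=0.0, le=1.0)
    arm_fraction: float = Field(0.5, ge=0.0, le=1.0)
    purity_exclude: float = Field(0.3, ge=0.0, le=1.0)
    bh_alpha: float = Field(0.05, gt=0.0, le=1.0)
    cn_fc: float = Field(2.0, ge=1.0)
    critical_coarse: float = Field(DEFAULT_CRITICAL_COARSE, gt=0.0)
    critical_fine: float = Field(DEFAULT_CRITICAL_FINE, gt=0.0)
    cn_max: int = Field(8, ge=2)

    @field_validator("monosomies", mode="before")
    @classmethod
    def _coerce_monosomies(cls, v):
        return tuple(str(x) for x in v)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.model_dump()
        data["monosomies"] = list(data["monosomies"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
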
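"""Run configuration.

All cutoffs applied anywhere in the pipeline live here so a run is fully
described by (inputs, config, seed).  Defaults follow the analysis protocol:
qPCR censoring at Ct 35, differential expression at |fold regulation| >= 2
with p < 0.05, pathway-analysis input at |FR| >= 1.5 with p <= 0.05, protein
grading bands at 150%/200% of the solvent control, transcript grading at
p <= 0.0005 / 0.005 / 0.05, and viability acceptance above 80%.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, field_validator


class RunConfig(BaseModel):
    ct_cutoff: float = 35.0
    fc_threshold: float = 2.0
    alpha: float = 0.05
    fr_cutoff: float = 1.5
    ipa_p_grades: Tuple[float, float, float] = (0.0005, 0.005, 0.05)
    protein_grade_bounds: Tuple[float, float] = (150.0, 200.0)
    viability_threshold: float = 80.0
    qc_tolerance_fold: float = 3.0
    n_boot: int = 10_000
    rng_seed: int = 0
    #: how a category's p-value is collapsed from its annotations; "min_p"
    #: keeps the most significant annotation, "max_p" the literal largest.
    collapse_rule: Literal["min_p", "max_p"] = "min_p"
    #: score in vivo effects that no in vitro endpoint can express as
    #: automatic misses instead of excluding them from the denominator.
    include_unmapped_effects: bool = False
    bootstrap_method: Literal["studentized", "percentile"] = "studentized"

    @field_validator(
        "ct_cutoff", "fc_threshold", "alpha", "fr_cutoff", "viability_threshold",
        "qc_tolerance_fold"
    )
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v

    @field_validator("ipa_p_grades", "protein_grade_bounds")
    @classmethod
    def _strictly_increasing(cls, v, info):
        if any(x <= 0 for x in v):
            raise ValueError(f"{info.field_name} entries must be strictly positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"{info.field_name} must be strictly increasing, got {v}")
        return v

    @field_validator("n_boot")
    @classmethod
    def _boot_count(cls, v):
        if v < 1:
            raise ValueError("n_boot must be at least 1")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls(**(data or {}))
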
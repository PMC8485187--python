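"""Engine configuration.

The defaults reproduce the deployed screening tool's behaviour: the
band cutoffs, the max-band severity-combination policy, the baseline
reference for the week-2 alert comparison, last-assessment worsening, and
the Wald CI for the number needed to screen.  All of these are policy
knobs for sensitivity analyses; changing them never requires a code edit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .bands import BandCutoffs

__all__ = ["EngineConfig"]


class EngineConfig(BaseModel):
    phq9_cutoffs: tuple[int, int, int, int] = (4, 9, 19, 27)
    gad7_cutoffs: tuple[int, int, int, int] = (4, 9, 14, 21)
    severity_policy: str = "max"  # or "phq_priority"
    worsened_at_any_point: bool = False
    ci_method: str = "wald"  # or "wilson"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    cohort_pct_decimals: int = 2
    table_pct_decimals: int = 1
    log_level: str = "INFO"

    @property
    def phq9_band_cutoffs(self) -> BandCutoffs:
        return BandCutoffs(self.phq9_cutoffs)

    @property
    def gad7_band_cutoffs(self) -> BandCutoffs:
        return BandCutoffs(self.gad7_cutoffs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable digest embedded in output files for provenance."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
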
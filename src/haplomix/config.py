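"""Run configuration with validated thresholds.

All analysis thresholds live here with their conventional defaults, are
validated on construction, and are echoed into output manifests so every
result file records the settings that produced it.  Unknown keys are
rejected.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """Configuration for an end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    haps_path: str | None = None
    sample_path: str | None = None
    vcf_path: str | None = None
    map_paths: list[str] = Field(default_factory=list)
    label_table: str | None = None
    out_dir: str = "results"
    seed: int = 0

    # painting
    ne: float = Field(190.82, gt=0)
    theta: float = Field(0.00045, gt=0, lt=0.5)
    n_painting_samples: int = Field(10, ge=2)
    n_em: int = Field(10, ge=1)

    # weighted LD / curve fitting
    min_d_cm: float | None = None  # None = data-driven shared-LD threshold
    min_d_override_cm: float = 0.5
    max_d_cm: float = Field(30.0, gt=0)
    ld_bin_cm: float = Field(0.05, gt=0)

    # coancestry curves
    curve_bin_cm: float = Field(0.1, gt=0)
    curve_max_g_cm: float = Field(50.0, gt=0)
    curve_min_g_cm: float = Field(1.0, ge=0)
    n_boot: int = Field(100, ge=1)
    n_iter: int = Field(5, ge=1)

    # thresholds
    beta_min: float = Field(0.001, ge=0)
    m_threshold: float = Field(0.35, gt=0)
    z_threshold: float = Field(2.0, gt=0)
    f3_z_threshold: float = Field(-5.0, lt=0)
    pihat_threshold: float = Field(0.2, gt=0)
    r2_threshold: float = Field(0.2, gt=0)
    p_threshold: float = Field(0.05, gt=0, lt=1)

    generation_years: float = Field(29.0, gt=0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a configuration file (YAML mapping; unknown keys rejected)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def provenance(self) -> dict:
        """Threshold/provenance block embedded in every output manifest."""
        return self.model_dump()
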
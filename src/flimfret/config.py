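"""Validated run configuration for the end-to-end pipeline.

The schema is strict: unknown keys are rejected before any computation, and
requesting significance calls without a control group is a validation error,
not a runtime failure.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "SceneConfig", "PopulationConfig", "FitConfig",
           "load_config"]


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    amplitudes: list[float]
    lifetimes_ns: list[float]
    n_cells: int = Field(ge=1)
    photons_per_cell: float = Field(gt=0)


class SceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    populations: list[PopulationConfig]
    shape: tuple[int, int] = (256, 256)
    semi_axis_range_px: tuple[float, float] = (10.0, 18.0)
    background_rate: float = 0.0
    n_bins: int = 256
    rep_period_ns: float = 50.0


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_components: int = Field(default=3, ge=1, le=4)
    irf_fwhm_ns: float = 0.150
    delta_chi2: float = 0.05
    min_amplitude: float = 0.01
    min_lifetime_ratio: float = 1.5
    min_roi_counts: int = 1000


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int
    output_dir: str
    scene: SceneConfig | None = None
    flim_path: str | None = None
    fit: FitConfig = Field(default_factory=FitConfig)
    donor_band_nm: tuple[float, float] = (500.0, 550.0)
    acceptor_band_nm: tuple[float, float] = (580.0, 630.0)
    control_label: str | None = None      # population/ROI group used for Eq. 5
    call_significance: bool = True
    r0_A: float | None = None             # attach distances when given
    min_cell_area_px: int = 200

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.scene is None and self.flim_path is None:
            raise ValueError("config needs either a scene to simulate or a flim_path")
        if self.call_significance and self.control_label is None:
            raise ValueError("significance calls requested but no control group "
                             "defined (set control_label or call_significance: false)")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)
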
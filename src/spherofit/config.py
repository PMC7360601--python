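"""Validated run configuration (YAML file → typed settings).

A single YAML document configures an end-to-end run.  Validation aggregates
every problem found (pydantic) rather than stopping at the first, and an
empty file yields the full default synthetic configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class PhantomSettings(BaseModel):
    field_size_um: tuple[float, float] = (500.0, 500.0)
    pixel_size_um: float = Field(5.0, gt=0)
    core_radius_um: float = Field(100.0, gt=0)
    plateau_density: float = Field(1.0, gt=0, le=1.0)
    falloff_width_um: float = Field(20.0, gt=0)
    bead_count: int = Field(300, gt=0)
    bead_sigma_px: float = Field(1.0, gt=0)
    cell_sigma_px: float = Field(1.0, ge=0)
    noise_sigma: float = Field(0.0, ge=0)
    shot_noise: bool = False
    mesh_target_edge_um: float = Field(45.0, gt=0)
    t_start_h: float = 24.0
    interval_h: float = Field(12.0, gt=0)

    @model_validator(mode="after")
    def _core_fits(self):
        if self.core_radius_um >= min(self.field_size_um) / 2:
            raise ValueError("core_radius_um must be below half the field size")
        return self


class SolverSettings(BaseModel):
    dt: float = Field(0.125, gt=0)
    interval_hours: float = Field(12.0, gt=0)
    mechanics_update_every: int = Field(1, ge=1)
    cfl_safety: float = Field(0.9, gt=0, le=1.0)
    theta: float = Field(1.0, gt=0)
    youngs_ecm_pa: float = Field(2000.0, gt=0)
    core_stiffening: float = Field(10.0, ge=1.0)
    poissons_ratio: float = Field(0.45, gt=0, lt=0.5)

    @model_validator(mode="after")
    def _dt_divides(self):
        n = self.interval_hours / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"dt ({self.dt}) must divide interval_hours ({self.interval_hours})"
            )
        return self


class FitSettings(BaseModel):
    init_d0: float = 200.0
    init_k: float = 5e-3
    init_lambda: float = 0.0
    gamma: float = Field(2.5e-3, ge=0)
    d0_bounds: tuple[float, float] = (0.0, 1e4)
    k_bounds: tuple[float, float] = (-1.0, 1.0)
    outer_tol: float = Field(1e-2, gt=0)
    outer_max: int = Field(10, ge=1)

    @field_validator("d0_bounds", "k_bounds")
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError(f"bounds must be increasing, got {v}")
        return v

    @model_validator(mode="after")
    def _d0_nonnegative(self):
        if self.d0_bounds[0] < 0:
            raise ValueError("lower D0 bound must be non-negative")
        return self


class RunConfig(BaseModel):
    mode: Literal["synthetic", "raw_acquisition", "prerendered_fields"] = "synthetic"
    input_dir: Path | None = None
    outdir: Path = Path("spherofit_run")
    seed: int = 0
    log_level: str = "INFO"
    n_systems_per_group: int = Field(3, ge=1)
    n_intervals: int = Field(6, ge=1)
    groups: tuple[str, ...] = ("untreated", "treated")
    core_threshold: float = Field(0.5, gt=0, lt=1)
    emit_tiles: bool = False
    phantom: PhantomSettings = PhantomSettings()
    solver: SolverSettings = SolverSettings()
    fit: FitSettings = FitSettings()

    @model_validator(mode="after")
    def _input_required(self):
        if self.mode != "synthetic" and self.input_dir is None:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        return self


def validate_config(path_or_dict=None, **overrides) -> RunConfig:
    """Load and validate a YAML config file (or dict).

    Missing fields take defaults; an empty file is the default synthetic
    configuration.  All validation errors are aggregated in the raised
    ``pydantic.ValidationError`` with paths into the config tree.
    """
    if path_or_dict is None:
        data = {}
    elif isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        data = yaml.safe_load(text) or {}
    data.update(overrides)
    return RunConfig.model_validate(data)
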
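"""Validated run configuration.

One flat YAML block drives every pipeline command; unknown keys are
rejected, defaults are filled explicitly, and the effective configuration is
echoed into run logs so any result is reproducible from (config, seed).
The defaults mirror the full-scale experiment this package models (200
photons/frame, 80% background, reciprocal voxel a*/7 with an a*/9 fine
stage, 30 iterations); presets scale the grid and frame count down for
desk-size runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import DetectorGeometry, ReciprocalGrid, RotationSet
from .lattice import UnitCell

__all__ = ["GeometryConfig", "RunConfig"]


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_fast: int = Field(gt=0)
    n_slow: int = Field(gt=0)
    pixel_pitch_mm: float = Field(gt=0)
    distance_mm: float = Field(gt=0)
    wavelength_A: float = Field(gt=0)
    beam_center_fast: float
    beam_center_slow: float
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def detector(self) -> DetectorGeometry:
        return DetectorGeometry(
            n_fast=self.n_fast, n_slow=self.n_slow,
            pixel_pitch=self.pixel_pitch_mm, distance=self.distance_mm,
            wavelength=self.wavelength_A,
            beam_center=(self.beam_center_fast, self.beam_center_slow),
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig
    cell_a_A: float = Field(gt=0)
    cell_c_A: float = Field(gt=0)
    n_rotations: int = Field(default=1080, ge=1)
    grid_divisor: int = Field(default=7, ge=2)
    grid_extent: int = Field(default=543, ge=3)
    fine_grid_divisor: int | None = Field(default=None, ge=2)
    fine_grid_extent: int | None = Field(default=None, ge=3)
    n_iter: int = Field(default=30, ge=0)
    tol: float = Field(default=0.0, ge=0)
    gamma_schedule: list[float] = [1.0, 1.7, 2.3, 3.0]
    window: int = Field(default=15, ge=3)
    window_fractions: list[float] = [0.10, 0.25, 0.50]
    refine_steps: int = Field(default=11, ge=1)
    refine_span: float = Field(default=0.02, gt=0)
    refine_fraction: float = Field(default=0.01, gt=0, le=1)
    master_seed: int = 0
    n_frames: int = Field(default=0, ge=0)
    mean_photons: float = Field(default=200.0, ge=0)
    background_fraction: float = Field(default=0.8, ge=0, le=1)
    peak_sigma_astar: float = Field(default=0.13, gt=0)
    b_factor_A2: float = Field(default=25.0, ge=0)
    angle_mode: str = "discrete"
    space_group_rules: bool = True
    friedel: bool = True

    @field_validator("grid_extent", "fine_grid_extent", "window")
    @classmethod
    def _odd(cls, v):
        if v is not None and v % 2 == 0:
            raise ValueError("must be odd")
        return v

    @field_validator("gamma_schedule")
    @classmethod
    def _nondecreasing(cls, v):
        if len(v) < 1 or np.any(np.diff(v) < 0):
            raise ValueError("gamma schedule must be non-empty and non-decreasing")
        return v

    @field_validator("angle_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("discrete", "cycle", "continuous"):
            raise ValueError("angle_mode must be discrete, cycle or continuous")
        return v

    # ---- constructors for the domain objects -------------------------------

    def cell(self) -> UnitCell:
        return UnitCell(self.cell_a_A, self.cell_c_A)

    def detector(self) -> DetectorGeometry:
        return self.geometry.detector()

    def rotations(self) -> RotationSet:
        return RotationSet.uniform(self.n_rotations, axis=np.asarray(self.geometry.axis))

    def grid(self) -> ReciprocalGrid:
        return ReciprocalGrid.from_cell(self.cell().a_star, self.grid_divisor, self.grid_extent)

    def fine_grid(self) -> ReciprocalGrid | None:
        if self.fine_grid_divisor is None or self.fine_grid_extent is None:
            return None
        return ReciprocalGrid.from_cell(self.cell().a_star, self.fine_grid_divisor,
                                        self.fine_grid_extent)

    def peak_sigma_q(self) -> float:
        return self.peak_sigma_astar * self.cell().a_star

    # ---- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.effective(), sort_keys=True))

    def effective(self) -> dict:
        """Fully defaulted configuration dict (echoed into run logs)."""
        return self.model_dump(mode="json")

    # ---- presets -----------------------------------------------------------

    @classmethod
    def orientation_benchmark(cls, **overrides) -> "RunConfig":
        """Sparse-regime orientation-recovery benchmark: the experiment's
        photon statistics (200/frame, 80% background) and its orientation
        stage resolution (2.0 A; q_max = 16 a* for the a = 32 A toy cell)
        with 360 rotations at 1 degree.  Probabilities are evaluated against
        the known truth model, so no EMC iterations are configured."""
        base = dict(
            geometry=dict(n_fast=204, n_slow=204, pixel_pitch_mm=0.33,
                          distance_mm=33.0, wavelength_A=1.54,
                          beam_center_fast=102.0, beam_center_slow=102.0),
            cell_a_A=32.0, cell_c_A=36.0,
            n_rotations=360, grid_divisor=7, grid_extent=225,
            n_iter=0, n_frames=6000,
        )
        base.update(overrides)
        return cls.model_validate(base)

    @classmethod
    def reconstruction_benchmark(cls, **overrides) -> "RunConfig":
        """End-to-end desk-scale reconstruction benchmark: 20k frames at the
        sparse regime, 120 rotations at 3 degrees, 95^3 grid at a*/7
        (4.8 A), 30 EMC iterations."""
        base = dict(
            geometry=dict(n_fast=72, n_slow=72, pixel_pitch_mm=0.32,
                          distance_mm=33.0, wavelength_A=1.54,
                          beam_center_fast=36.0, beam_center_slow=36.0),
            cell_a_A=32.0, cell_c_A=36.0,
            n_rotations=120, grid_divisor=7, grid_extent=95,
            n_iter=30, n_frames=20000,
        )
        base.update(overrides)
        return cls.model_validate(base)

    @classmethod
    def toy(cls, **overrides) -> "RunConfig":
        """Seconds-scale preset: small tetragonal cell, 60 rotations, 63^3
        grid, 2000 frames.  Photon statistics stay at the sparse regime's
        200/frame with 80% background."""
        base = dict(
            geometry=dict(n_fast=48, n_slow=48, pixel_pitch_mm=0.30,
                          distance_mm=33.0, wavelength_A=1.54,
                          beam_center_fast=24.0, beam_center_slow=24.0),
            cell_a_A=32.0, cell_c_A=36.0,
            n_rotations=60, grid_divisor=7, grid_extent=63,
            n_iter=10, n_frames=2000,
        )
        base.update(overrides)
        return cls.model_validate(base)
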
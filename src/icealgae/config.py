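"""Validated pipeline configuration.

Every numeric choice of the workflow — smoothing window, PAR bounds,
continuum window, CBD wavelength, bin factor, CV folds, variogram lag
and sample count — is a configuration default rather than a hard-coded
constant, and every stochastic stage carries its own explicit seed.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, Field, field_validator

from . import reference


class SceneConfig(BaseModel):
    """Synthetic scene generator parameters."""

    seed: int
    n_sections: int = 42
    section_shape: tuple[int, int] = (48, 48)
    # under-ice block, pixels after binning: 0.85 x 0.70 m at 2.4 mm
    block_shape: tuple[int, int] = (354, 292)
    pixel_pitch_mm: float = 2.4
    wavelength_start_nm: float = 400.0
    wavelength_stop_nm: float = 700.0
    n_bands: int = 89
    chla_mean: float = reference.BOTTOM_CHLA_MEAN
    chla_sd: float = reference.BOTTOM_CHLA_SD
    within_section_cv: float = 0.5
    correlation_length_cm: float = 12.0
    t_ice_level: float = 0.3
    cavity_fraction: float = 0.08
    snr: float | None = 100.0
    read_sd: float = 0.0
    extraction_error_cv: float = 0.1
    light_source: str = "solar"
    n_deep_sections: int = 0
    deep_chla_mean: float = 0.62
    deep_chla_sd: float = 0.45
    block_native_pitch_mm: float = reference.UNDER_ICE_NATIVE_PITCH_MM

    @field_validator("n_sections")
    @classmethod
    def _enough_sections(cls, v: int) -> int:
        if v < 3:
            raise ValueError("need at least 3 sections")
        return v


class PreprocessConfig(BaseModel):
    polyorder: int = 2
    window: int = Field(9, description="Savitzky-Golay window, bands")
    bin_factor: int = Field(
        4, description="spatial binning applied to the under-ice block")
    par_bounds: tuple[float, float] = (400.0, 700.0)


class IndexConfigModel(BaseModel):
    window: tuple[float, float] = (650.0, 700.0)
    cbd_wavelength: float = 677.0
    auc_mode: str = "depth"
    clip_depth: bool = True
    floor: float = 1e-6
    ndi_min_abs_r: float = 0.7
    ndi_min_separation_nm: float = 12.0


class CalibrationConfig(BaseModel):
    folds: int = 10
    seed: int


class SpatialConfig(BaseModel):
    lag_width_px: int = 5
    n_samples: int = 10_000
    seed: int
    variogram_model: str = "exponential"


class PipelineConfig(BaseModel):
    """Top-level configuration binding all pipeline stages."""

    scene: SceneConfig
    preprocess: PreprocessConfig = PreprocessConfig()
    indices: IndexConfigModel = IndexConfigModel()
    calibration: CalibrationConfig
    spatial: SpatialConfig
    output_dir: str = "icealgae_run"

    def config_hash(self) -> str:
        """Stable hash of the full configuration, stamped on artifacts."""
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Study-scale configuration with all seeds derived from *seed*:

        42 bottom + 12 deep sections and an 0.85 x 0.70 m under-ice
        block at 2.4 mm binned pitch.
        """
        payload = {
            "scene": {"seed": seed,
                      "n_deep_sections": 12},
            "calibration": {"seed": seed + 1},
            "spatial": {"seed": seed + 2},
        }
        payload.update(overrides)
        return cls.model_validate(payload)

    @classmethod
    def demo(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Small, fast configuration (12 sections, 64 x 64 block)."""
        payload = {
            "scene": {"seed": seed, "n_sections": 12,
                      "section_shape": (32, 32), "block_shape": (64, 64),
                      "pixel_pitch_mm": 3.6},
            "calibration": {"seed": seed + 1},
            "spatial": {"seed": seed + 2, "n_samples": 4000},
        }
        payload.update(overrides)
        return cls.model_validate(payload)
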
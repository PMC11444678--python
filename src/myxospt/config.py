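"""Validated configuration blocks for the whole pipeline.

Every tunable default of the simulator and of the analysis chain lives here
so that a single :class:`PipelineConfig` can drive simulate → localize →
track → classify reproducibly.  Configs serialize to a canonical JSON string
whose SHA-1 prefix is recorded in every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class RenderConfig(BaseModel):
    """Camera / acquisition model.

    Defaults mirror a 160 nm effective pixel EMCCD acquiring at 10 Hz.
    """

    pixel_size_nm: float = Field(160.0, gt=0)
    frame_interval_s: float = Field(0.1, gt=0)
    psf_sigma_nm: float = Field(120.0, gt=0)
    photons_per_frame: float = Field(500.0, gt=0)
    background_level: float = Field(10.0, ge=0)
    read_noise_sd: float = Field(2.0, ge=0)
    image_shape: tuple[int, int] = (192, 192)

    @model_validator(mode="after")
    def _psf_vs_pixel(self) -> "RenderConfig":
        if not self.psf_sigma_nm < 3 * self.pixel_size_nm:
            raise ValueError("psf_sigma_nm must be < 3 × pixel_size_nm")
        if min(self.image_shape) < 1:
            raise ValueError("image_shape must be at least 1×1")
        return self


class MotionDefaults(BaseModel):
    """Per-mode motion parameters used by the population simulator."""

    diffusive_D_um2_s: float = Field(0.06, ge=0)
    directed_v_um_s: float = Field(1.0, ge=0)
    directed_period_um: float = Field(1.0, gt=0)
    directed_amplitude_frac: float = Field(0.8, ge=0, le=1.0)
    loc_noise_sd_nm: float = Field(25.0, ge=0)


class PhotophysicsConfig(BaseModel):
    mean_on_frames: float = Field(6.0, ge=1)
    max_active_per_cell: int = Field(1, ge=1)


class CellLayoutConfig(BaseModel):
    length_um: float = Field(6.0, gt=0)
    width_um: float = Field(0.7, gt=0)
    margin_um: float = Field(0.6, ge=0)


class DetectionConfig(BaseModel):
    k_sd: float = Field(5.0, gt=0)
    min_separation_px: int = Field(4, ge=1)
    window_px: int = Field(7, ge=3)
    dog_low_px: float = Field(1.0, gt=0)
    dog_high_px: float = Field(4.0, gt=0)


class LinkingConfig(BaseModel):
    max_disp_nm: float = Field(500.0, gt=0)
    max_gap: int = Field(0, ge=0)


class ClassifyConfig(BaseModel):
    min_frames: int = Field(4, ge=2)
    max_frames: int = Field(12, ge=2)
    box_nm: float = Field(160.0, gt=0)
    fit_lags: int = Field(3, ge=2)
    alpha_directed: float = Field(1.5, gt=0)

    @model_validator(mode="after")
    def _window(self) -> "ClassifyConfig":
        if self.min_frames > self.max_frames:
            raise ValueError("min_frames must be ≤ max_frames")
        return self


class SimulateConfig(BaseModel):
    """Population simulation: mixture fractions plus shared blocks."""

    fractions: dict[str, float] = Field(
        default_factory=lambda: {"stationary": 0.321, "directed": 0.3395, "diffusive": 0.3395}
    )
    n_tracks: int = Field(500, ge=1)
    render: RenderConfig = Field(default_factory=RenderConfig)
    motion: MotionDefaults = Field(default_factory=MotionDefaults)
    photophysics: PhotophysicsConfig = Field(default_factory=PhotophysicsConfig)
    cells: CellLayoutConfig = Field(default_factory=CellLayoutConfig)

    @model_validator(mode="after")
    def _fractions_sum(self) -> "SimulateConfig":
        allowed = {"stationary", "directed", "diffusive"}
        extra = set(self.fractions) - allowed
        if extra:
            raise ValueError(f"unknown modes in fractions: {sorted(extra)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be ≥ 0")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1 (got {sum(self.fractions.values()):.12f})"
            )
        return self


class PipelineConfig(BaseModel):
    """Top-level config: seed plus one block per pipeline stage."""

    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    linking: LinkingConfig = Field(default_factory=LinkingConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    output_dir: Optional[str] = None


def config_hash(cfg: BaseModel) -> str:
    """Short stable hash of a config (canonical-JSON SHA-1 prefix)."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
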
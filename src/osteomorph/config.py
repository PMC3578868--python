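"""Run configuration for the osteomorph pipeline.

Every generative, segmentation, morphometric and modeling parameter is
collected here so that a whole run is a pure function of (config, seed).
Configs round-trip through YAML for the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

VALID_CONDITIONS = ("induction", "control")


class ConfigError(ValueError):
    """A configuration key or value is invalid; the message names the key."""


@dataclass(frozen=True)
class DesignConfig:
    """The lot x condition x passage x well x field x timepoint lattice.

    The canonical design mirrors the study layout: 3 donor lots, two culture
    conditions (osteogenic induction vs non-induction control), 3 passages
    per lot, 3 wells per (lot, condition, passage), 5 view fields per well,
    images every 8 h with 40 scheduled timepoints of which 3 (settling and
    two medium changes) are excluded, leaving 37 retained timepoints.
    """

    n_lots: int = 3
    n_passages_per_lot: int = 3
    conditions: tuple[str, ...] = VALID_CONDITIONS
    wells_per_condition: int = 3
    fields_per_well: int = 5
    timepoints_scheduled: int = 40
    timepoints_excluded: tuple[int, ...] = (0, 7, 26)
    image_shape: tuple[int, int] = (192, 192)
    interval_hours: float = 8.0

    def __post_init__(self) -> None:
        for key in ("n_lots", "n_passages_per_lot", "wells_per_condition",
                    "fields_per_well", "timepoints_scheduled"):
            v = getattr(self, key)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"design.{key} must be a positive integer, got {v!r}")
        if not self.conditions or any(c not in VALID_CONDITIONS for c in self.conditions):
            raise ConfigError(
                f"design.conditions must be a non-empty subset of {VALID_CONDITIONS}, "
                f"got {self.conditions!r}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("design.conditions contains duplicates")
        for t in self.timepoints_excluded:
            if not (0 <= t < self.timepoints_scheduled):
                raise ConfigError(
                    f"design.timepoints_excluded entry {t} outside scheduled range "
                    f"[0, {self.timepoints_scheduled})")
        if len(set(self.timepoints_excluded)) != len(self.timepoints_excluded):
            raise ConfigError("design.timepoints_excluded contains duplicates")
        if len(self.image_shape) != 2 or any(s < 16 for s in self.image_shape):
            raise ConfigError(f"design.image_shape must be (H, W) >= 16 px, got {self.image_shape!r}")
        if self.interval_hours <= 0:
            raise ConfigError("design.interval_hours must be positive")


@dataclass(frozen=True)
class LatentConfig:
    """Hierarchical variance structure of the latent osteogenic potential.

    Potential of a well = condition mean + lot + passage + well effects,
    clipped to [0, 1].  Variance decomposes lot > passage > well, emulating
    patient-derived vs processing-derived variance.  Each lot additionally
    carries a morphological "style" offset (log cell-size scale) that also
    leaks into the assay values — the patient-specific component that pilot
    data can calibrate away.
    """

    mu_induction: float = 0.70
    mu_control: float = 0.25
    sd_lot: float = 0.12
    sd_passage: float = 0.06
    sd_well: float = 0.03
    sd_style: float = 0.15

    def __post_init__(self) -> None:
        for key in ("sd_lot", "sd_passage", "sd_well", "sd_style"):
            if getattr(self, key) < 0:
                raise ConfigError(f"latent.{key} must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic phase-contrast rendering parameters.

    Cells are bright-on-dark superellipses; control / low-potential cells
    are elongated spindles (aspect 3-8), induced / high-potential cells are
    flat spread shapes (aspect 1-2), optionally with an interior hole.  The
    phenotype interpolates with culture time so group separation grows.
    Cell counts are scaled to tens per field (desk scale).
    """

    base_cell_area: float = 150.0
    min_cell_area: float = 80.0       # raster floor; keeps cells above debris scale
    area_sigma: float = 0.20          # lognormal spread of per-cell area
    spread_area_gain: float = 1.2     # spread cells are larger: area *= 1 + gain*phenotype
    spindle_aspect: tuple[float, float] = (3.0, 8.0)
    spread_aspect: tuple[float, float] = (1.0, 2.0)
    spindle_exponent: float = 1.3     # superellipse exponent (pointed)
    spread_exponent: float = 4.0      # superellipse exponent (boxy/spread)
    hole_prob_scale: float = 0.5      # P(hole) = scale * phenotype
    hole_radius_frac: float = 0.30    # hole semi-axes as fraction of cell's
    ramp_floor: float = 0.15          # phenotype ramp at t=0 (fraction of potential)
    initial_cells: int = 6
    growth_log_factor: float = 0.92   # n(t) = round(n0 * exp(g * t_frac)); e^0.92 ~ 2.5x
    intensity_bg: float = 40.0
    intensity_cell: float = 120.0     # added on top of background
    intensity_cell_sd: float = 12.0
    noise_sd: float = 5.0
    gradient_amp: float = 8.0         # planar illumination gradient amplitude
    n_noise_particles: float = 4.0    # Poisson mean of sub-cell bright specks
    noise_particle_radius: tuple[float, float] = (1.0, 2.0)
    min_gap: int = 5                  # min pixel gap between placed cells
    max_place_tries: int = 150

    def __post_init__(self) -> None:
        if self.base_cell_area <= 0:
            raise ConfigError("render.base_cell_area must be positive")
        if self.initial_cells < 0:
            raise ConfigError("render.initial_cells must be >= 0")


@dataclass(frozen=True)
class MarkerConfig:
    """Terminal biochemical marker generator.

    ALP activity (day 14) and calcium deposition (day 21) are monotone
    functions of the latent potential plus heteroscedastic noise; calcium
    has the larger coefficient of variation and the stronger lot-style
    offset, emulating the larger spread of the late maturation marker.
    """

    alp_base: float = 0.25
    alp_gain: float = 0.90
    alp_style_gain: float = 0.30
    alp_lot_sd: float = 0.08          # donor-level assay offset, SD on marker scale
    alp_cv: float = 0.07
    ca_base: float = 0.05
    ca_gain: float = 0.80
    ca_power: float = 2.0
    ca_style_gain: float = 0.35
    ca_lot_sd: float = 0.15           # larger donor-level offset for the late marker
    ca_cv: float = 0.22

    def __post_init__(self) -> None:
        if self.alp_cv < 0 or self.ca_cv < 0:
            raise ConfigError("marker CVs must be >= 0")


@dataclass(frozen=True)
class SegmentationConfig:
    """Binarization chain parameters (one global threshold per dataset)."""

    threshold: float | None = None    # None -> calibrated from reference counts
    threshold_grid: tuple[float, float, float] = (30.0, 180.0, 5.0)  # lo, hi, step
    n_calibration_images: int = 20
    open_radius: int = 1
    close_radius: int = 1
    min_particle_area: int = 50
    background_kernel: int = 33       # square window (px) for background opening
    invert: bool = False              # dark-on-bright inputs

    def __post_init__(self) -> None:
        if self.open_radius < 0 or self.close_radius < 0:
            raise ConfigError("segmentation radii must be >= 0")
        if self.min_particle_area < 0:
            raise ConfigError("segmentation.min_particle_area must be >= 0")
        if self.background_kernel < 3:
            raise ConfigError("segmentation.background_kernel must be >= 3 px")


@dataclass(frozen=True)
class FeatureTableConfig:
    morphology_only: bool = False     # True -> drop cell-count features (666-col design)
    max_missing_frac: float = 0.2
    cleanse_z_cut: float = 3.5
    total_area_filled: bool = True    # total area = hole-filled area (default convention)


@dataclass(frozen=True)
class ModelConfig:
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-3, 4, 15))
    pilot_passages: int = 1

    def __post_init__(self) -> None:
        if not self.lambda_grid:
            raise ConfigError("model.lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ConfigError("model.lambda_grid entries must be >= 0")
        if self.pilot_passages < 0:
            raise ConfigError("model.pilot_passages must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    latent: LatentConfig = field(default_factory=LatentConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    feature_table: FeatureTableConfig = field(default_factory=FeatureTableConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = _tuples_to_lists(self.to_dict())
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: f.type for f in dc_fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in sections:
                raise ConfigError(f"unknown config section {key!r}")
            sub_cls = {
                "design": DesignConfig, "latent": LatentConfig, "render": RenderConfig,
                "marker": MarkerConfig, "segmentation": SegmentationConfig,
                "feature_table": FeatureTableConfig, "model": ModelConfig,
            }[key]
            kwargs[key] = _build_section(sub_cls, key, value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping of sections")
        return cls.from_dict(d)


def _build_section(sub_cls, section: str, value):
    if not isinstance(value, dict):
        raise ConfigError(f"config section {section!r} must be a mapping")
    valid = {f.name for f in dc_fields(sub_cls)}
    kwargs = {}
    for k, v in value.items():
        if k not in valid:
            raise ConfigError(f"unknown config key {section}.{k}")
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return sub_cls(**kwargs)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def canonical_config() -> PipelineConfig:
    """The full study layout: 54 wells x 5 fields x 37 retained timepoints
    = 9,990 acquisition slots, 9 features x 2 statistics x 37 timepoints
    = 666 morphology columns."""
    return PipelineConfig()


def desk_config() -> PipelineConfig:
    """A reduced lattice for simulation-heavy runs.

    Keeps the complete 54-well lot/condition/passage structure (which the
    transfer scenarios depend on) but images 2 fields/well at 10 retained
    timepoints so a full image-to-prediction run takes seconds-to-minutes
    on one core.
    """
    return PipelineConfig(design=DesignConfig(
        fields_per_well=2,
        timepoints_scheduled=12,
        timepoints_excluded=(0, 5),
    ))
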
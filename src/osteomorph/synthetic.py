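"""Synthetic time-lapse study generator.

Stands in for the undeposited incubator-microscope dataset: renders
grayscale phase-contrast-like fields of hBMSC-shaped blobs whose morphology
tracks a latent osteogenic potential, and draws terminal ALP / calcium
marker values from the same latent, so every downstream stage (segmentation
-> morphometrics -> feature table -> modeling) is testable end to end.

The generative model, in brief:

* Each well has a latent potential in [0, 1] = condition mean (induction
  0.70 vs control 0.25 by default) + Gaussian lot, passage and well effects
  with SDs ordered lot > passage > well.
* Each lot has a "style" scalar scaling cell size and offsetting both
  markers — a patient-specific component that a model can only learn with
  in-lot (pilot) training data.
* Cell shape phenotype = potential x time ramp: spindly high-aspect
  superellipses at low phenotype, large spread low-aspect shapes (with
  occasional interior holes) at high phenotype, so induction and control
  morphologies diverge over culture time.
* Markers are monotone in potential with heteroscedastic noise; calcium
  deposition has the larger CV and lot offset than ALP activity.

Everything is a pure function of (config, seed): per-field RNGs are derived
from ``SeedSequence((seed, well_index, field, timepoint))``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import DesignConfig, LatentConfig, MarkerConfig, RenderConfig, ConfigError

__all__ = [
    "WellKey", "ExperimentDesign", "LatentPotential", "MarkerValues",
    "build_design", "sample_latents", "sample_markers", "render_field",
    "cells_at_timepoint", "simulate_markers_table", "write_dataset",
]


@dataclass(frozen=True, order=True)
class WellKey:
    """Identifies one well: (lot, condition, passage, well replicate)."""

    lot: int
    condition: str
    passage: int
    well: int

    @property
    def well_id(self) -> str:
        return f"L{self.lot}_{self.condition}_P{self.passage}_W{self.well}"


@dataclass(frozen=True)
class ExperimentDesign:
    """Enumerates every acquisition slot of the study lattice."""

    config: DesignConfig

    @property
    def retained_timepoints(self) -> tuple[int, ...]:
        excl = set(self.config.timepoints_excluded)
        return tuple(t for t in range(self.config.timepoints_scheduled) if t not in excl)

    @property
    def n_retained_timepoints(self) -> int:
        return len(self.retained_timepoints)

    @property
    def wells(self) -> tuple[WellKey, ...]:
        c = self.config
        return tuple(
            WellKey(lot, cond, p, w)
            for lot in range(1, c.n_lots + 1)
            for cond in c.conditions
            for p in range(1, c.n_passages_per_lot + 1)
            for w in range(1, c.wells_per_condition + 1)
        )

    @property
    def n_wells(self) -> int:
        c = self.config
        return (c.n_lots * len(c.conditions) * c.n_passages_per_lot
                * c.wells_per_condition)

    @property
    def n_slots(self) -> int:
        return self.n_wells * self.config.fields_per_well * self.n_retained_timepoints

    def iter_slots(self) -> Iterator[tuple[WellKey, int, int]]:
        """Yield (well, field, timepoint) for every retained acquisition slot."""
        tps = self.retained_timepoints
        for well in self.wells:
            for f in range(1, self.config.fields_per_well + 1):
                for t in tps:
                    yield well, f, t

    def well_index(self, well: WellKey) -> int:
        return self.wells.index(well)


@dataclass(frozen=True)
class LatentPotential:
    """Latent state of one well driving both morphology and markers."""

    well: WellKey
    lot_effect: float
    passage_effect: float
    well_effect: float
    style: float          # lot-level log cell-size scale, leaks into markers
    assay_offset: float   # lot-level N(0,1) assay bias, morphology-independent
    potential_score: float  # in [0, 1]

    @property
    def condition(self) -> str:
        return self.well.condition


@dataclass(frozen=True)
class MarkerValues:
    """Terminal assay outcomes for one well (dimensionless absorbance rates)."""

    alp_rate: float
    ca_rate: float


def build_design(config: DesignConfig | Mapping) -> ExperimentDesign:
    """Validate a design config and enumerate the acquisition lattice.

    Raises :class:`~osteomorph.config.ConfigError` naming the offending key
    for invalid input.
    """
    if isinstance(config, Mapping):
        valid = DesignConfig.__dataclass_fields__.keys()
        for k in config:
            if k not in valid:
                raise ConfigError(f"unknown design key {k!r}")
        cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in config.items()}
        config = DesignConfig(**cfg)
    return ExperimentDesign(config)


def sample_latents(design: ExperimentDesign, seed: int,
                   latent_cfg: LatentConfig | None = None) -> dict[WellKey, LatentPotential]:
    """Draw the hierarchical latent potential for every well.

    Lot and style effects are shared by all wells of a lot; passage effects
    by all wells of a (lot, passage); the result is reproducible given the
    seed.
    """
    cfg = latent_cfg or LatentConfig()
    c = design.config
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
    lot_eff = {lot: rng.normal(0.0, cfg.sd_lot) for lot in range(1, c.n_lots + 1)}
    style = {lot: rng.normal(0.0, cfg.sd_style) for lot in range(1, c.n_lots + 1)}
    assay = {lot: rng.standard_normal() for lot in range(1, c.n_lots + 1)}
    pass_eff = {
        (lot, p): rng.normal(0.0, cfg.sd_passage)
        for lot in range(1, c.n_lots + 1)
        for p in range(1, c.n_passages_per_lot + 1)
    }
    mu = {"induction": cfg.mu_induction, "control": cfg.mu_control}
    out: dict[WellKey, LatentPotential] = {}
    for well in design.wells:
        w_eff = rng.normal(0.0, cfg.sd_well)
        raw = mu[well.condition] + lot_eff[well.lot] + pass_eff[(well.lot, well.passage)] + w_eff
        out[well] = LatentPotential(
            well=well,
            lot_effect=lot_eff[well.lot],
            passage_effect=pass_eff[(well.lot, well.passage)],
            well_effect=w_eff,
            style=style[well.lot],
            assay_offset=assay[well.lot],
            potential_score=float(np.clip(raw, 0.0, 1.0)),
        )
    return out


def sample_markers(latent: LatentPotential, seed: int,
                   marker_cfg: MarkerConfig | None = None,
                   noise: bool = True) -> MarkerValues:
    """Draw terminal ALP / calcium values for one well.

    Noise-free means are monotone increasing in the potential score; the
    noise is heteroscedastic (SD proportional to the mean) with the calcium
    CV larger than the ALP CV.  ``noise=False`` returns the means.
    """
    cfg = marker_cfg or MarkerConfig()
    p = latent.potential_score
    mean_alp = (cfg.alp_base + cfg.alp_gain * p + cfg.alp_style_gain * latent.style
                + cfg.alp_lot_sd * latent.assay_offset)
    mean_ca = (cfg.ca_base + cfg.ca_gain * p ** cfg.ca_power
               + cfg.ca_style_gain * latent.style
               + cfg.ca_lot_sd * latent.assay_offset)
    mean_alp = max(mean_alp, 0.0)
    mean_ca = max(mean_ca, 0.0)
    if not noise:
        return MarkerValues(mean_alp, mean_ca)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    alp = mean_alp + rng.normal(0.0, cfg.alp_cv * mean_alp)
    ca = mean_ca + rng.normal(0.0, cfg.ca_cv * mean_ca)
    return MarkerValues(float(max(alp, 0.0)), float(max(ca, 0.0)))


def cells_at_timepoint(timepoint: int, n_timepoints: int,
                       render_cfg: RenderConfig) -> int:
    """Deterministic proliferation curve: exponential growth over the run."""
    t_frac = 0.0 if n_timepoints <= 1 else timepoint / (n_timepoints - 1)
    return int(round(render_cfg.initial_cells * math.exp(render_cfg.growth_log_factor * t_frac)))


# ---------------------------------------------------------------------------
# field rendering


def _superellipse_mask(length: float, breadth: float, exponent: float,
                       angle: float, hole_frac: float | None) -> np.ndarray:
    """Rasterize a rotated superellipse |x/a|^m + |y/b|^m <= 1 as a bool crop."""
    a, b = length / 2.0, breadth / 2.0
    # bounding half-extent after rotation
    ext = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-ext:ext + 1, -ext:ext + 1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = xx * ca + yy * sa
    v = -xx * sa + yy * ca
    with np.errstate(divide="ignore"):
        body = (np.abs(u / a) ** exponent + np.abs(v / b) ** exponent) <= 1.0
    if hole_frac is not None:
        ha, hb = max(a * hole_frac, 1.0), max(b * hole_frac, 1.0)
        hole = (np.abs(u / ha) ** 2 + np.abs(v / hb) ** 2) <= 1.0
        body &= ~hole
    return body


def _phenotype(latent: LatentPotential, timepoint: int, n_timepoints: int,
               cfg: RenderConfig) -> float:
    t_frac = 0.0 if n_timepoints <= 1 else timepoint / (n_timepoints - 1)
    ramp = cfg.ramp_floor + (1.0 - cfg.ramp_floor) * t_frac
    return float(np.clip(latent.potential_score * ramp, 0.0, 1.0))


def render_field(latent: LatentPotential, timepoint: int, n_cells: int, seed: int,
                 *, image_shape: tuple[int, int] = (160, 160),
                 n_timepoints: int = 37,
                 render_cfg: RenderConfig | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one view field.

    Returns ``(image, truth_labels, truth_count)``: an 8-bit grayscale image
    with bright cells on a dark background (plus illumination gradient,
    Gaussian noise and sub-cell-size bright specks for the cleansing stages
    to remove), the ground-truth label raster (cells labeled 1..n, specks
    excluded), and the true cell count.

    Raises ``RuntimeError`` if ``n_cells`` cannot be packed into the field
    without overlap.
    """
    cfg = render_cfg or RenderConfig()
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    h, w = image_shape
    rng = np.random.default_rng(np.random.SeedSequence(
        (int(seed), zlib.crc32(latent.well.well_id.encode()), int(timepoint))))

    phenotype = _phenotype(latent, timepoint, n_timepoints, cfg)
    size_scale = math.exp(latent.style)

    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    gap = cfg.min_gap
    gap_struct = np.ones((2 * gap + 1, 2 * gap + 1), dtype=bool)

    for i in range(1, n_cells + 1):
        placed = False
        for attempt in range(cfg.max_place_tries):
            area = cfg.base_cell_area * rng.lognormal(0.0, cfg.area_sigma)
            area *= (1.0 + cfg.spread_area_gain * phenotype) * size_scale
            # crowding: accept progressively smaller cells in dense fields
            area = max(area * 0.985 ** attempt, cfg.min_cell_area)
            asp_sp = rng.uniform(*cfg.spindle_aspect)
            asp_fl = rng.uniform(*cfg.spread_aspect)
            aspect = asp_sp * (1.0 - phenotype) + asp_fl * phenotype
            length = math.sqrt(area * aspect)
            breadth = max(math.sqrt(area / aspect), 3.0)
            exponent = cfg.spindle_exponent * (1.0 - phenotype) + cfg.spread_exponent * phenotype
            hole = cfg.hole_radius_frac if rng.random() < cfg.hole_prob_scale * phenotype else None
            angle = rng.uniform(0.0, math.pi)
            crop = _superellipse_mask(length, breadth, exponent, angle, hole)
            ch, cw = crop.shape
            if ch >= h - 2 or cw >= w - 2:
                continue
            r0 = rng.integers(1, h - ch)
            c0 = rng.integers(1, w - cw)
            grown = ndi.binary_dilation(crop, structure=gap_struct)
            if (occupied[r0:r0 + ch, c0:c0 + cw] & grown).any():
                continue
            sub = labels[r0:r0 + ch, c0:c0 + cw]
            sub[crop] = i
            occupied[r0:r0 + ch, c0:c0 + cw] |= crop
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not pack {n_cells} cells into a {h}x{w} field "
                f"(placed {i - 1}); reduce cell count or size")

    img = np.full((h, w), cfg.intensity_bg, dtype=np.float64)
    # planar illumination gradient, removed later by background flattening
    gy, gx = rng.uniform(-1.0, 1.0, size=2)
    yy, xx = np.mgrid[0:h, 0:w]
    img += cfg.gradient_amp * (gy * (yy / max(h - 1, 1) - 0.5) + gx * (xx / max(w - 1, 1) - 0.5))
    for i in range(1, n_cells + 1):
        img[labels == i] += rng.normal(cfg.intensity_cell, cfg.intensity_cell_sd)

    # sub-cell-size bright specks (debris); excluded from ground truth
    n_specks = rng.poisson(cfg.n_noise_particles)
    for _ in range(n_specks):
        r = rng.uniform(*cfg.noise_particle_radius)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img[dist2 <= r ** 2] += cfg.intensity_cell * rng.uniform(0.7, 1.1)

    img += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, labels, n_cells


# ---------------------------------------------------------------------------
# dataset-level helpers


def simulate_markers_table(design: ExperimentDesign, seed: int,
                           latent_cfg: LatentConfig | None = None,
                           marker_cfg: MarkerConfig | None = None) -> pd.DataFrame:
    """Latents + markers for every well as a tidy table.

    Columns: well_id, lot, passage, condition, potential_score, style,
    alp_rate, ca_rate.
    """
    latents = sample_latents(design, seed, latent_cfg)
    rows = []
    for idx, well in enumerate(design.wells):
        lat = latents[well]
        mk = sample_markers(lat, seed=int(seed) * 100_003 + idx, marker_cfg=marker_cfg)
        rows.append({
            "well_id": well.well_id, "lot": well.lot, "passage": well.passage,
            "condition": well.condition, "potential_score": lat.potential_score,
            "style": lat.style, "alp_rate": mk.alp_rate, "ca_rate": mk.ca_rate,
        })
    return pd.DataFrame(rows)


def field_seed(seed: int, design: ExperimentDesign, well: WellKey,
               field: int, timepoint: int) -> int:
    """Deterministic per-(well, field, timepoint) rendering seed."""
    idx = design.well_index(well)
    return (int(seed) * 1_000_003 + idx * 10_007 + field * 101 + timepoint) % (2 ** 31)


def iter_rendered_fields(design: ExperimentDesign, seed: int,
                         latents: Mapping[WellKey, LatentPotential],
                         render_cfg: RenderConfig | None = None,
                         ) -> Iterator[tuple[WellKey, int, int, np.ndarray, np.ndarray, int]]:
    """Stream every acquisition slot as (well, field, tp, image, truth, count)."""
    cfg = render_cfg or RenderConfig()
    tps = design.retained_timepoints
    n_t = design.config.timepoints_scheduled
    for well, f, t in design.iter_slots():
        lat = latents[well]
        n_cells = cells_at_timepoint(t, n_t, cfg)
        img, truth, count = render_field(
            lat, t, n_cells, field_seed(seed, design, well, f, t),
            image_shape=design.config.image_shape, n_timepoints=n_t,
            render_cfg=cfg)
        yield well, f, t, img, truth, count


def write_dataset(design: ExperimentDesign, seed: int, outdir: str | Path,
                  latent_cfg: LatentConfig | None = None,
                  render_cfg: RenderConfig | None = None,
                  marker_cfg: MarkerConfig | None = None) -> Path:
    """Materialize a synthetic study on disk.

    Layout: ``lot<L>/passage<P>/<condition>/well<W>/field<F>/t###.tif`` with
    a sibling ``t###_truth.tif`` label image per slot, plus ``markers.csv``
    at the root (well_id, lot, passage, condition, alp_rate, ca_rate).
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    latents = sample_latents(design, seed, latent_cfg)
    for well, f, t, img, truth, _count in iter_rendered_fields(
            design, seed, latents, render_cfg):
        d = (outdir / f"lot{well.lot}" / f"passage{well.passage}" / well.condition
             / f"well{well.well}" / f"field{f}")
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / f"t{t:03d}.tif", img)
        tifffile.imwrite(d / f"t{t:03d}_truth.tif", truth.astype(np.int32))
    table = simulate_markers_table(design, seed, latent_cfg, marker_cfg)
    table[["well_id", "lot", "passage", "condition", "alp_rate", "ca_rate"]].to_csv(
        outdir / "markers.csv", index=False)
    return outdir
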
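"""End-to-end orchestration: synthetic study -> segmentation ->
morphometrics -> feature table -> both endpoint models under both transfer
scenarios.

The run is a pure function of (config, seed).  Stages stream per-field to
keep memory flat; a :class:`RunManifest` records the config snapshot, seed,
version, per-stage counts and output hashes so a completed run is
reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .evaluation import PredictionReport
from .feature_table import FeatureMatrix, aggregate_well, build_matrix
from .modeling import ENDPOINTS, SCHEMES, run_scenario
from .morphometrics import cleanse_noise, measure_objects
from .segmentation import (default_threshold_grid, extract_objects, binarize,
                           optimize_threshold, preprocess)
from .synthetic import (build_design, iter_rendered_fields, sample_latents,
                        simulate_markers_table)

logger = logging.getLogger("osteomorph")

__all__ = ["RunManifest", "PipelineResult", "run_pipeline", "build_feature_matrix"]


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    threshold: float | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


@dataclass
class PipelineResult:
    manifest: RunManifest
    matrix: FeatureMatrix
    reports: dict[tuple[str, str], PredictionReport]
    object_table: pd.DataFrame


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.round(12), index=True).values.tobytes()
    ).hexdigest()[:16]


def build_feature_matrix(config: PipelineConfig, seed: int,
                         manifest: RunManifest | None = None
                         ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Run simulate -> segment -> measure -> cleanse -> aggregate -> matrix.

    Returns the feature matrix plus the full per-object feature table.
    """
    design = build_design(config.design)
    latents = sample_latents(design, seed, config.latent)
    markers = simulate_markers_table(design, seed, config.latent, config.marker)
    seg = config.segmentation
    ft_cfg = config.feature_table

    # stage 1: calibrate one global threshold on a random slot reservoir
    logger.info("rendering %d acquisition slots", design.n_slots)
    if seg.threshold is not None:
        threshold = float(seg.threshold)
        n_cal = 0
    else:
        from .synthetic import cells_at_timepoint, field_seed, render_field

        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
        all_slots = list(design.iter_slots())
        n_cal = min(seg.n_calibration_images, len(all_slots))
        picks = rng.choice(len(all_slots), size=n_cal, replace=False)
        calibration = []
        for k in sorted(map(int, picks)):
            well, f, t = all_slots[k]
            n_cells = cells_at_timepoint(t, design.config.timepoints_scheduled,
                                         config.render)
            img, _truth, count = render_field(
                latents[well], t, n_cells, field_seed(seed, design, well, f, t),
                image_shape=design.config.image_shape,
                n_timepoints=design.config.timepoints_scheduled,
                render_cfg=config.render)
            calibration.append((preprocess(img, seg), count))
        threshold = optimize_threshold(calibration, default_threshold_grid(seg), seg)
    logger.info("global threshold: %.1f (calibrated on %d images)", threshold, n_cal)
    if manifest is not None:
        manifest.threshold = threshold
        manifest.counts["images"] = design.n_slots

    # stage 2: stream every slot: preprocess, binarize, label, measure
    field_tables: dict[tuple[str, int], list[pd.DataFrame]] = {}
    for well, f, t, img, _truth, _count in iter_rendered_fields(
            design, seed, latents, config.render):
        pre = preprocess(img, seg)
        objset = extract_objects(binarize(pre, threshold), seg,
                                 source=f"{well.well_id}/f{f}/t{t}")
        df = measure_objects(objset, total_area_filled=ft_cfg.total_area_filled,
                             meta={"well_id": well.well_id, "field": f,
                                   "timepoint": t})
        field_tables.setdefault((well.well_id, t), []).append(df)

    # stage 3: cleanse and aggregate per (well, timepoint)
    object_frames = []
    aggregates = {}
    n_objects = n_removed = 0
    for well in design.wells:
        for t in design.retained_timepoints:
            tables = field_tables.get((well.well_id, t), [])
            pooled = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            if len(pooled):
                kept, removed = cleanse_noise(pooled, ft_cfg.cleanse_z_cut)
                n_removed += len(removed)
            else:
                kept = pooled
            n_objects += len(kept)
            object_frames.append(kept)
            per_field = [kept[kept["field"] == f] for f in
                         range(1, design.config.fields_per_well + 1)]
            aggregates[(well.well_id, t)] = aggregate_well(per_field, t)
    object_table = pd.concat(object_frames, ignore_index=True) if object_frames else pd.DataFrame()
    logger.info("measured %d objects (%d removed by cleansing)", n_objects, n_removed)

    matrix = build_matrix(design, aggregates, markers,
                          morphology_only=ft_cfg.morphology_only,
                          max_missing_frac=ft_cfg.max_missing_frac)
    logger.info("feature matrix: %d samples x %d columns",
                matrix.n_samples, matrix.n_columns)
    if manifest is not None:
        manifest.counts.update({
            "objects": int(n_objects), "objects_cleansed": int(n_removed),
            "samples": int(matrix.n_samples), "columns": int(matrix.n_columns),
            "morphology_columns": int(
                sum(1 for fname, _, _ in matrix.column_info if fname != "cell_count")),
        })
        manifest.hashes["feature_matrix"] = _hash_frame(matrix.X)
        manifest.hashes["markers"] = _hash_frame(markers)
    return matrix, object_table


def run_pipeline(config: PipelineConfig, seed: int,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain and evaluate both endpoints in both schemes.

    With fewer than 2 lots the transfer scenarios are refused with an
    explanatory error.  When ``outdir`` is given, the feature matrix, the
    per-scheme/endpoint reports and the manifest are written there.
    """
    manifest = RunManifest(seed=int(seed), version=__version__,
                           config=config.to_dict(), started=time.time())
    if config.design.n_lots < 2:
        raise ValueError(
            "transfer scenarios need >= 2 lots (held-out-patient evaluation); "
            f"got n_lots={config.design.n_lots}")
    matrix, object_table = build_feature_matrix(config, seed, manifest)

    reports: dict[tuple[str, str], PredictionReport] = {}
    for scheme in SCHEMES:
        for endpoint in ENDPOINTS:
            rep = run_scenario(matrix, scheme, endpoint,
                               lambda_grid=config.model.lambda_grid,
                               pilot_passages=config.model.pilot_passages)
            reports[(scheme, endpoint)] = rep
            logger.info("%s / %s: R=%.3f MAE=%.3f SE=%.3f", scheme, endpoint,
                        rep.r, rep.mean_abs_error, rep.standardized_error)
    manifest.finished = time.time()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(outdir / "feature_matrix.csv")
        col_dict = [{"column": c, "feature": f, "stat": s, "timepoint": t}
                    for c, (f, s, t) in zip(matrix.X.columns, matrix.column_info)]
        (outdir / "columns.json").write_text(json.dumps(col_dict))
        summary_rows = []
        for (scheme, endpoint), rep in reports.items():
            rep.per_sample.to_csv(outdir / f"predictions_{scheme}_{endpoint}.csv",
                                  index=False)
            summary_rows.append(rep.summary())
        pd.DataFrame(summary_rows).to_csv(outdir / "summary.csv", index=False)
        manifest.hashes["summary"] = _hash_frame(pd.DataFrame(summary_rows).round(9))
        manifest.to_json(outdir / "manifest.json")
    return PipelineResult(manifest=manifest, matrix=matrix, reports=reports,
                          object_table=object_table)
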
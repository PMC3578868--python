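"""Per-well sample vectors: mean/SD of each feature per retained timepoint.

The modeling sample unit is the well.  At each retained timepoint all
objects from the well's view fields are pooled and the mean (AVE) and
standard deviation (SD) of each of the nine morphometric features are
taken over that pooled object population; the per-field cell count
contributes its own mean/SD across fields (features 19-20).  Stacking over
timepoints gives the sample vector — 9 features x 2 statistics x 37
retained timepoints = 666 morphology columns under the canonical design,
plus 2 x 37 count columns unless ``morphology_only`` is set.

Column order is feature-major, statistic next, timepoint-minor:
``f1_mean_t01..f1_mean_tNN, f1_sd_t01.., f2_mean_..`` with count features
last.  Missing well/timepoint entries (zero retained objects) are linearly
interpolated along time and flagged; wells missing more than
``max_missing_frac`` of their timepoints are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometrics import FEATURE_NAMES
from .synthetic import ExperimentDesign, WellKey

__all__ = [
    "CELL_COUNT_FEATURE", "SampleRecord", "FeatureMatrix",
    "aggregate_well", "build_matrix", "delta_transform", "column_name",
]

CELL_COUNT_FEATURE = "cell_count"
STATS = ("mean", "sd")


def column_name(feature: str, stat: str, timepoint: int) -> str:
    return f"{feature}__{stat}__t{timepoint:03d}"


@dataclass(frozen=True)
class SampleRecord:
    """One well's feature vector tagged with its terminal marker values."""

    well_id: str
    lot: int
    passage: int
    condition: str
    feature_vector: np.ndarray
    columns: tuple[str, ...]
    alp_rate: float
    ca_rate: float
    missing_mask: np.ndarray  # bool per column, True where interpolated


@dataclass
class FeatureMatrix:
    """Samples x columns feature matrix with aligned metadata.

    ``X`` holds only feature columns (index = well_id); ``meta`` carries
    lot, passage, condition and the two marker endpoints; ``missing`` marks
    interpolated cells; ``column_info`` maps each column to its
    (feature, statistic, timepoint) triple.
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    missing: pd.DataFrame
    column_info: list[tuple[str, str, int]]
    interval_hours: float = 8.0

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def features(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f, _, _ in self.column_info:
            seen.setdefault(f)
        return tuple(seen)

    @property
    def timepoints(self) -> tuple[int, ...]:
        return tuple(sorted({t for _, _, t in self.column_info}))

    def records(self) -> list[SampleRecord]:
        out = []
        for well_id, row in self.X.iterrows():
            m = self.meta.loc[well_id]
            out.append(SampleRecord(
                well_id=well_id, lot=int(m["lot"]), passage=int(m["passage"]),
                condition=str(m["condition"]),
                feature_vector=row.to_numpy(float),
                columns=tuple(self.X.columns),
                alp_rate=float(m["alp_rate"]), ca_rate=float(m["ca_rate"]),
                missing_mask=self.missing.loc[well_id].to_numpy(bool),
            ))
        return out

    def drop_feature(self, feature: str) -> "FeatureMatrix":
        """Return a copy with every column of ``feature`` removed."""
        if feature not in self.features:
            raise KeyError(
                f"unknown feature {feature!r}; valid features: {list(self.features)}")
        keep = [i for i, (f, _, _) in enumerate(self.column_info) if f != feature]
        cols = [self.X.columns[i] for i in keep]
        return FeatureMatrix(
            X=self.X[cols].copy(), meta=self.meta.copy(),
            missing=self.missing[cols].copy(),
            column_info=[self.column_info[i] for i in keep],
            interval_hours=self.interval_hours)

    def to_csv(self, path) -> None:
        merged = pd.concat([self.meta, self.X], axis=1)
        merged.to_csv(path, index_label="well_id")


def aggregate_well(field_tables: Sequence[pd.DataFrame], timepoint: int
                   ) -> tuple[dict[str, float], dict[str, float], tuple[float, float]]:
    """Pool one well's per-field object tables at one timepoint.

    Returns (means, sds, (count_mean, count_sd)): feature means and SDs over
    the pooled object population across fields, and mean/SD of the
    per-field object counts.  With zero retained objects everywhere the
    feature entries are NaN (to be interpolated and flagged upstream).
    SDs use the population (ddof=0) convention.
    """
    counts = np.array([len(t) for t in field_tables], dtype=float)
    nonempty = [t for t in field_tables if len(t)]
    if nonempty:
        pooled = pd.concat(nonempty, ignore_index=True)
        means = {f: float(pooled[f].mean()) for f in FEATURE_NAMES}
        sds = {f: float(pooled[f].std(ddof=0)) for f in FEATURE_NAMES}
    else:
        means = {f: float("nan") for f in FEATURE_NAMES}
        sds = {f: float("nan") for f in FEATURE_NAMES}
    count_stats = (float(counts.mean()) if counts.size else float("nan"),
                   float(counts.std(ddof=0)) if counts.size else float("nan"))
    return means, sds, count_stats


def build_matrix(design: ExperimentDesign,
                 aggregates: Mapping[tuple[str, int], tuple[dict, dict, tuple[float, float]]],
                 markers: pd.DataFrame,
                 *, morphology_only: bool = False,
                 max_missing_frac: float = 0.2) -> FeatureMatrix:
    """Assemble the samples x columns matrix from per-(well, timepoint)
    aggregates and the marker table.

    ``aggregates`` maps (well_id, timepoint) to the triple produced by
    :func:`aggregate_well`; absent keys and NaN aggregates count as missing
    and are linearly interpolated along time (flagged in ``missing``).
    Raises ``KeyError`` naming any well that lacks a marker row and
    ``ValueError`` for wells exceeding the missing-fraction budget.
    """
    tps = design.retained_timepoints
    feats = list(FEATURE_NAMES) + ([] if morphology_only else [CELL_COUNT_FEATURE])
    column_info = [(f, s, t) for f in feats for s in STATS for t in tps]
    columns = [column_name(f, s, t) for f, s, t in column_info]

    marker_by_well = markers.set_index("well_id")
    rows, missing_rows, meta_rows, index = [], [], [], []
    for well in design.wells:
        wid = well.well_id
        if wid not in marker_by_well.index:
            raise KeyError(f"well {wid} has no marker values")
        # per-feature time series
        series: dict[tuple[str, str], list[float]] = {
            (f, s): [] for f in feats for s in STATS}
        for t in tps:
            agg = aggregates.get((wid, t))
            if agg is None:
                means, sds, cstats = ({}, {}, (float("nan"), float("nan")))
            else:
                means, sds, cstats = agg
            for f in FEATURE_NAMES:
                if f in feats:
                    series[(f, "mean")].append(means.get(f, float("nan")))
                    series[(f, "sd")].append(sds.get(f, float("nan")))
            if CELL_COUNT_FEATURE in feats:
                series[(CELL_COUNT_FEATURE, "mean")].append(cstats[0])
                series[(CELL_COUNT_FEATURE, "sd")].append(cstats[1])

        vec, miss = [], []
        n_missing_tp = sum(
            1 for t_idx in range(len(tps))
            if any(np.isnan(series[(f, s)][t_idx]) for f in feats for s in STATS))
        if len(tps) and n_missing_tp / len(tps) > max_missing_frac:
            raise ValueError(
                f"well {wid}: {n_missing_tp}/{len(tps)} timepoints missing exceeds "
                f"budget {max_missing_frac:.0%}")
        for f in feats:
            for s in STATS:
                ts = pd.Series(series[(f, s)], dtype=float)
                was_nan = ts.isna()
                if was_nan.any():
                    ts = ts.interpolate(limit_direction="both")
                    if ts.isna().any():
                        raise ValueError(
                            f"well {wid}: feature {f} {s} has no observed timepoints")
                vec.extend(ts.tolist())
                miss.extend(was_nan.tolist())
        rows.append(vec)
        missing_rows.append(miss)
        m = marker_by_well.loc[wid]
        meta_rows.append({
            "lot": well.lot, "passage": well.passage, "condition": well.condition,
            "alp_rate": float(m["alp_rate"]), "ca_rate": float(m["ca_rate"]),
        })
        index.append(wid)

    X = pd.DataFrame(rows, index=index, columns=columns)
    missing = pd.DataFrame(missing_rows, index=index, columns=columns)
    meta = pd.DataFrame(meta_rows, index=index)
    return FeatureMatrix(X=X, meta=meta, missing=missing, column_info=column_info,
                         interval_hours=design.config.interval_hours)


def delta_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each per-timepoint statistic by its successive change rate.

    Each feature/statistic time series of length T becomes T-1 forward
    differences divided by the inter-timepoint interval in hours, so the
    column count is 2 x features x (T-1).  Requires >= 2 retained
    timepoints.
    """
    tps = matrix.timepoints
    if len(tps) < 2:
        raise ValueError("delta transform requires at least 2 retained timepoints")
    dt = np.diff(np.array(tps, dtype=float)) * matrix.interval_hours
    new_cols, new_info, blocks, miss_blocks = [], [], [], []
    feats = matrix.features
    for f in feats:
        for s in STATS:
            cols = [column_name(f, s, t) for t in tps]
            vals = matrix.X[cols].to_numpy(float)
            deltas = np.diff(vals, axis=1) / dt[None, :]
            miss = matrix.missing[cols].to_numpy(bool)
            miss_d = miss[:, 1:] | miss[:, :-1]
            for j, t in enumerate(tps[1:]):
                new_cols.append(f"d_{column_name(f, s, t)}")
                new_info.append((f, s, t))
            blocks.append(deltas)
            miss_blocks.append(miss_d)
    X = pd.DataFrame(np.concatenate(blocks, axis=1), index=matrix.X.index,
                     columns=new_cols)
    missing = pd.DataFrame(np.concatenate(miss_blocks, axis=1),
                           index=matrix.X.index, columns=new_cols)
    return FeatureMatrix(X=X, meta=matrix.meta.copy(), missing=missing,
                         column_info=new_info, interval_hours=matrix.interval_hours)
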
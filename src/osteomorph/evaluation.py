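"""Evaluation indices, feature-elimination ablation, and per-timepoint
group comparisons.

Three indices summarize predictive accuracy:

* ``R`` — Pearson correlation of actual and predicted marker values;
* ``mean_abs_error`` — mean |actual − predicted|;
* ``standardized_error`` — mean squared prediction error divided by the
  population (ddof=0) variance of all experimentally determined values of
  that endpoint: 0 for perfect prediction, 1 for the constant
  mean-of-all-values predictor.  Note that on a held-out test set the
  value may exceed 1 (a near-mean-level prediction with extra error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["score", "PredictionReport", "ablate_features", "timepoint_group_test"]


def score(actual: Sequence[float], predicted: Sequence[float]
          ) -> tuple[float, float, float]:
    """(R, mean absolute error, standardized error) of a prediction set.

    R is undefined (NaN) when the actual values have zero variance; the
    standardized error divides by the population variance of ``actual``.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("score requires equal-length arrays with >= 2 entries")
    mae = float(np.abs(a - p).mean())
    var = float(a.var(ddof=0))
    if var == 0:
        return float("nan"), mae, float("nan")
    r = float(np.corrcoef(a, p)[0, 1]) if p.std() > 0 else float("nan")
    se = float(((a - p) ** 2).mean() / var)
    return r, mae, se


@dataclass
class PredictionReport:
    """Pooled predicted-vs-actual results for one (scheme, endpoint) run."""

    scheme: str
    endpoint: str
    per_sample: pd.DataFrame            # well_id, held_out_lot, actual, predicted
    r: float
    mean_abs_error: float
    standardized_error: float
    per_lot: pd.DataFrame               # lot-wise summaries
    lambdas: dict[int, float] = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, per_sample: pd.DataFrame, scheme: str, endpoint: str,
                         lambdas: Mapping[int, float] | None = None
                         ) -> "PredictionReport":
        r, mae, se = score(per_sample["actual"], per_sample["predicted"])
        lot_rows = []
        for lot, grp in per_sample.groupby("held_out_lot"):
            if len(grp) >= 2:
                lr, lmae, lse = score(grp["actual"], grp["predicted"])
            else:
                lr = lse = float("nan")
                lmae = float(np.abs(grp["actual"] - grp["predicted"]).mean())
            lot_rows.append({"held_out_lot": lot, "n": len(grp), "r": lr,
                             "mean_abs_error": lmae, "standardized_error": lse})
        return cls(scheme=scheme, endpoint=endpoint, per_sample=per_sample,
                   r=r, mean_abs_error=mae, standardized_error=se,
                   per_lot=pd.DataFrame(lot_rows), lambdas=dict(lambdas or {}))

    def summary(self) -> dict[str, float]:
        return {"scheme": self.scheme, "endpoint": self.endpoint,
                "n": len(self.per_sample), "r": self.r,
                "mean_abs_error": self.mean_abs_error,
                "standardized_error": self.standardized_error}


def ablate_features(matrix, scheme: str, endpoint: str,
                    feature_names: Sequence[str] | None = None,
                    lambda_grid: Sequence[float] | None = None,
                    pilot_passages: int = 1) -> pd.DataFrame:
    """Per-feature elimination: drop each feature's columns, rerun, score.

    Returns a table with one row per excluded feature (plus a baseline
    ``none`` row) and the three indices, mirroring the elimination analysis
    that shows no single morphometric feature dominates the prediction.
    Raises ``KeyError`` listing valid names for an unknown feature.
    """
    from .modeling import run_scenario  # local import to avoid cycle

    names = list(feature_names) if feature_names is not None else list(matrix.features)
    valid = set(matrix.features)
    for n in names:
        if n not in valid:
            raise KeyError(f"unknown feature {n!r}; valid features: {sorted(valid)}")
    if set(names) >= valid:
        raise ValueError("cannot ablate every feature: the matrix would be empty")
    rows = []
    base = run_scenario(matrix, scheme, endpoint, lambda_grid, pilot_passages)
    rows.append({"excluded_feature": "none", **{k: v for k, v in base.summary().items()
                                                if k not in ("scheme", "endpoint")}})
    for name in names:
        rep = run_scenario(matrix.drop_feature(name), scheme, endpoint,
                           lambda_grid, pilot_passages)
        rows.append({"excluded_feature": name,
                     **{k: v for k, v in rep.summary().items()
                        if k not in ("scheme", "endpoint")}})
    out = pd.DataFrame(rows)
    out.insert(0, "endpoint", endpoint)
    out.insert(0, "scheme", scheme)
    return out


def timepoint_group_test(well_means: pd.DataFrame, feature: str,
                         alpha: float = 0.01) -> pd.DataFrame:
    """Welch two-sample test of induction vs control per timepoint.

    ``well_means`` is a tidy table with columns (well_id, condition,
    timepoint, value-per-feature); the test compares well-level means of
    ``feature`` between the two conditions at each timepoint.  Returns a
    table with the Welch t statistic, raw p-value, a Bonferroni-adjusted
    p-value (multiplied by the number of timepoints tested) and a
    significance flag at ``alpha`` on the adjusted value.  Timepoints with
    fewer than 2 replicate wells in either group are flagged and not
    tested.
    """
    required = {"condition", "timepoint", feature}
    if not required <= set(well_means.columns):
        raise ValueError(f"well_means must contain columns {sorted(required)}")
    rows = []
    tps = sorted(well_means["timepoint"].unique())
    for t in tps:
        sub = well_means[well_means["timepoint"] == t]
        ind = sub.loc[sub["condition"] == "induction", feature].to_numpy(float)
        ctl = sub.loc[sub["condition"] == "control", feature].to_numpy(float)
        if len(ind) < 2 or len(ctl) < 2:
            rows.append({"timepoint": t, "n_induction": len(ind), "n_control": len(ctl),
                         "t_stat": float("nan"), "p_value": float("nan"),
                         "p_bonferroni": float("nan"), "significant": False,
                         "tested": False})
            continue
        res = stats.ttest_ind(ind, ctl, equal_var=False)
        p_adj = min(float(res.pvalue) * len(tps), 1.0)
        rows.append({"timepoint": t, "n_induction": len(ind), "n_control": len(ctl),
                     "t_stat": float(res.statistic), "p_value": float(res.pvalue),
                     "p_bonferroni": p_adj, "significant": bool(p_adj < alpha),
                     "tested": True})
    out = pd.DataFrame(rows)
    out.insert(0, "feature", feature)
    return out
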
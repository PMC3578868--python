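"""Ridge regression of terminal markers on time-series morphology, with the
two clinical transfer scenarios.

The estimator minimizes ||y - Z b - c||^2 + lambda ||b||^2 where Z is the
column-standardized design (training-set means/SDs) and the intercept c is
unpenalized.  With p >> n (666+ columns, <= 54 wells) the solution is
computed in the dual / Gram form: b = Z' (Z Z' + lambda I)^{-1} y_c.  The
penalty is selected by leave-one-out cross-validation over a log-spaced
grid, on the training rows only.

Transfer scenarios (one donor lot = one "patient"):

* ``new_patient`` — train on all samples of the other lots, predict every
  sample of the held-out lot (canonical design: 36 train / 18 test).
* ``ongoing_patient`` — additionally move the held-out lot's first
  ``pilot_passages`` passages into training (pilot culture data), predict
  the remaining passages (canonical, 1 pilot passage: 42 train / 12 test).

``run_scenario`` loops every lot as the held-out patient, selects lambda
and fits on each training set, and pools the held-out predictions into a
single report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_table import FeatureMatrix
from . import evaluation

__all__ = [
    "RidgeModel", "ScenarioSplit", "fit_ridge", "select_lambda",
    "make_split", "run_scenario", "ENDPOINTS", "SCHEMES",
]

ENDPOINTS = {"D14_ALP": "alp_rate", "D21_Ca": "ca_rate"}
SCHEMES = ("new_patient", "ongoing_patient")


@dataclass
class RidgeModel:
    """Fitted ridge model in standardized-column space."""

    coefficients: np.ndarray        # beta per retained (non-constant) column
    intercept: float
    lam: float
    column_means: np.ndarray
    column_sds: np.ndarray
    kept_columns: np.ndarray        # indices of non-constant columns
    columns: tuple[str, ...]        # original column names
    endpoint: str = ""

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.kept_columns] - self.column_means) / self.column_sds
        return self.intercept + Z @ self.coefficients

    def coefficient_norm(self) -> float:
        return float(np.linalg.norm(self.coefficients))

    def to_json(self, path: str | Path) -> None:
        d = {
            "endpoint": self.endpoint,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "columns": list(self.columns),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "RidgeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.array(d["coefficients"], float),
            intercept=float(d["intercept"]), lam=float(d["lambda"]),
            column_means=np.array(d["column_means"], float),
            column_sds=np.array(d["column_sds"], float),
            kept_columns=np.array(d["kept_columns"], int),
            columns=tuple(d["columns"]), endpoint=d.get("endpoint", ""),
        )


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = np.flatnonzero(sd > 0)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, mu[keep], sd[keep], keep


def _solve_ridge(Z: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    n, p = Z.shape
    if lam == 0:
        beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        return beta
    if p > n:
        K = Z @ Z.T
        alpha = np.linalg.solve(K + lam * np.eye(n), yc)
        return Z.T @ alpha
    A = Z.T @ Z + lam * np.eye(p)
    return np.linalg.solve(A, Z.T @ yc)


def fit_ridge(X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series, lam: float,
              *, columns: Sequence[str] | None = None, endpoint: str = "") -> RidgeModel:
    """Closed-form ridge fit with unpenalized intercept.

    Columns are standardized with the training statistics; constant columns
    are dropped (recorded via ``kept_columns``).  ``lam`` must be >= 0;
    a constant target yields beta = 0 with intercept = mean(y).
    """
    if lam < 0:
        raise ValueError("ridge penalty lambda must be >= 0")
    if isinstance(X, pd.DataFrame):
        columns = columns or tuple(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_ridge requires a 2-D X with >= 2 samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("fit_ridge requires complete (non-NaN) inputs")
    Z, mu, sd, keep = _standardize_train(X)
    ybar = float(y.mean())
    yc = y - ybar
    beta = _solve_ridge(Z, yc, lam) if yc.any() else np.zeros(Z.shape[1])
    cols = tuple(columns) if columns is not None else tuple(f"x{i}" for i in range(X.shape[1]))
    return RidgeModel(coefficients=beta, intercept=ybar, lam=float(lam),
                      column_means=mu, column_sds=sd, kept_columns=keep,
                      columns=cols, endpoint=endpoint)


def loocv_mse(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Leave-one-out mean squared prediction error for one penalty.

    Standardization uses the statistics of the full set handed in (the
    lambda-selection training set); each fold then refits the ridge
    solution on the remaining rows via the Gram matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    Z, *_ = _standardize_train(X)
    ybar_all = y.mean()
    K = Z @ Z.T
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        ybar = ytr.mean()
        yc = ytr - ybar
        Ktr = K[np.ix_(tr, tr)]
        if lam == 0:
            beta, *_ = np.linalg.lstsq(Z[tr], yc, rcond=None)
            pred = ybar + Z[i] @ beta
        else:
            alpha = np.linalg.solve(Ktr + lam * np.eye(n - 1), yc)
            pred = ybar + K[i, tr] @ alpha
        errs[i] = (y[i] - pred) ** 2
    return float(errs.mean())


def select_lambda(X: np.ndarray | pd.DataFrame, y: np.ndarray | pd.Series,
                  grid: Sequence[float]) -> float:
    """Grid lambda minimizing LOOCV MSE on the given (training) rows.

    Ties break toward the larger lambda (more regularization).  Requires at
    least 3 samples and a non-empty grid.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("lambda selection requires at least 3 samples")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    best_lam, best_mse = grid[0], np.inf
    for lam in grid:
        mse = loocv_mse(X, y, lam)
        if mse <= best_mse:  # <= so ties prefer the larger lambda
            best_lam, best_mse = lam, mse
    return best_lam


@dataclass(frozen=True)
class ScenarioSplit:
    scheme: str
    held_out_lot: int
    pilot_passages: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def make_split(matrix: FeatureMatrix, scheme: str, held_out_lot: int,
               pilot_passages: int = 1) -> ScenarioSplit:
    """Build the train/test id lists for one held-out lot.

    ``new_patient``: test = all samples of the held-out lot.
    ``ongoing_patient``: the held-out lot's lowest ``pilot_passages``
    passages move into training; the rest are the test set.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    meta = matrix.meta
    lots = sorted(meta["lot"].unique())
    if held_out_lot not in lots:
        raise ValueError(f"held-out lot {held_out_lot} not present (lots: {lots})")
    if len(lots) < 2:
        raise ValueError("transfer scenarios require at least 2 lots")
    in_lot = meta["lot"] == held_out_lot
    if scheme == "new_patient":
        pilot_passages = 0
    passages = sorted(meta.loc[in_lot, "passage"].unique())
    if pilot_passages >= len(passages):
        raise ValueError(
            f"pilot_passages={pilot_passages} must be < passages per lot ({len(passages)})")
    pilot = set(passages[:pilot_passages])
    is_pilot = in_lot & meta["passage"].isin(pilot)
    train = meta.index[~in_lot | is_pilot]
    test = meta.index[in_lot & ~meta["passage"].isin(pilot)]
    return ScenarioSplit(scheme=scheme, held_out_lot=int(held_out_lot),
                         pilot_passages=int(pilot_passages),
                         train_ids=tuple(train), test_ids=tuple(test))


def run_scenario(matrix: FeatureMatrix, scheme: str, endpoint: str,
                 lambda_grid: Sequence[float] | None = None,
                 pilot_passages: int = 1) -> "evaluation.PredictionReport":
    """Evaluate one endpoint under one transfer scheme.

    Every lot takes a turn as the held-out patient: lambda is selected by
    LOOCV on that training set, the model is fitted and the held-out
    samples predicted.  Predictions pooled over all held-out lots form the
    report (per-lot summaries included).  Test rows never touch scaling,
    lambda selection or fitting.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {list(ENDPOINTS)}")
    grid = tuple(lambda_grid) if lambda_grid is not None else tuple(np.logspace(-3, 4, 15))
    ycol = ENDPOINTS[endpoint]
    records = []
    lam_by_lot = {}
    for lot in sorted(matrix.meta["lot"].unique()):
        split = make_split(matrix, scheme, lot, pilot_passages)
        Xtr = matrix.X.loc[list(split.train_ids)]
        ytr = matrix.meta.loc[list(split.train_ids), ycol]
        Xte = matrix.X.loc[list(split.test_ids)]
        yte = matrix.meta.loc[list(split.test_ids), ycol]
        lam = select_lambda(Xtr, ytr, grid)
        model = fit_ridge(Xtr, ytr, lam, endpoint=endpoint)
        pred = model.predict(Xte)
        lam_by_lot[int(lot)] = lam
        for wid, a, p in zip(split.test_ids, yte.to_numpy(float), pred):
            records.append({"well_id": wid, "held_out_lot": int(lot),
                            "actual": float(a), "predicted": float(p)})
    per_sample = pd.DataFrame(records)
    return evaluation.PredictionReport.from_predictions(
        per_sample, scheme=scheme, endpoint=endpoint, lambdas=lam_by_lot)
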
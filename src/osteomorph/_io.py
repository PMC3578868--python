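"""Round-trip helpers for on-disk feature matrices."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .feature_table import FeatureMatrix

META_COLUMNS = ("lot", "passage", "condition", "alp_rate", "ca_rate")


def read_feature_matrix(matrix_csv: str | Path, columns_json: str | Path
                        ) -> FeatureMatrix:
    """Load a feature matrix written by the pipeline (CSV + column dict)."""
    merged = pd.read_csv(matrix_csv, index_col="well_id")
    col_dict = json.loads(Path(columns_json).read_text())
    feature_cols = [c["column"] for c in col_dict]
    column_info = [(c["feature"], c["stat"], int(c["timepoint"])) for c in col_dict]
    X = merged[feature_cols].astype(float)
    meta = merged[list(META_COLUMNS)]
    missing = pd.DataFrame(False, index=X.index, columns=X.columns)
    return FeatureMatrix(X=X, meta=meta, missing=missing, column_info=column_info)
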
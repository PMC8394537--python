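"""Feature-table reading and writing.

Feature tables are CSV files with an ``image_id`` column, an optional
``label`` column, and the 30 canonical descriptor columns in their fixed
order.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .descriptors import FEATURE_NAMES, TopoFeatureVector

__all__ = ["SchemaError", "feature_frame", "write_features", "read_features"]


class SchemaError(ValueError):
    """A tabular input does not carry the expected columns."""


def feature_frame(
    vectors: "list[TopoFeatureVector]",
    ids: "list[str]",
    labels: "list[str] | None" = None,
) -> pd.DataFrame:
    """Assemble feature vectors into the canonical table layout."""
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=list(FEATURE_NAMES)
    )
    df.insert(0, "image_id", ids)
    if labels is not None:
        df.insert(1, "label", labels)
    return df


def write_features(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def read_features(
    path: str | os.PathLike,
) -> tuple[list[str], np.ndarray, "list[str] | None"]:
    """Load a feature table; returns (image ids, matrix, labels or None)."""
    df = pd.read_csv(path)
    missing = [c for c in ("image_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table {path} lacks columns: {missing}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return df["image_id"].astype(str).tolist(), X, labels
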
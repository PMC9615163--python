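"""Surface-protein (antibody-tag) count normalization and marker calls.

Tag counts are compositional per cell, so they are normalized by a centered
log-ratio: y_j = ln(1 + x_j) - mean_k ln(1 + x_k) within each cell.  Marker
positivity is called by thresholding the CLR value (default cutoff 1,
strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["clr_normalize", "binarize_protein", "cluster_marker_summary"]


def clr_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio of 1 + count per cell (rows sum to zero)."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one antibody tag")
    if counts.to_numpy().min() < 0:
        raise ValueError("counts must be non-negative")
    logs = np.log1p(counts.to_numpy(dtype=float))
    return pd.DataFrame(logs - logs.mean(axis=1, keepdims=True),
                        index=counts.index, columns=counts.columns)


def binarize_protein(clr: pd.DataFrame, cutoff: float = 1.0) -> pd.DataFrame:
    """Marker-positive iff CLR value is strictly above the cutoff."""
    return (clr > cutoff).astype(np.int8)


def cluster_marker_summary(clr: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Per-cluster mean +/- 2 SE for every tag (SE = sd / sqrt(n), ddof 1).

    Singleton clusters get NaN SE and a flag.
    """
    clusters = pd.Series(clusters).reindex(clr.index)
    if clusters.isna().any():
        raise ValueError("every cell needs a cluster label")
    rows = []
    for c, block in clr.groupby(clusters):
        n = len(block)
        for tag in clr.columns:
            v = block[tag].to_numpy(dtype=float)
            se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({"cluster": c, "tag": tag, "mean": float(v.mean()),
                         "se": se, "n": n, "singleton": n == 1})
    out = pd.DataFrame(rows)
    out["ci_low"] = out["mean"] - 2 * out["se"]
    out["ci_high"] = out["mean"] + 2 * out["se"]
    return out
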
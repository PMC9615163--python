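"""Per-amplicon false-negative and false-positive rate estimation.

The undigested control library measures pure technical dropout: for an
amplicon the FNR ``p_i`` is the fraction of called cells with zero reads.
The digested library on constitutively *unmethylated* amplicons measures
digestion failure: the FPR is the fraction of called cells with at least one
read where complete digestion would have produced none.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CountMatrix

__all__ = [
    "estimate_fnr",
    "estimate_fpr",
    "lower_median",
    "select_high_performance",
    "control_sample_correlation",
    "gc_fnr_diagnostic",
    "error_rate_table",
]


def lower_median(values) -> float:
    """Median taking the lower of the two central order statistics for even n."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    return float(v[(v.size - 1) // 2])


def estimate_fnr(
    undigested: CountMatrix,
    amplicon_classes: pd.Series,
    target_classes=("bcell",),
) -> pd.DataFrame:
    """FNR per amplicon of the target classes from the undigested control.

    ``p_i`` = #cells with zero reads / #cells.  The matrix must already be
    restricted to called cells.
    """
    if undigested.condition != "undigested":
        raise ValueError("FNR must be estimated from the undigested control")
    n = undigested.shape[0]
    if n < 1:
        raise ValueError("need at least one called cell")
    classes = pd.Series(amplicon_classes)
    keep = [a for a in undigested.amplicons if classes.get(a) in set(target_classes)]
    sub = undigested.subset_amplicons(keep)
    fnr = (sub.counts == 0).mean(axis=0)
    return pd.DataFrame(
        {"amplicon_id": keep, "class": [classes[a] for a in keep],
         "fnr": fnr, "n_cells": n}
    ).set_index("amplicon_id")


def estimate_fpr(digested: CountMatrix, const_unmeth_ids) -> tuple[pd.DataFrame, float]:
    """FPR per constitutively unmethylated amplicon from the digested sample.

    Returns (per-amplicon table, lower-median across amplicons).
    """
    if digested.condition != "digested":
        raise ValueError("FPR must be estimated from a digested sample")
    ids = list(const_unmeth_ids)
    if not ids:
        raise ValueError("need at least one constitutively unmethylated amplicon")
    n = digested.shape[0]
    if n < 1:
        raise ValueError("need at least one called cell")
    sub = digested.subset_amplicons(ids)
    fpr = (sub.counts >= 1).mean(axis=0)
    table = pd.DataFrame({"amplicon_id": ids, "fpr": fpr, "n_cells": n}).set_index("amplicon_id")
    return table, lower_median(fpr)


def select_high_performance(fnr_table: pd.DataFrame, max_fnr: float = 0.25) -> list[str]:
    """Amplicons with FNR strictly below ``max_fnr``."""
    if fnr_table.empty:
        raise ValueError("empty FNR table")
    return list(fnr_table.index[fnr_table["fnr"] < max_fnr])


def control_sample_correlation(
    sample_a: CountMatrix,
    sample_b: CountMatrix,
    amplicon_classes: pd.Series,
    control_classes=("non_hha", "const_meth"),
) -> float:
    """Pearson correlation of per-amplicon detection fractions on controls.

    Used to check that an undigested control library is a faithful reference
    for a digested sample: on amplicons unaffected by digestion (no
    recognition site, or constitutively methylated) their detection profiles
    should agree.
    """
    classes = pd.Series(amplicon_classes)
    shared = [a for a in sample_a.amplicons
              if a in set(sample_b.amplicons) and classes.get(a) in set(control_classes)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared control amplicons")
    fa = sample_a.subset_amplicons(shared).detection_fraction()
    fb = sample_b.subset_amplicons(shared).detection_fraction()
    return float(stats.pearsonr(fa, fb).statistic)


def gc_fnr_diagnostic(fnr_table: pd.DataFrame, gc: pd.Series, gc_max: float = 0.65) -> dict:
    """Flag GC-rich amplicons and quantify the GC-dropout relationship.

    High GC amplifies poorly, inflating dropout; amplicons above ``gc_max``
    are flagged for exclusion and the Spearman correlation between GC and
    FNR is reported.
    """
    gc = pd.Series(gc).reindex(fnr_table.index)
    if gc.isna().any():
        raise ValueError("gc missing for some amplicons")
    flags = gc > gc_max
    rho = np.nan
    if len(fnr_table) >= 3 and fnr_table["fnr"].nunique() > 1 and gc.nunique() > 1:
        rho = float(stats.spearmanr(gc, fnr_table["fnr"]).statistic)
    return {"flagged": list(fnr_table.index[flags]), "spearman_gc_fnr": rho}


def error_rate_table(
    fnr_table: pd.DataFrame,
    fpr_table: pd.DataFrame | None = None,
    gc: pd.Series | None = None,
    max_fnr: float = 0.25,
) -> pd.DataFrame:
    """Merge FNR/FPR estimates into one per-amplicon table with the
    high-performance flag (FNR < ``max_fnr``)."""
    out = fnr_table.copy()
    out["fpr"] = np.nan
    if fpr_table is not None:
        fpr_rows = fpr_table.copy()
        fpr_rows["class"] = "const_unmeth"
        fpr_rows["fnr"] = np.nan
        out = pd.concat([out, fpr_rows.reindex(columns=out.columns.union(["fpr"]))])
        out.loc[fpr_table.index, "fpr"] = fpr_table["fpr"]
    out["gc"] = pd.Series(gc).reindex(out.index) if gc is not None else np.nan
    out["high_performance"] = out["fnr"] < max_fnr
    return out
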
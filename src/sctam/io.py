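"""Plain-text I/O: panel CSV/BED, count matrices, TSV round trips.

Coordinates are 0-based half-open internally and in BED output; MatrixMarket
files use the standard 1-based coordinate format via scipy.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import CountMatrix

__all__ = ["PANEL_COLUMNS", "read_panel", "write_panel", "write_panel_bed",
           "read_counts", "write_counts", "write_tsv", "read_tsv"]

PANEL_COLUMNS = ["amplicon_id", "chrom", "start", "end", "site_pos", "cpg_id", "class", "gc"]
PANEL_CLASSES = {"bcell", "const_meth", "const_unmeth", "imprint", "non_hha"}


def read_panel(path) -> pd.DataFrame:
    """Read an amplicon panel CSV (validated columns, 0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    panel = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel {path} missing columns: {sorted(missing)}")
    bad = set(panel["class"]) - PANEL_CLASSES
    if bad:
        raise ValueError(f"unknown amplicon classes: {sorted(bad)}")
    if (panel["end"] <= panel["start"]).any():
        raise ValueError("panel intervals must satisfy start < end (0-based half-open)")
    return panel.set_index("amplicon_id", drop=False)


def write_panel(panel: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.reset_index(drop=True)[PANEL_COLUMNS].to_csv(path, index=False)
    return path


def write_panel_bed(panel: pd.DataFrame, path) -> Path:
    """BED6: name = amplicon_id, score = round(1000 * gc), strand '.'."""
    path = Path(path)
    bed = pd.DataFrame({
        "chrom": panel["chrom"], "start": panel["start"].astype(int),
        "end": panel["end"].astype(int), "name": panel["amplicon_id"],
        "score": (1000 * panel["gc"]).round().astype(int), "strand": ".",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
    return path


def read_counts(prefix, condition: str | None = None) -> CountMatrix:
    return CountMatrix.read(prefix, condition)


def write_counts(matrix: CountMatrix, prefix) -> dict:
    return matrix.write(prefix)


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)
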
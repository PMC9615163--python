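"""Barcode x amplicon read-count matrices and their on-disk MatrixMarket form."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Non-negative integer read counts for barcodes (rows) x amplicons (columns).

    ``condition`` records whether the library was processed with the
    methylation-sensitive enzyme ("digested") or without ("undigested").
    """

    barcodes: list[str]
    amplicons: list[str]
    counts: np.ndarray  # dense int array, shape (n_barcodes, n_amplicons)
    condition: str = "digested"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.amplicons)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.barcodes)} barcodes x {len(self.amplicons)} amplicons"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.condition not in ("digested", "undigested"):
            raise ValueError("condition must be 'digested' or 'undigested'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.barcodes, columns=self.amplicons)

    def subset_amplicons(self, ids) -> "CountMatrix":
        ids = list(ids)
        unknown = set(ids) - set(self.amplicons)
        if unknown:
            raise ValueError(f"unknown amplicon ids: {sorted(unknown)}")
        idx = [self.amplicons.index(a) for a in ids]
        return CountMatrix(list(self.barcodes), ids, self.counts[:, idx], self.condition)

    def subset_barcodes(self, ids) -> "CountMatrix":
        ids = list(ids)
        unknown = set(ids) - set(self.barcodes)
        if unknown:
            raise ValueError(f"unknown barcodes: {sorted(unknown)}")
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in ids]
        return CountMatrix(ids, list(self.amplicons), self.counts[idx, :], self.condition)

    def detection_fraction(self) -> pd.Series:
        """Per-amplicon fraction of barcodes with at least one read."""
        if not self.barcodes:
            raise ValueError("no barcodes")
        return pd.Series((self.counts >= 1).mean(axis=0), index=self.amplicons)

    # ---- MatrixMarket + TSV sidecars -------------------------------------

    def write(self, prefix) -> dict[str, Path]:
        """Write ``<prefix>.mtx`` plus barcode/amplicon TSV sidecars.

        The MTX holds the sparse counts (1-based coordinate format, barcodes
        as rows); sidecars carry the row/column ids and the condition tag.
        Round-trips losslessly through :meth:`read`.
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "mtx": prefix.with_suffix(".mtx"),
            "barcodes": Path(str(prefix) + ".barcodes.tsv"),
            "amplicons": Path(str(prefix) + ".amplicons.tsv"),
        }
        coo = sp.coo_matrix(self.counts)
        scipy.io.mmwrite(
            paths["mtx"], coo, field="integer", comment=f"condition: {self.condition}"
        )
        paths["barcodes"].write_text("".join(f"{b}\n" for b in self.barcodes))
        paths["amplicons"].write_text("".join(f"{a}\n" for a in self.amplicons))
        return paths

    @classmethod
    def read(cls, prefix, condition: str | None = None) -> "CountMatrix":
        prefix = Path(prefix)
        mtx = prefix.with_suffix(".mtx")
        try:
            mat = scipy.io.mmread(mtx)
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read MatrixMarket file {mtx}: {exc}") from exc
        if condition is None:
            condition = "digested"
            for line in mtx.read_text().splitlines():
                if line.startswith("%") and "condition:" in line:
                    condition = line.split("condition:")[1].strip()
                    break
                if not line.startswith("%"):
                    break
        barcodes = Path(str(prefix) + ".barcodes.tsv").read_text().split()
        amplicons = Path(str(prefix) + ".amplicons.tsv").read_text().split()
        counts = np.asarray(sp.coo_matrix(mat).todense()).astype(np.int64)
        return cls(barcodes, amplicons, counts, condition)
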
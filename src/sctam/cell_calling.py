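"""Distinguish cells from empty droplets using non-HhaI control amplicons.

Control amplicons without a recognition site amplify regardless of
methylation and digestion, so their read counts depend only on whether a
barcode contained a cell.  A barcode is called a cell when it has more than
a data-derived read threshold in at least 70% of the control amplicons; the
threshold is min(10, 0.2 x the average per-amplicon read count among
well-covered barcodes), where "well-covered" means total reads of at least
eight times the number of amplicons in the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["CellCallingParams", "NoQualifyingBarcodesError",
           "compute_read_threshold", "call_cells", "call_cells_table"]


class NoQualifyingBarcodesError(RuntimeError):
    """No barcode reaches the coverage floor used to estimate the threshold."""


@dataclass(frozen=True)
class CellCallingParams:
    min_coverage_multiple: int = 8
    threshold_cap: float = 10.0
    threshold_fraction: float = 0.2
    amplicon_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.min_coverage_multiple <= 0 or self.threshold_cap <= 0:
            raise ValueError("min_coverage_multiple and threshold_cap must be positive")
        if not 0 < self.threshold_fraction <= 1 or not 0 < self.amplicon_fraction <= 1:
            raise ValueError("fractions must lie in (0, 1]")


def compute_read_threshold(
    counts: CountMatrix,
    params: CellCallingParams = CellCallingParams(),
    n_panel_amplicons: int | None = None,
    panel_totals: np.ndarray | None = None,
) -> float:
    """Per-amplicon read threshold from well-covered barcodes.

    ``counts`` must already be restricted to the non-HhaI control amplicons.
    The coverage floor uses the *full* panel: a barcode qualifies when its
    whole-panel total (``panel_totals``, defaulting to the totals of the
    given matrix) reaches ``min_coverage_multiple * n_panel_amplicons``.
    The average is then the mean per-amplicon read count of the qualifying
    barcodes on the control amplicons,
    ``total control reads of Q / (|Q| * n_control_amplicons)``.
    """
    if counts.shape[0] < 1 or counts.shape[1] < 1:
        raise ValueError("need at least one barcode and one control amplicon")
    if n_panel_amplicons is None:
        n_panel_amplicons = counts.shape[1]
    totals = counts.counts.sum(axis=1)
    cover = totals if panel_totals is None else np.asarray(panel_totals)
    if cover.shape != totals.shape:
        raise ValueError("panel_totals must have one entry per barcode")
    floor = params.min_coverage_multiple * n_panel_amplicons
    q = cover >= floor
    if not q.any():
        raise NoQualifyingBarcodesError(
            f"no barcode has >= {floor} total reads ({params.min_coverage_multiple}x "
            f"{n_panel_amplicons} panel amplicons)"
        )
    avg = totals[q].sum() / (q.sum() * counts.shape[1])
    return float(min(params.threshold_cap, params.threshold_fraction * avg))


def call_cells(
    counts: CountMatrix,
    threshold: float,
    params: CellCallingParams = CellCallingParams(),
) -> list[str]:
    """Barcodes with count > ``threshold`` (strict) in >= ``amplicon_fraction``
    of the control amplicons (ties at the fraction count)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    frac = (counts.counts > threshold).mean(axis=1)
    keep = frac >= params.amplicon_fraction
    return [b for b, k in zip(counts.barcodes, keep) if k]


def call_cells_table(
    counts: CountMatrix,
    control_amplicons,
    params: CellCallingParams = CellCallingParams(),
    n_panel_amplicons: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Full cell-calling pass on a complete matrix.

    Returns (per-barcode table with is_cell / fraction_detected / total_reads /
    doublet placeholder column, computed threshold).  ``n_panel_amplicons``
    defaults to the full matrix width.
    """
    if n_panel_amplicons is None:
        n_panel_amplicons = counts.shape[1]
    ctl = counts.subset_amplicons(control_amplicons)
    threshold = compute_read_threshold(
        ctl, params, n_panel_amplicons, panel_totals=counts.counts.sum(axis=1)
    )
    cells = set(call_cells(ctl, threshold, params))
    table = pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "is_cell": [b in cells for b in counts.barcodes],
            "fraction_detected": (ctl.counts > threshold).mean(axis=1),
            "total_reads": counts.counts.sum(axis=1),
            "doublet_flag": "",  # filled by external doublet annotation
        }
    ).set_index("barcode")
    return table, threshold
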
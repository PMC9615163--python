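"""End-to-end pipeline driver: cell calling -> error rates -> binarize ->
cluster -> pseudobulk, with plain-text stage artifacts and a JSON manifest.

Each stage writes its outputs before the next starts, so a failed run keeps
the partial artifacts and any stage can be re-run from its predecessor's
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_calling import CellCallingParams, call_cells_table
from .error_model import error_rate_table, estimate_fnr, estimate_fpr, select_high_performance
from .io import read_counts, read_panel, write_tsv
from .matrix import CountMatrix
from .methylation import binarize, cluster_cells
from .pseudobulk import PseudobulkModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("sctam")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and parameters for a full run.

    ``digested``/``undigested`` are MTX prefixes; ``panel`` a panel CSV.
    """

    digested: str
    undigested: str
    panel: str
    outdir: str
    n_clusters: int = 3
    max_fnr: float = 0.25
    target_class: str = "bcell"
    cell_calling: CellCallingParams = field(default_factory=CellCallingParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cc = raw.pop("cell_calling", None)
        cfg = cls(**raw)
        if cc:
            cfg.cell_calling = CellCallingParams(**cc)
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="[sctam:%(levelname)s] %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_clusters": config.n_clusters, "max_fnr": config.max_fnr,
            "target_class": config.target_class,
        },
        "inputs": {}, "stages": [],
    }
    for name in ("panel",):
        p = Path(getattr(config, name))
        if not p.exists():
            raise PipelineError("load", f"missing input file: {p}")
        manifest["inputs"][name] = {"path": str(p), "sha256": _hash_file(p)}

    stage = "load"
    try:
        panel = read_panel(config.panel)
        digested = read_counts(config.digested, "digested")
        undigested = read_counts(config.undigested, "undigested")
        classes = panel["class"]

        stage = "cell_calling"
        logger.info("cell calling on %d barcodes", digested.shape[0])
        controls = list(panel.index[panel["class"] == "non_hha"])
        dig_cells, dig_thr = call_cells_table(digested, controls, config.cell_calling)
        undig_cells, undig_thr = call_cells_table(undigested, controls, config.cell_calling)
        write_tsv(dig_cells, out / "cells_digested.tsv")
        write_tsv(undig_cells, out / "cells_undigested.tsv")
        (out / "cell_calling.json").write_text(json.dumps(
            {"threshold_digested": dig_thr, "threshold_undigested": undig_thr,
             "n_cells_digested": int(dig_cells["is_cell"].sum()),
             "n_cells_undigested": int(undig_cells["is_cell"].sum())}, indent=2))
        manifest["stages"].append("cell_calling")

        stage = "error_rates"
        dig_called = digested.subset_barcodes(
            list(dig_cells.index[dig_cells["is_cell"]]))
        undig_called = undigested.subset_barcodes(
            list(undig_cells.index[undig_cells["is_cell"]]))
        fnr = estimate_fnr(undig_called, classes, target_classes=(config.target_class,))
        cu = list(panel.index[panel["class"] == "const_unmeth"])
        fpr_tab, fpr_median = (estimate_fpr(dig_called, cu) if cu else (None, float("nan")))
        errors = error_rate_table(fnr, fpr_tab, gc=panel["gc"], max_fnr=config.max_fnr)
        write_tsv(errors, out / "error_rates.tsv")
        (out / "error_rates.json").write_text(json.dumps(
            {"median_fnr": float(np.median(fnr["fnr"])), "median_fpr": float(fpr_median),
             "n_high_performance": int(errors["high_performance"].sum())}, indent=2))
        manifest["stages"].append("error_rates")

        stage = "binarize"
        keep = select_high_performance(fnr, config.max_fnr)
        if not keep:
            raise ValueError("no amplicon passes the FNR filter")
        binary = binarize(dig_called, keep)
        write_tsv(binary.calls, out / "binary_matrix.tsv")
        manifest["stages"].append("binarize")

        stage = "cluster"
        k = min(config.n_clusters, len(binary.cells))
        assign = cluster_cells(binary, k)
        write_tsv(assign.labels.rename("cluster").to_frame(), out / "clusters.tsv")
        manifest["stages"].append("cluster")

        stage = "pseudobulk"
        model = PseudobulkModel(binary, assign, fnr)
        results = model.fit(seed=config.seed)
        write_tsv(results.summary(), out / "pseudobulk.tsv", index=False)
        manifest["stages"].append("pseudobulk")
    except Exception as exc:  # keep partial artifacts; name the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return manifest
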
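"""Synthetic digested/undigested single-cell methylation count matrices.

The generative model mirrors the error structure of droplet-based targeted
methylation sequencing with a methylation-sensitive enzyme:

* each cell of type ``t`` carries, per amplicon ``i``, a methylation state
  ``M ~ Bernoulli(profile[i, t])`` (or two alleles combined by OR in allelic
  mode);
* in the *undigested* library an amplicon is captured with probability
  ``1 - d_i`` regardless of methylation — ``d_i`` is pure technical dropout,
  i.e. the per-amplicon false-negative rate;
* in the *digested* library an unmethylated site is cut and only amplifies
  on digestion failure (probability ``digestion_fpr``), so capture has
  probability ``(1 - d_i) * (M + (1 - M) * digestion_fpr)``;
* a captured amplicon yields ``1 + Poisson(mean_reads - 1)`` reads, so
  presence and "at least one read" coincide;
* empty droplets draw a small Poisson background per amplicon, and doublet
  barcodes are element-wise maxima of two cells' count vectors.

Constitutively methylated / unmethylated control amplicons are pinned to
profile 1 / 0, and non-HhaI control amplicons (no recognition site, hence
never digested) behave like the undigested model in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_experiment"]

CLASS_BCELL = "bcell"
CLASS_NON_HHA = "non_hha"
CLASS_CONST_METH = "const_meth"
CLASS_CONST_UNMETH = "const_unmeth"


@dataclass
class SimConfig:
    """Ground-truth configuration of a simulated experiment.

    ``cell_type_profiles`` is an amplicon x cell-type DataFrame of methylation
    probabilities; ``amplicon_classes`` labels each amplicon (const_meth rows
    must be 1, const_unmeth rows 0; non_hha amplicons ignore digestion).
    ``dropout`` is the per-amplicon capture-failure probability ``d_i``.
    """

    n_cells: dict[str, int]
    cell_type_profiles: pd.DataFrame
    amplicon_classes: pd.Series
    dropout: pd.Series
    digestion_fpr: float = 0.002
    allelic_mode: bool = False
    mean_reads: float = 40.0
    n_empty_droplets: int = 0
    empty_mean_reads: float = 0.2
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        prof = self.cell_type_profiles
        self.amplicon_classes = pd.Series(self.amplicon_classes).reindex(prof.index)
        self.dropout = pd.Series(self.dropout).reindex(prof.index).astype(float)
        if self.amplicon_classes.isna().any() or self.dropout.isna().any():
            raise ValueError("amplicon_classes and dropout must cover every profile row")
        p = prof.to_numpy(dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("profiles must lie in [0, 1]")
        d = self.dropout.to_numpy()
        if d.size and (d.min() < 0 or d.max() > 1):
            raise ValueError("dropout must lie in [0, 1]")
        if not 0 <= self.digestion_fpr <= 1:
            raise ValueError("digestion_fpr must lie in [0, 1]")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must lie in [0, 1]")
        if self.mean_reads < 1:
            raise ValueError("mean_reads must be >= 1 (one read marks presence)")
        cm = self.amplicon_classes == CLASS_CONST_METH
        cu = self.amplicon_classes == CLASS_CONST_UNMETH
        if cm.any() and not np.allclose(p[cm.to_numpy()], 1.0):
            raise ValueError("const_meth amplicon profiles must be 1")
        if cu.any() and not np.allclose(p[cu.to_numpy()], 0.0):
            raise ValueError("const_unmeth amplicon profiles must be 0")
        missing = set(self.n_cells) - set(prof.columns)
        if missing:
            raise ValueError(f"n_cells names unknown cell types: {sorted(missing)}")


@dataclass
class SimTruth:
    """Ground truth for a simulated run: barcode annotations, methylation
    states and the realized per-amplicon error rates."""

    barcode_table: pd.DataFrame  # index barcode; cell_type, is_doublet, is_empty
    methylation: pd.DataFrame    # cells x amplicons, {0,1} (doublets: OR of parents)
    realized_fnr: pd.Series      # undigested capture failure per amplicon, real cells
    realized_fpr: pd.Series      # digested detection per const_unmeth amplicon

    @property
    def cell_types(self) -> pd.Series:
        tab = self.barcode_table
        mask = ~(tab["is_doublet"] | tab["is_empty"])
        return tab.loc[mask, "cell_type"]


def _reads_given_present(rng, present: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Shifted Poisson: >=1 read wherever present, 0 otherwise."""
    reads = 1 + rng.poisson(np.broadcast_to(lam - 1.0, present.shape))
    return np.where(present, reads, 0).astype(np.int64)


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Simulate a paired digested/undigested experiment.

    Both conditions observe the same cells (same methylation states and the
    same amplicon panel) so that downstream error-rate estimates from the
    undigested run transfer to the digested one, as in the real assay.
    Reproducible: all randomness flows from ``config.seed`` through
    deterministic substreams.
    """
    root = np.random.SeedSequence(config.seed)
    rng_state, rng_undig, rng_dig, rng_empty, rng_doub = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    prof = config.cell_type_profiles
    amplicons = list(prof.index)
    n_amp = len(amplicons)
    d = config.dropout.to_numpy()
    lam = np.full(n_amp, float(config.mean_reads))
    non_hha = (config.amplicon_classes == CLASS_NON_HHA).to_numpy()

    # --- real cells -------------------------------------------------------
    types: list[str] = []
    for t in prof.columns:
        types.extend([t] * int(config.n_cells.get(t, 0)))
    n_cell = len(types)
    probs = np.stack([prof[t].to_numpy(dtype=float) for t in types]) if n_cell else \
        np.empty((0, n_amp))
    if config.allelic_mode:
        alleles = rng_state.random((n_cell, n_amp, 2)) < probs[:, :, None]
        meth = alleles.any(axis=2)
    else:
        meth = rng_state.random((n_cell, n_amp)) < probs

    undig_present = rng_undig.random((n_cell, n_amp)) < (1.0 - d)
    p_amplifiable = np.where(meth, 1.0, config.digestion_fpr)
    p_amplifiable[:, non_hha] = 1.0  # no recognition site: digestion is irrelevant
    dig_present = rng_dig.random((n_cell, n_amp)) < (1.0 - d) * p_amplifiable

    undig_counts = _reads_given_present(rng_undig, undig_present, lam)
    dig_counts = _reads_given_present(rng_dig, dig_present, lam)

    barcodes = [f"cell_{i:05d}" for i in range(n_cell)]
    rows = [{"barcode": b, "cell_type": t, "is_doublet": False, "is_empty": False}
            for b, t in zip(barcodes, types)]

    # --- doublets: element-wise max of two distinct cells -----------------
    n_doub = int(round(config.doublet_rate * n_cell))
    doub_meth = []
    for j in range(n_doub):
        a, b = rng_doub.choice(n_cell, size=2, replace=False)
        undig_counts = np.vstack([undig_counts, np.maximum(undig_counts[a], undig_counts[b])])
        dig_counts = np.vstack([dig_counts, np.maximum(dig_counts[a], dig_counts[b])])
        doub_meth.append(np.maximum(meth[a], meth[b]))
        barcodes.append(f"doublet_{j:04d}")
        rows.append({"barcode": barcodes[-1], "cell_type": f"{types[a]}+{types[b]}",
                     "is_doublet": True, "is_empty": False})

    # --- empty droplets: uniform low Poisson background -------------------
    n_empty = int(config.n_empty_droplets)
    if n_empty:
        empty_u = rng_empty.poisson(config.empty_mean_reads, size=(n_empty, n_amp))
        empty_d = rng_empty.poisson(config.empty_mean_reads, size=(n_empty, n_amp))
        undig_counts = np.vstack([undig_counts, empty_u])
        dig_counts = np.vstack([dig_counts, empty_d])
        for j in range(n_empty):
            barcodes.append(f"empty_{j:05d}")
            rows.append({"barcode": barcodes[-1], "cell_type": "empty",
                         "is_doublet": False, "is_empty": True})

    meth_all = np.vstack([meth.astype(np.int8)] + [m.astype(np.int8)[None, :] for m in doub_meth]) \
        if (n_cell or n_doub) else np.empty((0, n_amp), dtype=np.int8)
    truth = SimTruth(
        barcode_table=pd.DataFrame(rows).set_index("barcode"),
        methylation=pd.DataFrame(meth_all, index=barcodes[: n_cell + n_doub],
                                 columns=amplicons),
        realized_fnr=pd.Series(1.0 - undig_present.mean(axis=0), index=amplicons)
        if n_cell else pd.Series(np.nan, index=amplicons),
        realized_fpr=pd.Series(
            dig_present[:, (config.amplicon_classes == CLASS_CONST_UNMETH).to_numpy()]
            .mean(axis=0),
            index=config.amplicon_classes.index[config.amplicon_classes == CLASS_CONST_UNMETH],
        ) if n_cell else pd.Series(dtype=float),
    )
    digested = CountMatrix(list(barcodes), amplicons, dig_counts, "digested")
    undigested = CountMatrix(list(barcodes), amplicons, undig_counts, "undigested")
    return digested, undigested, truth


def default_panel(
    n_discriminating: int = 200,
    n_non_hha: int = 50,
    n_const_meth: int = 21,
    n_const_unmeth: int = 32,
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC"),
    min_profile_diff: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build (cell_type_profiles, amplicon_classes) for a synthetic panel.

    Discriminating amplicons get cell-type profiles drawn from {0.05, 0.95}
    patterns that differ between at least two types by ``min_profile_diff``
    or more; control classes are pinned to their constitutive values
    (non-HhaI amplicons are modelled as always amplifiable — profile 1).
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    lo, hi = 0.5 - min_profile_diff / 2, 0.5 + min_profile_diff / 2
    rows, classes, names = [], [], []
    for i in range(n_discriminating):
        while True:  # reject patterns identical across all types
            pattern = rng.integers(0, 2, size=k)
            if pattern.min() != pattern.max():
                break
        rows.append(np.where(pattern == 1, hi, lo))
        names.append(f"amp_bcell_{i:04d}")
        classes.append(CLASS_BCELL)
    for cls, n, val in ((CLASS_NON_HHA, n_non_hha, 1.0),
                        (CLASS_CONST_METH, n_const_meth, 1.0),
                        (CLASS_CONST_UNMETH, n_const_unmeth, 0.0)):
        for i in range(n):
            rows.append(np.full(k, val))
            names.append(f"amp_{cls}_{i:04d}")
            classes.append(cls)
    profiles = pd.DataFrame(np.array(rows), index=names, columns=list(cell_types))
    return profiles, pd.Series(classes, index=names)
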
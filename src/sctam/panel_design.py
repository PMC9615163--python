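"""Amplicon-panel design for methylation-sensitive restriction profiling.

Targeted single-cell methylation assays read out the digestion state of a
methylation-sensitive restriction site (HhaI, ``GCGC``): a methylated site
resists digestion and its amplicon amplifies, an unmethylated one is cut and
drops out.  Designing a panel therefore means (1) finding recognition sites
whose digestion state reports on exactly one CpG, (2) keeping amplifiable
windows around them, and (3) choosing, from bulk methylomes of the cell types
of interest, the CpGs that best discriminate those types, plus constitutively
(un)methylated controls.

This module implements that pipeline: motif scanning with two-CpG context
exclusion, candidate-window enumeration from FASTA, simulation of single-cell
binary calls from bulk beta values under allelic error rates, elastic-net
feature selection, pairwise differential-methylation augmentation, and
control-CpG selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RecognitionMotif",
    "HHAI",
    "CandidateRegion",
    "BulkMethylationTable",
    "PanelSelectionConfig",
    "find_recognition_sites",
    "gc_fraction",
    "enumerate_candidate_regions",
    "simulate_calls_from_bulk",
    "select_informative_cpgs",
    "add_pairwise_dm_cpgs",
    "select_control_cpgs",
    "select_intermediate_cpgs",
    "recommend_read_depth",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class RecognitionMotif:
    """A restriction-enzyme recognition motif with excluded sequence contexts.

    ``excluded_contexts`` are strings containing the motif whose occurrence
    voids any overlapping motif match — used to discard sites whose digestion
    state would report on two CpGs at once (e.g. CGCGC / GCGCG for HhaI).
    """

    name: str
    motif: str
    excluded_contexts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be an ACGT string, got {self.motif!r}")
        if self.motif.count("CG") != 1:
            raise ValueError("motif must contain exactly one CG dinucleotide")
        object.__setattr__(self, "excluded_contexts", frozenset(self.excluded_contexts))
        for ctx in self.excluded_contexts:
            if set(ctx) - set("ACGT"):
                raise ValueError(f"excluded context must be ACGT, got {ctx!r}")
            if self.motif not in ctx:
                raise ValueError(f"excluded context {ctx!r} does not contain the motif")


#: HhaI cuts unmethylated GCGC; CGCGC/GCGCG harbour a second CpG and are excluded.
HHAI = RecognitionMotif("HhaI", "GCGC", frozenset({"CGCGC", "GCGCG"}))


@dataclass(frozen=True)
class CandidateRegion:
    """A single-site amplicon candidate window (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    site_pos: int  # genomic offset of the recognition site
    gc: float
    overlaps_previous: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("require 0 <= start < end")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")


def _find_occurrences(sequence: str, pattern: str) -> list[int]:
    """All (overlapping) occurrences of ``pattern`` in ``sequence``."""
    out: list[int] = []
    i = sequence.find(pattern)
    while i != -1:
        out.append(i)
        i = sequence.find(pattern, i + 1)
    return out


def find_recognition_sites(
    sequence: str,
    motif: RecognitionMotif = HHAI,
    apply_exclusions: bool = True,
) -> list[int]:
    """Scan ``sequence`` for recognition-site offsets (0-based, sorted).

    Overlapping matches are each reported.  With ``apply_exclusions``, any
    match overlapped by an occurrence of an excluded context is removed,
    implementing the "single CpG per site" rule.  ``N`` never matches.
    """
    if not motif.motif:
        raise ValueError("motif must be non-empty")
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError("sequence must be over {A,C,G,T,N}")
    sites = _find_occurrences(seq, motif.motif)
    if not apply_exclusions or not sites or not motif.excluded_contexts:
        return sites
    # collect excluded intervals, then drop sites overlapping any of them
    blocked: list[tuple[int, int]] = []
    for ctx in motif.excluded_contexts:
        for j in _find_occurrences(seq, ctx):
            blocked.append((j, j + len(ctx)))
    if not blocked:
        return sites
    blocked.sort()
    m = len(motif.motif)
    kept = []
    for s in sites:
        if not any(s < b_end and b_start < s + m for b_start, b_end in blocked):
            kept.append(s)
    return kept


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length; ``N`` counts in the denominator only."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def enumerate_candidate_regions(
    genome,
    motif: RecognitionMotif = HHAI,
    window: int = 300,
    gc_min: float = 0.45,
    gc_max: float = 0.65,
) -> list[CandidateRegion]:
    """Enumerate single-site candidate windows over a genome.

    Parameters
    ----------
    genome
        Path to a FASTA file, or any mapping of contig name -> sequence string.
    window
        Window size in bp; the window is centred on the recognition site.
    gc_min, gc_max
        Inclusive GC-fraction bounds for the whole window.

    A window qualifies when it lies fully inside the contig, contains no ``N``,
    has exactly one (non-excluded) recognition site, and passes the GC filter.
    Overlap between consecutive returned windows is allowed and flagged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if gc_min > gc_max:
        raise ValueError("gc_min must be <= gc_max")
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        import pyfaidx

        try:
            fa = pyfaidx.Fasta(str(genome))
        except (OSError, pyfaidx.FastaIndexingError) as exc:
            raise IOError(f"cannot read FASTA {genome!r}: {exc}") from exc
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = {str(k): str(v) for k, v in dict(genome).items()}

    m = len(motif.motif)
    regions: list[CandidateRegion] = []
    for chrom, seq in contigs.items():
        seq = seq.upper()
        sites = find_recognition_sites(seq, motif, apply_exclusions=True)
        prev_end = -1
        for s in sites:
            centre = s + m // 2
            start = centre - window // 2
            end = start + window
            if start < 0 or end > len(seq):
                continue
            sub = seq[start:end]
            if "N" in sub:
                continue
            inside = [t for t in sites if start <= t and t + m <= end]
            if len(inside) != 1:
                continue
            gc = gc_fraction(sub)
            if not gc_min <= gc <= gc_max:
                continue
            regions.append(
                CandidateRegion(chrom, start, end, s, gc, overlaps_previous=start < prev_end)
            )
            prev_end = end
    return regions


@dataclass(frozen=True)
class BulkMethylationTable:
    """Bulk beta values (CpG x sample) with a sample -> cell-type group map."""

    beta: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups[s] for s in self.beta.columns))

    def group_means(self) -> pd.DataFrame:
        """CpG x group mean beta."""
        labels = pd.Series({s: self.groups[s] for s in self.beta.columns})
        return self.beta.T.groupby(labels).mean().T

    @classmethod
    def from_tsv(cls, beta_path, groups_path) -> "BulkMethylationTable":
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        g = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
        return cls(beta, dict(zip(g["sample"].astype(str), g["group"].astype(str))))


@dataclass(frozen=True)
class PanelSelectionConfig:
    """Parameters of bulk-to-single-cell simulation and CpG selection.

    The allelic error rates describe the assay at the level of a single
    allele: a methylated allele is missed with probability ``allelic_fnr``,
    an unmethylated allele fires spuriously with probability ``allelic_fpr``.
    The elastic-net penalty is fixed (no cross-validation) at
    ``penalty_lambda`` with mixing ``alpha_mix``.
    """

    allelic_fnr: float = 0.2
    allelic_fpr: float = 0.1
    penalty_lambda: float = math.exp(-4.0)
    alpha_mix: float = 0.9
    cells_per_group: int = 200
    fdr_cutoff: float = 0.05
    min_diff: float = 0.25
    unmeth_max: float = 0.06
    meth_min: float = 0.94
    n_unmeth: int = 50
    n_meth: int = 30
    intermediate_low: float = 0.35
    intermediate_high: float = 0.65
    n_alleles: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("allelic_fnr", "allelic_fpr", "alpha_mix", "fdr_cutoff",
                     "min_diff", "unmeth_max", "meth_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.penalty_lambda <= 0:
            raise ValueError("penalty_lambda must be positive")
        if self.cells_per_group < 1:
            raise ValueError("cells_per_group must be >= 1")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")

    def with_(self, **kw) -> "PanelSelectionConfig":
        return replace(self, **kw)


def simulate_calls_from_bulk(
    bulk: BulkMethylationTable,
    config: PanelSelectionConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate binary single-cell calls from bulk group-mean beta values.

    For each simulated cell of group ``g`` and CpG ``j``, each of
    ``n_alleles`` alleles is methylated with probability ``beta(j, g)``; a
    methylated allele yields signal with probability ``1 - allelic_fnr``, an
    unmethylated one with ``allelic_fpr``.  The cell-level call is 1 iff at
    least one allele yields signal.

    Returns (cells x CpG 0/1 DataFrame, cell-type label array).
    """
    rng = np.random.default_rng(config.seed)
    means = bulk.group_means()
    n_cpg = means.shape[0]
    frames, labels = [], []
    for g in means.columns:
        beta = means[g].to_numpy(dtype=float)
        if np.any(beta < 0) or np.any(beta > 1):
            raise ValueError("beta values must lie in [0, 1]")
        shape = (config.cells_per_group, n_cpg, config.n_alleles)
        meth = rng.random(shape) < beta[None, :, None]
        p_signal = np.where(meth, 1.0 - config.allelic_fnr, config.allelic_fpr)
        signal = rng.random(shape) < p_signal
        frames.append(signal.any(axis=2).astype(np.int8))
        labels.extend([g] * config.cells_per_group)
    calls = pd.DataFrame(np.vstack(frames), columns=means.index)
    return calls, np.asarray(labels)


def select_informative_cpgs(
    sim_matrix: pd.DataFrame,
    labels: np.ndarray,
    config: PanelSelectionConfig,
) -> dict:
    """Select discriminative CpGs by an elastic-net multinomial classifier.

    Fits a multinomial logistic regression with elastic-net penalty at the
    fixed penalty strength ``penalty_lambda`` (glmnet parameterisation: the
    mean log-loss is penalised by ``lambda * [alpha |b|_1 + (1-alpha)/2 |b|_2^2]``,
    mapped to scikit-learn's ``C = 1 / (n * lambda)``) and returns the CpGs
    with a nonzero coefficient in any class.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes for selection")
    X = sim_matrix.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("sim_matrix must be binary")
    n = X.shape[0]
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=config.alpha_mix,
        C=1.0 / (n * config.penalty_lambda),
        max_iter=20_000,
        tol=1e-7,
        random_state=config.seed,
    )
    clf.fit(X, labels)
    nonzero = np.abs(clf.coef_).max(axis=0) > 1e-8
    selected = list(sim_matrix.columns[nonzero])
    # two-class fits collapse to a single contrast row
    coef_index = list(clf.classes_) if clf.coef_.shape[0] == len(clf.classes_) \
        else [f"{clf.classes_[1]}_vs_{clf.classes_[0]}"]
    return {
        "selected": selected,
        "n_selected": len(selected),
        "coefficients": pd.DataFrame(clf.coef_, index=coef_index, columns=sim_matrix.columns),
        "config": config,
    }


def add_pairwise_dm_cpgs(
    bulk: BulkMethylationTable,
    fdr_cutoff: float = 0.05,
    min_diff: float = 0.25,
) -> list:
    """CpGs differentially methylated between at least one pair of groups.

    Per group pair a two-sided Welch t-test is run on every CpG's beta values
    and Benjamini-Hochberg corrected within that pair; a CpG qualifies when
    FDR < ``fdr_cutoff`` and the absolute group-mean difference is at least
    ``min_diff`` in at least one pair.
    """
    by_group: dict[str, pd.DataFrame] = {}
    for g in bulk.group_names:
        cols = [s for s in bulk.beta.columns if bulk.groups[s] == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicate samples")
        by_group[g] = bulk.beta[cols]
    names = sorted(by_group)
    hits: set = set()
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            a, b = by_group[ga].to_numpy(), by_group[gb].to_numpy()
            diff = np.abs(a.mean(axis=1) - b.mean(axis=1))
            t = stats.ttest_ind(a, b, axis=1, equal_var=False)
            pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
            rej, _, _, _ = multipletests(pvals, alpha=fdr_cutoff, method="fdr_bh")
            hits.update(bulk.beta.index[rej & (diff >= min_diff)])
    return sorted(hits, key=list(bulk.beta.index).index)


def select_control_cpgs(bulk: BulkMethylationTable, config: PanelSelectionConfig) -> dict:
    """Constitutive control CpGs for error-rate estimation.

    Unmethylated controls: beta < ``unmeth_max`` in *every* sample, ranked by
    mean beta ascending, truncated to ``n_unmeth``.  Methylated controls:
    beta > ``meth_min`` in every sample, ranked by mean descending, truncated
    to ``n_meth``.
    """
    beta = bulk.beta
    mean = beta.mean(axis=1)
    un_ok = beta.max(axis=1) < config.unmeth_max
    me_ok = beta.min(axis=1) > config.meth_min
    unmeth = mean[un_ok].sort_values(kind="stable").index[: config.n_unmeth]
    meth = mean[me_ok].sort_values(ascending=False, kind="stable").index[: config.n_meth]
    return {
        "constitutively_unmethylated": list(unmeth),
        "constitutively_methylated": list(meth),
    }


def select_intermediate_cpgs(bulk: BulkMethylationTable, config: PanelSelectionConfig) -> list:
    """CpGs with intermediate methylation in every sample (imprinting-like).

    Loci under parent-of-origin imprinting sit near 50% methylation in bulk;
    a generic band filter (defaults 0.35-0.65, applied to all samples) stands
    in for curated imprinting-region lists.
    """
    beta = bulk.beta
    ok = (beta.min(axis=1) >= config.intermediate_low) & (
        beta.max(axis=1) <= config.intermediate_high
    )
    return list(beta.index[ok])


def recommend_read_depth(n_cells: int, n_amplicons: int, coverage: int) -> int:
    """Total paired reads = expected cells x amplicons x per-amplicon coverage."""
    for name, v in (("n_cells", n_cells), ("n_amplicons", n_amplicons), ("coverage", coverage)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    return int(n_cells) * int(n_amplicons) * int(coverage)
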
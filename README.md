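# sctam

Analysis toolkit for **targeted single-cell DNA methylation profiling with a
methylation-sensitive restriction enzyme**, as in droplet assays that combine
single-cell targeted PCR with HhaI digestion: the enzyme cuts unmethylated
`GCGC` sites, so an amplicon spanning such a site amplifies only when its CpG
is methylated. Reading out presence/absence of amplicons per cell barcode
therefore yields binary methylation calls for hundreds of CpGs across
thousands of cells.

The package covers the full computational workflow around that assay, for
epigenomics researchers designing panels or analysing the resulting count
matrices:

- **Panel design** — scan a genome for single-CpG `GCGC` recognition sites
  (excluding two-CpG contexts `CGCGC`/`GCGCG`), enumerate 300-bp single-site
  candidate windows with 45–65% GC, simulate single-cell calls from bulk
  methylomes (allelic FNR 0.2 / FPR 0.1) and select discriminative CpGs with
  an elastic-net multinomial classifier (λ = e⁻⁴, α = 0.9), augmented by
  pairwise differential-methylation tests (FDR < 0.05, Δβ ≥ 0.25) and
  constitutively (un)methylated controls (β < 0.06 / > 0.94 in all samples).
- **Simulation** — synthetic digested/undigested barcode×amplicon count
  matrices with per-amplicon capture dropout, digestion failure, empty
  droplets and doublets, plus full ground truth.
- **Cell calling** — identify cells among barcodes using only the non-HhaI
  control amplicons: read threshold min(10, 0.2 × average per-amplicon reads
  of well-covered barcodes), called if above threshold in ≥ 70% of controls.
- **Error rates** — per-amplicon false-negative rate (dropout) from the
  undigested control, false-positive rate (digestion failure) from
  constitutively unmethylated amplicons; high-performance filter FNR < 0.25.
- **Clustering** — binarize at ≥ 1 read, asymmetric binary (Jaccard)
  distance, Ward (ward.D2) hierarchical clustering of cells and CpGs,
  Fisher-exact chromatin-state enrichment, methylation–expression
  correlation within 25 kb.
- **Pseudobulk inference** — FNR-corrected cluster methylation levels under
  the Binomial observation model

  n₁,ᵢ,c ~ Binom(n₀,ᵢ,c + n₁,ᵢ,c, (1 − pᵢ)·mᵢ,c),  mᵢ,c ~ Beta(1, 1)

  where n₀/n₁ count cells without/with a read for amplicon *i* in cluster
  *c* and pᵢ is the amplicon's FNR. Exposed statsmodels-style:
  `PseudobulkModel(...).fit()` returns a `PseudobulkResults` with posterior
  means, 95% credible intervals and a `summary()` table (deterministic
  adaptive quadrature by default; seeded MCMC backend available).
- **Protein normalization** — CLR normalization and marker binarization of
  oligo-tagged antibody counts.

## Worked example

Simulate a realistic experiment (3 cell types, 2,000 cells, 200
discriminating amplicons, dropout Uniform(0.05, 0.25), digestion failure
0.002, 2,000 empty droplets) and run the full analysis:

```python
import numpy as np, pandas as pd
from sctam.simulate import SimConfig, default_panel, simulate_experiment
from sctam.cell_calling import call_cells_table
from sctam.error_model import estimate_fnr, estimate_fpr, select_high_performance
from sctam.methylation import binarize, cluster_cells
from sctam.pseudobulk import PseudobulkModel

profiles, classes = default_panel(n_discriminating=200, seed=0)
rng = np.random.default_rng(1)
cfg = SimConfig(
    n_cells={"typeA": 700, "typeB": 700, "typeC": 600},
    cell_type_profiles=profiles, amplicon_classes=classes,
    dropout=pd.Series(rng.uniform(0.05, 0.25, len(profiles)), index=profiles.index),
    digestion_fpr=0.002, n_empty_droplets=2000, seed=2,
)
digested, undigested, truth = simulate_experiment(cfg)

controls = list(classes.index[classes == "non_hha"])
cells, threshold = call_cells_table(digested, controls)
print(f"read threshold: {threshold:.2f}")
print(f"called cells: {int(cells['is_cell'].sum())} of {len(cells)} barcodes")

ucells, _ = call_cells_table(undigested, controls)
fnr = estimate_fnr(undigested.subset_barcodes(list(ucells.index[ucells['is_cell']])), classes)
fpr_tab, fpr_med = estimate_fpr(digested.subset_barcodes(list(cells.index[cells['is_cell']])),
                                list(classes.index[classes == "const_unmeth"]))
print(f"median FNR: {fnr['fnr'].median():.3f}   median FPR: {fpr_med:.4f}")
keep = select_high_performance(fnr, 0.25)
print(f"high-performance amplicons (FNR < 0.25): {len(keep)} of {len(fnr)}")

binary = binarize(digested.subset_barcodes(list(cells.index[cells['is_cell']])), keep)
assign = cluster_cells(binary, k=3)
model = PseudobulkModel(binary, assign, fnr)
print(model.fit().summary().head(3).round(3).to_string(index=False))
```

which prints:

```
read threshold: 6.83
called cells: 2000 of 4000 barcodes
median FNR: 0.150   median FPR: 0.0020
high-performance amplicons (FNR < 0.25): 198 of 200
   amplicon_id  cluster  n0  n1   fnr  m_mean  ci_low  ci_high  saturated
amp_bcell_0000        1 260 440 0.157   0.745   0.702    0.787      False
amp_bcell_0001        1 298 402 0.249   0.764   0.715    0.813      False
amp_bcell_0002        1 534 166 0.075   0.257   0.224    0.292      False
```

The threshold and cell counts show that the non-HhaI rule separates the
2,000 true cells from the 2,000 empty droplets; the median FNR recovers the
simulated dropout level (0.15) and the median FPR the digestion-failure rate
(0.002); and the pseudobulk table reports, per amplicon and cluster, the
detection counts, the FNR used for correction and the posterior methylation
level with its 95% credible interval — e.g. for `amp_bcell_0000` the raw
detection fraction 440/700 = 0.63 is corrected to m ≈ 0.75 because ~16% of
methylated cells drop out.

A `sctam` command-line interface wraps every stage
(`simulate`, `design-panel`, `call-cells`, `estimate-errors`, `binarize`,
`cluster`, `pseudobulk`, `protein-normalize`, `enrich`, `correlate`, `run`);
`sctam run --config run.yaml` executes the whole pipeline and writes
plain-text artifacts plus a JSON manifest.

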
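# Methods

## Input model

`snvmap` assumes somatic SNV calling and annotation have already happened
upstream: one annotated variant table per cell, produced by ANNOVAR from a
per-cell VCF called against a matched normal sample. Two ANNOVAR output
dialects are recognized automatically — `*_multianno.txt` tables (header
row with `Chr`, `Start`, `Ref`, `Alt`, `Gene.<model>`, `ExonicFunc.<model>`
columns, any gene model) and headerless `exonic_variant_function` output
(`lineN` tag, functional class, `GENE:transcript:...` annotations, then the
variant coordinates). An explicit `ColumnMap` override handles anything
else. The cell ID is the file basename minus the longest recognized
extension chain, which makes discovery deterministic across runs and
between a directory and a ZIP archive of the same files.

Functional classes are normalized into a closed vocabulary
(`nonsynonymous SNV`, `synonymous SNV`, `stopgain`, `stoploss`,
`startloss`, `unknown`) with an explicit `other` bucket for anything
unrecognized. The default analysis retains only non-synonymous SNVs; a
keep-all mode exists for sparse datasets where discarding classes would
leave too few genes. Non-SNV rows (indels, multi-base alleles) are excluded
by default and can be included with a flag.

## Count semantics

`counts[c, g]` is the number of retained variant records in cell *c*
annotated to gene *g*, with two deliberate conventions:

* duplicate rows (same chrom, pos, ref, alt within one cell) are collapsed
  first, so a per-cell VCF annotated at multiple transcripts cannot
  double-count a site — a variant counts once per (cell, variant, gene);
* a record listing several genes (ANNOVAR separates them with `;` or `,`)
  increments **every** listed gene, preserving total evidence. Users who
  dislike this can pre-filter their tables; the behavior is documented
  rather than configurable because it interacts with the recount oracle in
  the test suite.

Cells present on disk but missing from the metadata sheet are kept, their
metadata fields set to the sentinel category `"NA"` and flagged in a
`metadata_matched` column (a strict mode errors instead): a converter
should not silently drop data. Cell-to-sample matching is exact first,
then longest sample ID that prefixes the cell ID at a `_`/`-`/`.`
boundary, since metadata is typically per patient while files are per
cell.

The matrix is serialized in the AnnData `.h5ad` convention (matrix +
per-cell table + per-gene table); `h5py` writes are byte-deterministic
here, which the determinism guarantees below rely on.

## QC chain

The five steps run once, in order, without iteration — a gene may fall
below the step-1 support threshold after outlier cells are removed, which
is accepted (re-filtering would change the semantics of the printed
thresholds). Defaults: `min_cells_per_gene=3`, `min_genes_per_cell=30`,
`upper_percentile=98`, `target_sum="median"`, `n_hvg=3000`.

* **Step 2 boundary:** "fewer than 30 mutated genes" excluded means a cell
  with exactly 30 is kept.
* **Step 3 percentile:** the threshold is the linear-interpolation
  percentile of per-cell mutated-gene counts over the *currently retained*
  cells (i.e. computed after step 2 by default; a config flag swaps the
  order). Cells are removed only when strictly above the threshold, so
  `p=100` or an all-equal distribution removes nothing.
* **Normalization:** every cell is scaled to a common total; the default
  target is the median of the pre-normalization per-cell totals, so a
  dataset with homogeneous totals is left essentially unchanged. Row totals
  match the target to 1e-9 relative tolerance by construction.
* **HVG selection:** on the expm1 scale of the log-normalized values,
  per-gene dispersion = variance/mean. Genes are ranked by mean and split
  into 20 equal-count bins (contiguous chunks of the mean-sorted list, ties
  broken by gene order); log-dispersion is z-scored within each bin and the
  top *n* genes by the z-score are selected, ties again broken by stable
  gene order. Rank-based binning was chosen over quantile-edge binning
  because it is a pure function of the mean *ranking*: quantile edges move
  under last-bit floating-point noise and can silently reassign boundary
  genes. Bins with a single gene, or zero dispersion spread, get z = 0.
* **Regress-out:** per gene, ordinary least squares of the value on
  (intercept, total counts per cell), replaced by residuals; residuals are
  orthogonal to the covariate (|Pearson r| < 1e-8 enforced by the tests). A
  constant covariate leaves the values unchanged with a warning. No
  unit-variance scaling follows unless `scale=True`: only the printed
  pipeline steps run by default, the common extra step is opt-in.

The filter report telescopes (each step's "before" equals the previous
step's "after") and carries the removed cell/gene labels, the computed
percentile threshold, the mean retained variant count per cell on the
post-filter matrix, and per-patient post-filter gene counts.

## Embedding and clustering

PCA (arpack solver, `n_pcs=50` capped at min(n_cells, n_genes) − 1) feeds a
15-nearest-neighbor graph with UMAP-style connectivity weights; the graph
is symmetrized with a zero diagonal. UMAP runs **from the neighbor graph**,
not from raw PC distances, so the embedding and the clustering see the same
topology. Leiden uses leidenalg's RBConfiguration partition; Louvain uses
igraph's multilevel algorithm (the reference implementation igraph ships),
both on the same weighted graph at the same resolution (default 1.0) and
seed. Cluster labels are renamed by descending cluster size (ties by first
occurrence), so label "0" is always the largest cluster regardless of the
algorithm's internal numbering — this keeps labels stable across runs and
between algorithms.

Everything stochastic (PCA sign conventions, UMAP layout, both clusterers)
takes the single pipeline seed; with a fixed seed a full run is
bit-reproducible on one machine, including the PNG outputs (figures are
rendered on the Agg backend with fixed metadata).

## Gene-set analytics

A gene *qualifies* for a patient when it is mutated in at least 2 of that
patient's post-filter cells (`min_cells_per_patient_gene`, applied to the
post-QC, pre-HVG count matrix — the qualifying-gene rule and the QC filters
are two halves of one accounting, so they see the same matrix). A patient
with fewer cells than the threshold gets an empty set with a warning. Group
gene sets are unions over member patients; the Venn partition of 2–4 sets
has 2^k − 1 exclusive regions whose counts sum to the union size. The
renderer places each region's count at the geometric centroid of the
region (computed by rasterizing the circle/ellipse layout), which avoids a
hand-tuned label-position table and generalizes across the 2-, 3- and
4-set layouts.

The per-patient summary reports cells in, cells surviving, the mean
retained variant count per cell on the post-filter matrix, and the
qualifying-gene count; a patient whose cells were all filtered is listed
with blank statistics and the flag `no cells passed filtering`. Summary
totals are cross-checked against the filter report at build time.

## Synthetic data

The generator plants separable group structure of the kind the pipeline is
meant to reveal: each group owns a disjoint signature of
`signature_size=60` genes mutated in a member cell with probability 0.8;
every other gene is background, mutated with probability 0.02 per cell;
synonymous decoy rows (rate 0.01 per gene) exercise the functional-class
filter. Default geometry is 3 groups × 20 cells over 2 patients per group
and 2000 background genes, giving ~62 mutated genes per cell — comfortably
above the 30-gene cell filter, while background genes (expected support
1.2 cells) mostly fall to the 3-cell gene filter. Positions and alleles
are synthetic and not tied to a real genome build; gene symbols are
`G00001…`. The generator is a pure function of its seed, byte-for-byte.

What the fixtures do **not** emulate: allele dropout and coverage
variability of single-cell WES, mutational trinucleotide signatures, shared
driver genes between groups, and patient-level batch structure. Passing
tests therefore demonstrate that the machinery (counting, filtering,
embedding, clustering, set arithmetic) is correct and deterministic — not
that real tumor histologies will separate this cleanly.

## Problem sizes

Tests and the acceptance script run the full pipeline at 60 cells × ~2200
genes (the planted-fixture geometry above) and unit-level checks at
10–40 cells; these sizes keep every oracle exact (brute-force recounts,
enumeration) while exercising all code paths. The pipeline itself is
vectorized throughout and has no size-specific logic.

## Known limitations

* Louvain has no per-level refinement (it is classic multilevel); on
  marginal graphs Leiden and Louvain can disagree, which is why both labels
  are always written.
* The Venn renderer supports at most 4 groups; more groups require
  subsetting (UpSet-style plots are out of scope).
* Kind inference for metadata columns is all-or-nothing: one non-numeric
  value makes a column categorical.
* The percentile outlier cut uses linear interpolation; other percentile
  definitions will disagree on tiny datasets.
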
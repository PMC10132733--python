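# Methods

## Scope and model

`lenbias` quantifies technique-dependent transcript capture between paired
single-cell (whole cell) and single-nucleus RNA-seq libraries. The analysis
model is deliberately simple: after depth matching, each gene's expression
is compared between techniques with nonparametric or count-model tests, the
resulting top marker lists are annotated with gene structure, and the
structural distributions of the lists are compared with each other and with
the host-genome background. No latent-space integration or clustering is
performed — synthetic data carries ground-truth cluster labels, and
real-data users are expected to supply their own labels (the pipeline's
integration stage is an explicit identity surrogate behind which an external
batch-correction step can be plugged).

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated. It emulates:

* **Gene catalog.** Exon count per gene is 1 + NB(mean 7.8, size 2), which
  together with the intronless mitochondrial genes and short (≤ 6 exon)
  ribosomal-protein genes gives a catalog-wide mean of ~8.7 exons per gene,
  matching the mammalian genome-wide average (~8.8). Per-exon lengths are
  log-normal (median 160 nt, σ = 0.7), so transcript length is the sum of
  exon lengths (~1.8 kb on average); introns are log-normal (median 1.5 kb,
  σ = 1.0), making genomic span grow with exon count (~20 kb average); the
  CDS is a uniform 30–90% fraction of the transcript. All structural
  invariants (CDS ≤ transcript ≤ span; single-exon ⇒ transcript = span)
  hold by construction.
* **Compartment-exclusive genes.** A configurable fraction of genes is
  flagged mitochondrial (default 0.5%, symbols `mt-…`, one exon) or
  ribosomal-protein (default 2%, `Rpl…`/`Rps…`, mouse convention;
  human-style prefixes are a parameter). These genes receive zero capture
  weight in the nucleus technique and an expression boost (default ×8) in
  the base profile, so they carry roughly 15–20% of whole-cell library
  mass — enough to dominate an unfiltered between-technique DEG list, which
  is what the prefix-exclusion rule exists to handle, without crowding out
  ordinary short genes from the whole-cell marker list.
* **Planted capture bias.** The nucleus technique's per-gene capture weight
  is `1 + (A − 1)·logistic(s·(exon_count − m))` with midpoint m = 10 exons,
  steepness s = 0.7 and amplitude A (default 4; A = 1 is the null
  generator). The curve is planted in exon count — the most operational
  form of the bias — with length correlated through the catalog. The
  whole-cell technique is flat by default; an optional inverse-length tilt
  (`single_cell_length_tilt`) is exposed but off, since the short-gene
  preference of whole cells is not quantified beyond its direction.
  An optional `technique_fold_changes` map multiplies the nucleus weight of
  named genes, used to plant exact fold changes for power calibration.
* **Counts.** Cells draw a cluster label uniformly (default 3 clusters,
  15 markers each at fold change 4), a log-normal library size
  (median 1,500 counts, σ_log = 0.22), and then a single multinomial over
  the normalized product base × cluster × capture weights. Overdispersion
  enters through per-gene-per-cell Gamma(θ, 1/θ) perturbations
  (θ = `baseline_dispersion`, default 10; θ = ∞ disables them), which makes
  each gene's counts exactly NB(θ) given the library size. The multinomial
  construction keeps depth exactly controllable — the point of the
  depth-matching stage — at the cost of a tiny negative dependence between
  genes within a cell.

What the generator does **not** emulate: ambient RNA, doublets, UMI
collisions, dissociation-stress signatures, batch chemistry effects, or any
sequence-level process. Passing the recovery tests therefore shows the
pipeline detects a planted exon-count-linked capture difference at realistic
sparsity and depth; it does not certify behavior under real-data artifacts
the generator omits.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| QC min cells/gene, min features/cell | 5, 300 | cells, genes | conventional minimum-evidence filters |
| depth window | (1100, 2000), exclusive | counts/cell | linear counts-vs-features regime; per-technique, config input |
| cells per technique | 1000 | cells | balanced comparison size |
| scale factor | 10⁴ | counts | counts-per-ten-thousand convention |
| min.pct, log-FC threshold | 0.25, 0.25 | fraction, ln units | test only informative genes |
| excluded prefixes | mt-, Rpl, Rps | — | nucleus-absent compartments; applied to the whole-cell list |
| top list size | 100/technique | genes | downstream structural analysis input |
| exon-bin edges | unit bins 1..70, then one open bin above | exons | genes beyond 70 exons are negligible |
| ssGSEA α | 0.25 | — | standard rank-weight exponent |
| NB dispersion floor | θ = 0.01 | — | guards the method-of-moments estimate |

## Numerical choices

* **Wilcoxon rank-sum.** Midranks for ties. Exact branch (pooled n ≤ 12):
  full enumeration of label assignments over the pooled midranks, two-sided
  p = fraction of assignments with |U − E[U]| at least the observed value;
  enumeration handles ties, so the branch agrees with a permutation oracle
  to 10⁻¹⁰ with or without ties. Asymptotic branch: tie-corrected variance
  and a 0.5 continuity correction (agrees with the untied enumeration at
  n = 12 to within 0.02; with extreme ties at such small n any normal
  approximation can deviate far more — use the exact branch there, as the
  default `method='auto'` does).
* **log fold change** is the natural-log ratio of group means of
  expm1-transformed log-normalized values, with pseudocount 1 — the
  convention behind the "0.25-fold (log-scale)" threshold. For the non-log
  normalization alternates the means are taken on the values as given.
* **NB GLM.** Per gene: Poisson GLM (group indicator + ln total-counts
  offset) to get fitted means; θ by method of moments on those means
  (floored at 0.01, near-Poisson when the moment excess is non-positive);
  one NB refit of full and null models at fixed θ; likelihood-ratio χ²₁
  p-value. Genes whose fit fails are logged and skipped, never fatal.
* **Bonferroni** multiplies by the number of genes actually tested
  (post-filter), per scan.
* **Top-list ranking**: p_adj ascending, then |log-FC| descending, then
  gene id (deterministic tie-break).
* **ssGSEA**: descending expression with index-stable tie order; weights
  are ascending midranks raised to α, so scores are pure rank statistics
  and invariant under monotone transforms of a cell's profile. NES divides
  by the ES range over the scored population (width-1 interval).
* **χ² exon-bin test** uses the genome bin fractions scaled to the list
  size. With the default unit bins and a 100-gene list many expected counts
  are < 1, so the statistic is descriptive there; calibration checks use
  coarser bins where expected counts are ≥ 5.
* **Marker-list overlap** uses the union as denominator.
* **Depth-window bounds are exclusive**; genome-background comparisons
  include the list's own members unless excluded by flag.

## Design choices where the design was open

* QC is a single gene-then-cell pass, not iterated to a fixed point; the
  suite asserts the documented order, not idempotence.
* Depth windows are config inputs chosen by inspection of the
  counts-vs-features diagnostic (`linearity_check` is advisory, not an
  automatic window finder).
* The three normalization schemes (log, relative, sqrt of scaled counts)
  are this package's robustness panel: all strictly monotone per cell, so
  rank-based statistics agree across them and only the fold-change filter
  can differ.
* Structural "sequence length" is reported as transcript length, with CDS
  length and genomic span always computed alongside.
* Gene-set scoring cohort for NES normalization is all scored cells of the
  run.

## Problem sizes used by the validation suite

The packaged tests and `scripts/acceptance.py` run the full-size default
pipeline (2,000 genes, 2,000 cells per technique, 1,000 subsampled per
technique) once, and use reduced simulations for repeated-run calibration:
300 genes × 150 cells/technique for the 200–500-run null (type-I) harness
with filters relaxed to min.pct = 0 and log-FC 0 (under the null generator
essentially no gene clears the 0.25 log-FC filter, so the top lists the
comparison needs would otherwise be empty); 800 genes × 300 cells/technique
for 20-seed planted-bias recovery and normalization robustness; 2,000 genes
× 200 cells/group for NB-GLM null calibration and 1,000 genes with 60
planted 4-fold genes for its power. These sizes are the package's chosen
trade-off between Monte-Carlo resolution and a test suite that runs in a
couple of minutes.

## Known limitations

* The NB GLM estimates one dispersion per gene by moments, not by
  profile/Cox–Reid likelihood; with very low counts the LRT can be mildly
  conservative.
* The exact Wilcoxon branch is O(C(n, n_x)) and capped at pooled n = 12.
* ssGSEA tie handling within a tie group walks genes in index order; the
  midrank weights make the score tie-invariant in the weights but the
  running-sum path (not its endpoints' statistics) can depend on within-tie
  order in pathological constructions.
* The genome background is the full simulated catalog; with real
  annotations the choice of universe (all genes vs protein-coding) is the
  user's and changes the background distributions.
* Marker-overlap percentages depend on the union denominator; pooled-total
  denominators would halve them for disjoint lists of equal size.
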
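# lenbias

Gene-length capture-bias analysis for paired single-cell / single-nucleus
RNA-seq experiments.

## The problem

Single-cell RNA-seq profiles the whole-cell mRNA pool of dissociated live
cells; single-nucleus RNA-seq profiles only nuclear mRNA. The two protocols
do not capture the same transcriptome: nuclei are enriched for long,
exon-rich (unspliced or slowly exported) transcripts and completely miss
mitochondrial and most ribosomal-protein mRNAs, while whole cells capture
short genes at higher rates. The effect pivots around roughly 10 exons per
gene and distorts everything downstream of the count matrix — marker lists,
differential expression and gene-set enrichment — so pipelines that mix or
compare the two techniques need a way to quantify it.

`lenbias` is a tested, reusable pipeline for exactly that comparison, for
computational biologists who have a paired sparse count matrix
(genes × cells, MTX + TSV sidecars) with per-cell technique labels and a
per-gene structure annotation (exon count, transcript/CDS length, genomic
span). It also ships a synthetic paired-experiment generator with a
*planted*, parameterized bias curve, so every stage is validated against a
known ground truth.

## What it computes

Stages (each is a library module and a `lenbias` CLI subcommand):

1. **QC** — keep genes detected in ≥ 5 cells, then cells expressing ≥ 300
   features (single pass, in that order).
2. **Depth matching** — restrict to a per-technique library-size window
   (the regime where genes/cell grows linearly with counts/cell; Pearson r
   diagnostic) and draw a balanced subsample, by default 1,000 cells per
   technique (2,000 total), uniformly without replacement.
3. **Normalization** — counts per 10,000 with log1p (`ln(1 + c/T·10⁴)`),
   plus `relative` and `sqrt_scaled` alternates to show the bias call is
   not a transform artifact.
4. **Differential expression** — between-technique Wilcoxon rank-sum test
   (midranks for ties; exact enumeration for pooled n ≤ 12, otherwise the
   tie-corrected, continuity-corrected normal approximation), or a per-gene
   negative-binomial GLM on raw counts with a log library-size offset and a
   likelihood-ratio χ²₁ p-value (dispersion by method of moments, floored at
   θ = 0.01). Genes are tested when expressed in ≥ 25% of one group and
   |log-FC| ≥ 0.25 (natural log); Bonferroni correction over tested genes.
   Mitochondrial (`mt-`) and ribosomal (`Rpl`/`Rps`) symbols are removed
   from the whole-cell top list before taking the top-100 per technique.
5. **Structural bias** — annotate each top list with exon count, transcript
   length, CDS length and genomic span; compare lists pairwise and against
   the whole-genome catalog (rank-sum tests, Fisher–Pearson skewness
   g₁ = m₃/m₂^{3/2}, exon-count density curves, and a binned exon-count
   table with a χ² goodness-of-fit statistic against the genome expectation).
6. **Enrichment** — per-cell single-sample gene-set scores
   ES = Σᵢ [P_in(i) − P_out(i)] over the expression-ranked gene list, where
   P_in is the rank^α-weighted cumulative fraction of set members (α = 0.25)
   and P_out the plain cumulative fraction of non-members; NES divides by
   the ES range over all scored cells; techniques compared by rank-sum test.

The synthetic generator plants a logistic capture-efficiency curve for the
nucleus technique, `w(e) = 1 + (A − 1)·σ(s·(e − m))` with midpoint m = 10
exons and amplitude A (A = 1 is the null generator), zero nucleus weight for
mito/ribo genes, cluster markers, log-normal library sizes, and per-cell
multinomial counts with optional gamma overdispersion — and writes a truth
ledger so recovery can be judged.

## Worked example

```python
import lenbias as lb

config = lb.RunConfig(seed=1, out_dir="run1")   # simulate -> ... -> enrichment
report = lb.run_pipeline(config)

print(report.stages["subsample"]["n_cells"])
print(report.stages["deg"]["top_list_sizes"])
print(report.stages["bias"]["mean_exon_count"])
print(report.stages["deg"]["overlap"]["shared_fraction"])
print(report.truth_recovery["verdict"])
```

prints

```
2000
{'single_cell': 100, 'single_nucleus': 100}
{'single_nucleus': 17.49, 'single_cell': 3.31}
0.0
recovered
```

Read: the depth-matched object holds 2,000 cells (1,000 per technique); each
technique contributes 100 top markers; the nucleus list averages ~17.5 exons
per gene versus ~3.3 for the whole-cell list (rank-sum p ≈ 2 × 10⁻³⁴ in
`report.stages["bias"]["exon_count_p"]`), the two lists share no genes, and
the planted amplitude-4 bias was recovered. The run directory contains every
intermediate (MTX/TSV/JSON: QC'd and balanced matrices, the DEG table, the
bias report, density-curve TSVs and per-set enrichment summaries).

The same pipeline runs from a shell:

```
lenbias simulate --n-genes 2000 --n-cells 2000 --seed 1 --out-dir sim
lenbias qc --mtx sim/matrix.mtx --genes sim/genes.tsv --cells sim/cells.tsv \
  --min-cells 5 --min-features 300 --out-dir qc
lenbias subsample --mtx qc/matrix.mtx --genes qc/genes.tsv --cells qc/cells.tsv \
  --window-min 1100 --window-max 2000 -n 1000 --seed 1 --out-dir balanced
lenbias run --config run.toml     # or everything at once
```

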
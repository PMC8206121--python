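# chromatlas

Building an atlas of active regulatory elements from multi-assay chromatin
data in a patient cohort: **chromatlas** integrates per-sample ChIP-seq
peak calls (H3K4me3, H3K27ac), ATAC-seq, coverage tracks, transcript
expression, chromatin-contact maps, TF-binding sites, conservation scores
and CpG methylation into a catalog of active promoters and putative
enhancers, stratifies elements by how many samples share them, detects
promoters specifically active in one sample group, and links enhancers to
their target transcripts by combining distance-decay-corrected contact
calls with co-activation statistics.

It is written for computational epigenomics practitioners who have
standard per-sample outputs (BED peaks, bedGraph coverage, a TSS table, a
counts matrix, triplet-format contact bins) and want the integration
steps as a tested, scriptable library plus a thin CLI — including a
synthetic multi-omics cohort generator with planted ground truth, so the
entire pipeline can be exercised and validated with no external data.

## The model

* **Promoters** are windows of ±1,000 bp around every TSS; an element
  carries a mark in a sample iff it overlaps (≥1 bp) any peak called for
  that sample.  **Putative enhancers** are the merged union, across
  samples, of H3K27ac peaks that have *no* overlap with any promoter
  window.
* **Common vs variable**: an element is *common* when active in at least
  *t* samples (defaults: *t* = 20 for H3K4me3 promoters/genes, 10 for
  H3K27ac, 4 for enhancers), otherwise *variable*.
* **Group-specific promoters**: active in ≥ 4 of 5 focal-group samples,
  ≤ 2 of 13 contrast samples, and one-sided Fisher exact *p* < 0.003 on
  the 2×2 group × activity table (symmetric rule for the reverse
  direction: ≤ 1 and ≥ 11).
* **Signal profiles**: reads at positions with count *z*-score > 7 are
  discarded; remaining reads are binned (500 bp), normalized per million
  mapped reads, and abundance of a TSS ± 2 kb region is the mean of
  (ChIP − input) over overlapping bins.  Metaprofiles use 10-bp bins
  smoothed with a running mean (k = 15).
* **Contact calls**: a banded intra-chromosomal contact map (10 kb bins,
  ≤ 2 Mb span) is tested against a distance-stratified negative-binomial
  null (μ_d = mean count at bin distance d, method-of-moments
  dispersion; Poisson when dispersion ≈ 0); pairs with upper-tail
  *p* < 0.001 are called, and called target bins overlapping a promoter
  window yield candidate enhancer–transcript pairs.
* **Co-activation**: expression and coverage are quantile normalized;
  Spearman correlations are pooled per distance stratum (< 20 kb,
  20–200 kb, > 200 kb) and per linkage source (closest vs contact); a
  resampling null (draws of matched size from the reference pair set)
  gives an empirical *p* for the contact-vs-closest difference; the
  final significant pairs satisfy BH-FDR < 0.1, Spearman R > 0.7 and a
  maximum transcript count ≥ 20.

## Worked example

Generate a synthetic cohort (24 samples: 5 PA, 6 DA, 13 GB; 300 genes,
400 enhancers, planted loops and correlated enhancer–transcript links)
and run every stage:

```bash
chromatlas run --stages generate,atlas,profiles,structure,contacts,coactivation,methylation,report \
    --cohort-dir cohort --outdir results --seed 1
python -c "import json; print(json.load(open('results/recovery_report.json'))['links'])"
```

prints

```
{'n_true': 20, 'n_called': 20, 'sensitivity': 1.0, 'fdp': 0.0}
```

meaning all 20 planted correlated enhancer–transcript links were
recovered by the full chain (enhancer calling → contact calling → pair
correlation → significance filter) with no false discoveries.  The
accompanying `coactivation_correlations.tsv` reports the pooled
promoter-mark/expression Spearman R (≈ 0.72 on this cohort) and the
per-stratum enhancer correlations, and `specific_promoters.json` lists
the promoters called PA- or GB-specific (34 and 38 transcripts here,
exactly the planted sets plus none).

Every numeric default (flanks, thresholds 20/10/4, z = 7, bin widths
500/10, resolution 10 kb, span 2 Mb, α = 0.001, strata 20/200 kb, filter
gates 0.1/0.7/20, resampling 260 × 1,000) lives in the pipeline config
and can be overridden from a YAML file (`--config`).

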
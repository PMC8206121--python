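# Methods

This note documents the statistical procedures implemented in
`chromatlas`, the choices made where the design was genuinely open, what
the synthetic cohort does and does not emulate, and the package's known
limitations.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention).  Merging treats
touching intervals (end == start) as one element, matching the behaviour
of standard peak-merging tools with default settings.  Intervals
extending past a chromosome edge are clipped at read time with a logged
warning.  Sorting is chromosome (genome-layout order), then start, then
end.  Interval shuffling preserves the multiset of lengths and places
each interval uniformly over all valid genome-wide positions, so
chromosome assignment probabilities are proportional to (length − size
+ 1).

## Element definitions and commonality

Promoter windows are strand-symmetric TSS ± flank (activity analyses use
flank = 1,000 bp; methylation analyses use an independent flank of
2,000 bp).  The non-promoter filter for enhancer calling is a peak-level
predicate: a single base of overlap with any promoter window discards
the whole peak, with no trimming.  Enhancer ids are derived from the
merged element's coordinates (`enh|chrom:start-end`), so catalogs are
reproducible across runs.  Promoter exclusion uses all transcripts, not
only protein-coding ones (configurable through the TSS table contents).

Commonality is a hard threshold on the per-element row sum of the
boolean activity matrix: at least 20 of the cohort's samples for
H3K4me3 promoters/genes, 10 for H3K27ac, 4 for enhancers.  The partition
is exhaustive, exclusive, and invariant to sample order.

## Signal profiles

Anomalous-position masking computes the count mean and standard
deviation over positions carrying at least one read, per sample (the
reference population is not prescribed elsewhere; covered positions make
the statistic independent of genome size), and masks positions with
z > 7.  Library size is counted before masking, so masking lowers a
sample's recovered signal rather than renormalizing it.  Binned tracks
are reads per million mapped in 500-bp non-overlapping bins; abundance
of a TSS ± 2 kb region is the unweighted mean of (ChIP − input) over all
bins overlapping the window — partially overlapping bins count fully.
Regions whose window intersects the annotated span of a different gene
are excluded.  Top-decile selection ranks regions by the group-mean
difference, breaking ties by region id, and returns the top
⌈fraction · N⌉; group-level abundance averages per-sample region
abundances across the group's samples.  Metaprofiles use 10-bp bins and
a centered running mean of window 15 with shrinking windows at the
edges; the confidence band is mean ± 1.96 SEM over (region, sample)
rows.

## Sample structure

Sample similarity is the Jaccard index of active-promoter sets (defined
as 1 when both sets are empty).  Clustering is UPGMA on distance
1 − J, implemented in-repo with a deterministic tie-break
(lexicographically smallest cluster-index pair) and verified against
scipy's average-linkage cophenetic distances.  The dendrogram exports
Newick with branch lengths equal to merge-height differences.

Group-specific promoter calling combines count gates with a one-sided
Fisher exact test (the gates already impose direction, so sidedness
follows the gate direction).  With the default gates on a 5-vs-13
comparison, the patterns that pass all three rules are exactly
(5 active, ≤ 2), (4, 0): the Fisher threshold 0.003 eliminates (4, 1)
and (4, 2).

TFBS enrichment counts every (site, promoter) intersection event and
reports per-megabase fold changes; a factor with zero reference hits but
positive target hits is +inf, a factor absent from both is NaN.
Conservation comparison takes per-interval mean scores over covered
bases of the score track (uncovered bases are absent from the mean, not
zeros) and applies a one-sided Mann–Whitney U test (elements greater),
exact for samples of ≤ 20, tie-corrected asymptotic otherwise.

## Contact calling

The distance-decay null is estimated per chromosome from *all* bin pairs
at each distance (implicit zeros included): μ_d is the stratum mean and
the negative-binomial dispersion α_d comes from the method of moments
(α = (var − μ)/μ², floored at 0, which reduces to Poisson).  Strata with
fewer than 50 pairs are pooled with geometrically growing windows of
adjacent distances.  Upper-tail p-values are exact NB/Poisson survival
probabilities; calls use raw p < 0.001 with no multiple-testing
correction, and BH-FDR values are reported alongside for transparency.
Anchors spanning several bins contribute the union of their bins' calls,
deduplicated per (anchor, target bin) keeping the smallest p.  This
caller is this package's own reimplementation of distance-corrected
contact significance; no equivalence with any particular published tool
is claimed.  One note on invariants: doubling every count and refitting
preserves the p-value ranking exactly within a distance stratum; across
strata the discrete Poisson tail can reorder near-tied p-values at the
10⁻⁴ level.

Target–promoter enrichment compares the fraction of called target bins
overlapping promoter windows against uniformly re-placed bin sets, with
an add-one empirical p.

## Co-activation

Quantile normalization maps every column onto the vector of row-wise
means of sorted columns; tied values receive the mean over their rank
range, and the operation is idempotent.  For the promoter-mark
correlation, the transcript with the highest mean normalized coverage
represents its gene, and Spearman R is pooled over all (promoter,
sample) points.  Closest-transcript assignment treats a transcript as
its TSS point; the distance is zero when the TSS lies inside the
element, otherwise the gap to the nearer edge, with ties going to the
smaller coordinate.  Stratum boundaries: < 20 kb proximal, 20–200 kb
inclusive mid, > 200 kb distal.  Contact-derived enhancers linked to
several promoters contribute the mean expression over their contacted
transcripts as the pairing value.

The resampling comparison draws pair subsets of fixed size without
replacement from the reference population (closest pairs with distal
targets when enough exist; on gene-dense genomes where distal closest
pairs are structurally absent, the full closest-pair set is the
fallback, logged) and reports p = (1 + #{null R ≥ observed})/(1 + reps),
upper tail — contact pairs are expected to be the more correlated set.

Per-pair significance across samples uses the exact permutation
distribution of Spearman R when there are ≤ 9 samples and the two-sided
t approximation otherwise; BH-FDR is computed over all tested pairs
(not only a pre-filtered subset).  The final gates are FDR < 0.1,
R > 0.7, and a maximum-over-samples raw transcript count of ≥ 20.

## Methylation

Beta values are classified with closed outer intervals: β ≤ 0.2
hypomethylated, β ≥ 0.8 hypermethylated (boundaries belong to the outer
classes; configurable).  Promoter methylation is the mean β over CpGs in
the ±2 kb window; windowless promoters are omitted.  Group comparisons
use a two-sided Mann–Whitney U on per-sample mean levels over a promoter
set — a declared substitute where no specific test is prescribed.

## Synthetic cohort

The generator plants, on a 2 × 5 Mb genome, an interleaved lattice of
gene and enhancer slots whose geometry guarantees that promoter windows,
gene spans and enhancers never collide across slots.  Defaults: 24
samples (5 PA, 6 DA, 13 GB), 300 genes (~360 transcripts; every fifth
gene has two), 400 enhancers, half of genes / 45% of enhancers common,
30 PA-specific and 30 GB-specific promoters, 20 correlated
enhancer–transcript links (Spearman ρ = 0.9) among 200 uncorrelated
decoy loops, loop strength 10× the decay expectation, contact decay
μ_d = 100/d at 10 kb resolution, library size 100,000 reads per track,
promoter-mark/expression coupling ρ = 0.6, methylation shift Δβ = 0.3,
peak dropout 0.05 and spurious activation 0.01.

Design choices worth knowing:

* **Noise is asymmetric.**  Dropout (a peak-caller miss on a truly
  active element) and spurious activation are separate rates, and
  coverage signal follows the *planted* design — a dropped-out peak
  still leaves its reads, as a missed call would in real data.  The
  group-specific promoter design is kept free of spurious activation in
  its contrast group: its activity pattern is the planted contrast
  itself.  Under pure dropout ε the analytic sensitivity of the
  PA-specific caller is P(Binom(5, 1−ε) ≥ 4) ≈ 0.92 at ε = 0.1 and
  ≈ 0.98 at the default 0.05.
* **Rank coupling via a Gaussian copula.**  Expression counts are
  negative-binomial quantile-mapped from latent normals correlated with
  element intensities at r = 2·sin(πρ_S/6), so the target Spearman is
  planted exactly up to read noise.  Correlated links target common
  (constitutively active) promoters, because the expression of a
  variable promoter is dominated by its on/off pattern and would mask
  the planted ranks.  Expression at designed-inactive promoters is
  scaled down 20-fold, so mark presence and expression co-vary as the
  promoter-correlation analysis assumes.
* **Read-level realism is limited.**  Reads are independent positions
  (no fragments, no duplicates, no GC bias); measured link correlations
  attenuate from the planted 0.9 to ≈ 0.85 through Poisson coverage
  noise, comfortably inside the ±0.1 recovery band.  A few planted hot
  positions (400 reads each) exercise the z-mask.
* **Planted loop geometry.**  Correlated links sit 50–600 kb from their
  targets (5–60 bins), where a 10× loop is detected at α = 0.001 with
  per-link probability > 0.99; decoys spread to 1.5 Mb, where long-range
  decoys are only partially detected — intentionally, as in real decay
  backgrounds.  With ~220 loops over ~2 × 200 distance strata, loop
  pairs inflate the fitted NB dispersion slightly; the planted-recovery
  margins absorb this.
* **Per-sample coverage is emitted at 500 bp resolution; 10-bp tracks**
  (for metaprofiles) are pooled per group and restricted to TSS ± 2 kb
  windows, keeping the on-disk cohort ~50 MB and generation under ten
  seconds.  Per-position masking and 10-bp binning are therefore
  exercised inside the generator and in unit tests rather than from
  disk.

What passing the planted-recovery tests shows: the chain of
definitions, thresholds and statistics recovers structure of the stated
effect sizes at the stated cohort size under idealized noise.  What it
does not show: robustness to mappability artifacts, copy-number
alterations, batch effects, tumor purity variation, or peak-caller
idiosyncrasies — none of which the generator emulates.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the default cohort
(24 samples, 10 Mb genome) end to end in tens of seconds; calibration
checks use 2 × 500-bin contact maps and a 300-replicate resampling
grid.  These sizes were chosen so that planted effects are measurable
with comfortable statistical margins while a full validation cycle
stays interactive.  All randomness flows from a single integer seed
(`numpy.random.default_rng`); regenerating a cohort and rerunning the
pipeline with the same seed produces byte-identical files, which the
stage-memoization stamps rely on.

## Known limitations

* The contact caller assumes a banded, single-resolution,
  intra-chromosomal map without balancing/ICE normalization.
* The exact-permutation path for per-pair Spearman p-values enumerates
  all n! pairings and is only used for n ≤ 9 samples.
* TFBS enrichment counts intersection events, which double-counts sites
  spanning two promoters; with typical site (~200 bp) and window (2 kb)
  sizes this is rare.
* The resampling reference population falls back from distal closest
  pairs to all closest pairs on gene-dense genomes (including the
  default synthetic one).
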
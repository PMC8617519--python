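# Methods

This note documents the models behind `cinsig`, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real data.

## The analysis problem

In shallow single-cell DNA-seq of a clonally structured epithelium, each
cell yields ~10⁵ reads covering 0.5–1% of the genome. That is enough to
call per-cell copy number at sub-megabase bins, but far too little to call
point mutations per cell; single-base substitutions become measurable only
when pooled over clusters of cells. The pipeline therefore (a) clusters
cells by copy number, (b) assembles cluster-level somatic variant sets
through a filter cascade that substitutes for a missing matched germline
control, and (c) asks how much of each cluster's trinucleotide spectrum is
explained by signatures of interest — here the SBS17 pair (SBS17a: T>C in
the CTT context; SBS17b: T>G in NTT contexts) whose appearance tracks
chromosomal instability.

## Copy number

**Normalization.** Counts are divided by the bin weight (partial terminal
bins carry proportional weight), then each cell by its median, times 2.
Every profile has median exactly 2; this assumes the majority of each
cell's genome is diploid. When aberrations approach half the genome the
median shifts and all copy-number levels are compressed or inflated by a
common factor (visible in segment means like 2.8 for a true 3-copy gain);
cluster separation and gain/loss calls are unaffected as long as the
diploid state still holds the median. Cells with a zero median are rejected
by name, never silently dropped.

**Clustering.** Ward linkage on Euclidean distance between profile vectors.
The number of clusters `k` is a per-sample user choice, mirroring how such
data are analyzed in practice; a silhouette-score suggestion is logged but
never applied automatically. Cells are processed in lexicographic barcode
order and relabeled `cluster_1..k` by decreasing size, so results do not
depend on input order.

**Circular binary segmentation.** Per contig, the arc `(i, j]` maximizing
`T(i,j) = |mean_in − mean_out| / sqrt(1/n_in + 1/n_out)` is found by
exhaustive search (the statistic's scale factor cancels under permutation,
so no variance estimate is needed). The split is accepted when the
permutation p-value of the max statistic is below `alpha = 0.01`
(1,000 permutations, add-one correction, seeded RNG, minimum segment width
2 bins), then both sides are segmented recursively. Two consequences worth
knowing: (i) the permutation null is granular — a profile of fewer than
~14 bins cannot reach p < 0.01 even for a perfect step, because a
non-negligible fraction of permutations recreates the step; contigs are
therefore binned to ≥20 bins by default; (ii) alpha is a per-segment
false-positive rate, so roughly 1% of tested flat segments acquire a
spurious breakpoint — the acceptance tests bound rather than forbid this.

**CS labeling and CIN regions.** A cluster's aberrant fraction is the
weighted genome share in segments with `|mean − 2| > cn_delta` (0.5, half a
copy). The minimum-aberrant cluster is flagged chromosomally stable iff its
fraction is ≤ `cs_max_aberrant` (0.05); otherwise no CS flag is set and a
warning is raised. Ties break to the larger cluster, then the smaller
label. Segments beyond `cn_delta` become gain/loss regions; adjacent
same-direction regions merge; shared regions across samples are plain
same-direction interval intersections (commutative and associative). Genes
can be restricted to stable regions with an any-overlap exclusion rule.

## Variant filtering

The cascade runs MQ → blacklist → cross-patient shared → CS-overlap →
Fisher, each step returning a new matrix with an audit-trail entry
(attrition is monotone by construction):

* **MQ:** strictly greater than 20 (single-cell mode) or 60 (bulk WGS
  mode, where a VAF > 0.3 filter also applies). Variants with missing MQ
  are unqualifiable and dropped, with a count.
* **Blacklist:** exact-key matching on (contig, pos, ref, alt) — the
  conservative reading of "known germline variant"; a different alternate
  allele at a blacklisted position survives.
* **Shared-between-patients:** a key observed (≥1 supporting cell) in every
  patient is removed everywhere; with one patient the step is an audited
  no-op.
* **CS-overlap:** any variant supported by ≥1 CS-cluster cell is removed
  (the threshold "≥1 cell" is a choice; a fraction-based rule would also be
  defensible but is not implemented). Zero-support rows are dropped here as
  unobserved.
* **Fisher:** per (variant, cluster), the 2×2 table of supporting cells
  inside/outside the cluster, one-sided (enrichment) by default since the
  question is directional; two-sided and Benjamini–Hochberg correction are
  available by flag but off by default, matching the plain p < 0.05
  convention. p-values are upper hypergeometric tails.

**A coverage-driven design choice.** With 50-cell clusters at 0.5–1%
coverage, a clonal variant is observed in ~0.4 cells on average, and a
one-sided Fisher test needs ≥5 observing cells (50 vs 50, none outside) to
reach p < 0.05 — so per-variant enrichment is statistically out of reach at
this depth, and an enriched-variants-only spectrum would be empty. The
pipeline therefore computes and exports enrichment results as specified,
but builds each cluster's spectrum from its *supported* variant set (≥1
supporting cell in the cluster after the cascade) by default;
`spectra_from="enriched"` switches to the strict set for deeper data.
Relatedly, the CS cluster's own (baseline) spectrum is necessarily built
*before* the CS-overlap step, which by construction removes every
CS-supported variant.

## Spectra and refitting

Spectra are 96-channel, pyrimidine-centered, substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G × 16 flank pairs); purine-reference variants
are strand-collapsed, and N-context variants are skipped and counted.
Channel counts are normalized by `(100000 / reads_per_cell) ×
(0.01 / covered_fraction)` using the cluster's mean per-cell reads and
covered fraction — the product-of-linear-factors form is an interpretive
choice; both inputs are recorded in the spectrum metadata. Subtraction of
the CS baseline is channel-wise with negatives clipped to zero, on matching
scales only (a proportions mode is available by flag). A pooled baseline
(cell-count-weighted mean of CS spectra across samples) smooths the
sampling noise of individual CS clusters.

Refitting is non-negative least squares of the spectrum on the selected
catalog columns. `fraction_explained = Σ reconstructed / Σ observed`,
clipped to [0, 1] (NNLS can overshoot the total when the residual is
orthogonal-ish to the observation; after baseline subtraction of a
concentrated spectrum the clipped value of 1.0 is common); the cosine
between observed and reconstructed is reported alongside, since "explained"
has no single canonical definition. Reports carry both the raw and the
baseline-subtracted refit per cluster — for the CS cluster the subtracted
spectrum is identically zero under a per-sample baseline, so its raw refit
is the informative number.

**INDEL channels.** 1-bp insertions/deletions are collapsed to the
pyrimidine base and binned by the homopolymer run length adjacent to (for
deletions: including) the event, bins {1,2,3,4,5+}; ≥2-bp insertions whose
unit tandem-repeats immediately 5′ of the insertion point are binned by
pre-existing copy count {1,2,3+}; everything else is `other_del`/
`other_ins`. This is deliberately a compact scheme targeting poly-T and
repeat-stretch events, not the full COSMIC ID83 taxonomy.

**Proxy catalog.** `SBS17a-proxy` (0.90 on C[T>C]T, 0.10 flat),
`SBS17b-proxy` (0.225 on each N[T>G]T, 0.10 flat), `clocklike-proxy`
(0.60 over the four N[C>T]G CpG-deamination channels, 0.40 flat) and
`flat-proxy` (uniform). These are synthetic stand-ins with the right
channel support, suitable for validating machinery; conclusions about real
samples require a real catalog TSV (COSMIC layout), which `load_catalog`
accepts.

## The simulator

One seed drives independent substreams for reference, cell table, counts
and variants, so stages can be re-run separately yet consistently, and
identical configs give byte-identical outputs. Defaults describe the study
conditions: 4 contigs × 10 Mb, 500-kb bins, 50 cells per clone, lognormal
total reads around 100,000 (σ = 0.25 — the per-cell depth distribution of
a real plate is not known, this is a modeling choice), covered fraction
uniform on (0.005, 0.01), negative-binomial bin counts with dispersion 10
(shallow single-cell counts are overdispersed; dispersion → ∞ recovers
Poisson), 500 germline SNPs, 5% of variants at MQ 10 (the rest 60).
Somatic variants are drawn channel-first (multinomial over the mixture's
96-channel probability) and placed uniformly on context-matching sites
without collision, on either strand; germline variants are placed uniformly
and carried by all cells; observation per carrying cell is
Bernoulli(covered fraction).

What the simulator does **not** model: read-level data (no FASTQ/BAM),
doublets, GC or replication-timing bias, mappability structure, the strong
site-recurrence of restriction-enzyme-anchored protocols (observation is
independent across cells, which makes per-variant statistics *harder* than
in such protocols), allele fractions, or INDEL generation. Passing tests
therefore demonstrate correctness of the machinery under a clean
generative model, not performance on real libraries.

## Problem sizes and numerical conventions

Tests and the acceptance script run a 40-Mb genome, 100 cells and 2,000–
3,500 variants — scaled-down but structurally faithful analogs chosen so
the whole suite completes in minutes. Coordinates are 0-based half-open
internally, 1-based in VCF, BED-convention in interval tables. Variant
sites avoid contig ends so trinucleotide contexts always exist. All
tabular output uses fixed float formatting, and every tie in the pipeline
(cluster naming, CS flag, arc selection) breaks deterministically, so
re-runs are byte-identical. The CBS permutation RNG is seeded per
(cluster, contig) from the run seed via a CRC of the cluster label.

## Known limitations

* Median normalization mis-scales profiles when aberrations reach ~half a
  cell's genome; a mode-based normalization would be more robust but is
  not implemented.
* CS labeling assumes at most one near-diploid cluster; two genuinely
  stable clusters tie-break by size rather than being merged.
* The CS-overlap filter is sensitive to cluster contamination when
  coverage is dense: a single misassigned unstable cell can veto many true
  somatic variants. At the sparse default coverage the effect is
  negligible; with dense data, inspect the clustering before trusting the
  cascade.
* `fraction_explained` saturates at 1.0 by construction and should be read
  together with the reported cosine.
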
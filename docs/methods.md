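# Methods

`metapyro` reimplements, as a tested library, the bespoke computational
stages of a pyrosequencing metagenome survey of an anaerobic
(biogas-producing) microbial community: read-level normalization
against a GC/length bias, confidence-filtered taxonomic and functional
profiling, diversity estimation, strain-variant resolution of a marker
gene, and reference-coverage analysis stratified by horizontal gene
transfer (HGT) prediction.  Every stage can be exercised end to end on
a synthetic community whose ground truth is recorded per read, so the
recovery properties of each method are measurable rather than assumed.

## GC-bias endpoint detection (read_qc)

Long pyrosequencing reads show a systematic decline in mean GC:
GC-rich single-stranded fragments form secondary structures during
emulsion PCR ("backfolding") that truncate amplification, so long reads
are AT-enriched.  In a metagenome, where fragment GC spans a wide range,
this depresses the apparent abundance of GC-rich organisms unless the
affected read-length range is removed.

The detector works on the profile of mean GC per integer read length:

1. Profile points supported by fewer than `min_reads_per_point`
   (default 20) reads are dropped — sparse length classes in the tail
   otherwise dominate the residual variance.
2. An ordinary least squares line is fitted to 30 points starting at
   the first length ≥ 100 bp (the early, high-variance region is
   skipped).
3. Points beyond the window are tested in increasing length order as
   *new* observations against the current fit, using the externally
   studentized prediction residual
   `t = e / sqrt(s² (1 + 1/m + (x − x̄)²/Sxx))`, which under the linear
   null is t-distributed with `m − 2` degrees of freedom for a fit of
   `m` points (equivalently `n − 3` when the candidate is counted in
   the fit set).  A two-sided p-value below `alpha = 0.05` flags an
   outlier.
4. Non-outliers are absorbed into the fit set and the line refit
   (running-sums update, O(1) per point); outliers are never absorbed.
   The first run of 10 consecutive outliers terminates the scan, and
   the length of the run's first point is the filtering threshold.
   Reads *strictly longer* than the threshold are removed.

The expanding fit set is a deliberate choice: a fixed 30-point fit
leaves the t-test with few degrees of freedom and makes far
extrapolation so uncertain that moderate drops are missed
(`fixed_window=True` exposes that behaviour).  A one-sided,
decline-only mode exists for users who want directional testing; the
default is directionless.  Detection is invariant under adding a
constant to all profile means, since only the intercept changes.

Measured on synthetic profiles with an abrupt drop of 5 point-noise
standard deviations, the endpoint is recovered within ±25 bp in ≥ 90 of
100 seeded replicates, and without a planted drop the detector stays
silent in ≥ 95 of 100 (run lengths of ten consecutive false rejections
at α = 0.05 are vanishingly rare).

## Duplicate removal (read_qc)

Emulsion-PCR duplicates are near-identical reads starting at the same
template position.  Removal is greedy: reads are bucketed by their
exact first 20 bases, processed in descending length, and a read is
collapsed into an earlier representative when it aligns end-gap-free
against the representative's leading region with ≥ 96% identity over
the read's length (edit distance via edlib's prefix mode).  The longest
read of each cluster is kept.  The procedure is idempotent, and the
filter report always conserves reads
(`in = out + removed_length + removed_duplicates`).

## Taxonomic profiling (taxonomic_profiling)

Assignments arrive as per-read lineages with per-rank confidences, the
shape produced by naive-Bayes 16S classifiers and by protein-fragment
(EGT) classifiers.  Filters: marker-gene alignments need ≥ 50 bp
aligned length and E-value ≤ 1e-5 (the E-value default is
configuration — see "open parameters" below); assignments need ≥ 80%
confidence at the profiled rank.  Both boundaries are inclusive.

Reads with several classifications are merged to the lowest common
ancestor (LCA): the deepest node that is ancestor-or-self of every
input.  LCA merging is commutative, associative and idempotent, and
never yields a node deeper than any input — properties tested against
a brute-force ancestor-set-intersection oracle on random trees.
Missing intermediate ranks are pass-through: a node's ancestor at rank
r is absent only when its lineage genuinely ends above r, and such
reads are counted in an explicit "unclassified at rank" bucket rather
than dropped.  Percentages use the full normalized dataset size as
denominator.

## Function × taxonomy (functional_context)

Per-read orthologous-group (COG) hits are reduced to the best E-value
hit (ties broken lexicographically, so the join is deterministic) and
inner-joined with the taxonomic assignments on read id.  A COG →
(pathway, subcategory) map — data, not code; the shipped TSV covers
cellulose/hemicellulose/lignin degradation, the Wood-Ljungdahl pathway
and methanogenesis marker groups, and is an editable stand-in for a
full curated list — selects the reads in each fermentation context.
Counts aggregate over the taxonomy tree: a node's count is the number
of pathway reads at or below it, its residual (the bracketed number)
is `count − Σ child counts`, and subcategory tallies normalize to pie
fractions per node.  Aggregation conserves reads (root count = joined
pathway reads) by construction.

Best-hit tallies per reference locus are a multiset count; each read
contributes to exactly one locus, so the tally sums to the number of
reads with hits.

## Diversity (diversity)

Shannon index `H = −Σ pᵢ ln pᵢ` over genus relative abundances, natural
log (the reported magnitudes for communities of 16–38 genera, ≈ 1.9 to
2.6, are ln-scale; base is configurable), zero-count categories
excluded.  `H ≤ ln S` with equality iff uniform.

Datasets of unequal size are compared by subsampled Shannon: the mean
index over uniform without-replacement subsamples matched to the
smaller dataset, 5,000 iterations by default.  Subsampling is at the
read level and re-applies the confidence filter inside each subsample;
a category-level multivariate-hypergeometric mode is provided as a
fast path and is distributionally identical (reads below the threshold
become one category that never contributes to the index) — the two
modes are tested for agreement.

Analytic rarefaction gives the expected category richness of a
subsample of size n in closed form,
`E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]`, with `C(a,b) = 0` for `a < b`,
evaluated via log-gamma for stability at large N.  `E[S₁] = 1`,
`E[S_N] = S`, and the curve increases strictly until every category is
expected.  Correctness is checked against full subset enumeration for
small totals and exact integer binomials for larger ones, and against
Monte-Carlo subsampling.  The default curve grid is 50 evenly spaced
sample sizes.

## Variant binning (variant_binning)

Closely related strains carry marker genes differing at a handful of
positions; their reads cannot be co-assembled, but can be separated by
substitution content.  Each read is aligned semi-globally to a
reference copy (Bio.Align's dynamic programming; match +1, mismatch −1,
gap −2, free end gaps on the reference so the read sits at its best
offset).  Its SNP signature is the set of (reference position, base)
substitutions, ignoring gap columns and the 5 aligned bases at each
read end (`end_trim`, guarding against alignment-edge artifacts); the
signature's covered interval is correspondingly the trimmed span.
Indels are excluded throughout — in this sequencing technology
homopolymer indel errors would otherwise dominate every signature.

Clustering is greedy in descending signature size with three
robustness elements beyond the naive "join on one shared SNP" rule,
each answering a measured failure mode of that rule at realistic error
rates:

- **Majority signatures.**  A group stores per-position base-support
  counts over its members; its signature carries a base only where
  more covering members observed it than observed the reference.
  Isolated sequencing-error SNPs therefore wash out of the signature
  instead of accumulating (a union signature lets an error in an early
  read permanently poison the group).
- **Majority joining.**  A read joins the first group that agrees with
  it at a majority of the read's SNP positions the group covers, with
  at least `min_shared` (default 1) co-observed SNPs.  Requiring the
  majority — not just one shared site — prevents a single error SNP
  that coincides with another variant's diagnostic site from chaining
  unrelated groups.  SNP-free reads join a group only where the group
  overlaps them and is SNP-free there.
- **Refinement and merging.**  A reassignment pass re-tests every read
  against the groups in descending size order, undoing greedy order
  dependence (early reads can found fragments before any group covers
  their region).  Groups whose covered intervals overlap and whose
  signatures agree there (same majority criterion, both directions)
  are merged; two SNP-free groups merge only over a long (≥ 200 bp)
  overlap, since a short SNP-free sliver carries no evidence of
  identity.

The whole procedure is deterministic for a given input order and
independent of read ids.  On error-free data with full mutual coverage
the group count equals the brute-force minimal compatible partition
(tested exhaustively on toy mixtures); at the pipeline's reference
condition — 132 reads of 200–400 bp from 7 variants at 0.5% error —
the 7 groups are recovered with ≥ 95% partition accuracy.  Variants
whose read sets leave a literal coverage gap on the reference are
unlinkable by SNP content and correctly remain split; the real mixture
this emulates produced partial consensus sequences for the same
reason.

Consensus is reference-guided majority per column over the group's
members: ties resolve to the reference base, columns below `min_depth`
are emitted as lowercase reference (partial-consensus marking).  A
commercial de novo assembler played this role in the original
workflow; for marker-length sequences the reference-guided majority is
sufficient and fully testable.

## Reference coverage and HGT stratification (reference_coverage)

Coordinates are 0-based half-open throughout; 1-based closed
annotation is converted at the parser boundary.  Covered fraction is
the measure of the interval union over the genome length (equal to a
per-base bitmap, tested up to 100 kb).  Per-gene mapped bases sum the
overlaps of all read intervals with the gene's coding interval
(depth-weighted, strand-symmetric); dividing by gene length and then
by the across-gene median depth puts normalized coverage on a unitless
O(1) scale.  The median scaling is what makes a fixed kernel bandwidth
of 0.4 meaningful; a raw bases-per-length mode is available behind
`median_scale=False`.

Densities use the Epanechnikov kernel `K(u) = 0.75(1−u²)` on `|u| ≤ 1`,
`f(x) = (1/nh) Σ K((x−vᵢ)/h)`, bandwidth 0.4, evaluated on a grid
spanning the data padded by one bandwidth (so the estimate integrates
to 1 within trapezoid accuracy).  The HGT comparison reports densities
for HGT-flagged genes, remaining genes and all genes on one grid, plus
group means/medians and the median difference as the location-shift
summary; an empty stratum is reported explicitly rather than raised.

## The synthetic community (synthetic_community)

The generator emulates, with recorded ground truth, exactly the
phenomena the pipeline targets:

- **Community**: 9 taxa with full seven-rank lineages, genome GC 0.37
  to 0.62, abundances 5 to 30% — cellulolytic and fermentative
  Firmicutes/Bacteroidetes dominating, hydrogenotrophic
  Methanomicrobiales among the Archaea, mirroring the composition of
  anaerobic digester communities.
- **Reads**: lengths from a truncated normal (mean 380, sd 110,
  range 60–700 bp, a Titanium-era distribution); per-read GC from a
  beta distribution centred on the taxon GC (concentration 50 —
  bounded in [0,1] with realistic within-genome spread), shifted by an
  optional linear drift below the planted breakpoint `L*` and reduced
  by `backfold_gc_drop` per base beyond it; sequences are then random
  with that per-base GC probability, so per-length profile noise is
  genuinely binomial.
- **Duplicates**: a configurable fraction of reads are copies of a
  random original from the same start, truncated up to 10% with up to
  2% substitutions placed beyond the first 20 bases (pyrosequencing
  error concentrates toward read ends, and the shared template start
  stays recognizable — the property duplicate detection keys on).
- **Classifier tables**: true lineages with a mislabeling rate (the
  read receives another member's internally consistent lineage, with
  depressed confidence at and below the mislabeled rank) and a
  confidence spread; with zero noise every confidence is exactly 1 and
  the tables equal the truth.  COG hits are drawn from the shipped
  pathway map with log-uniform E-values.
- **Variant mixtures**: 7 variant SNP sets with one site per 40 bp
  window at per-window offsets drawn without replacement, so variant
  sites are pairwise disjoint; ≈ 2.5% divergence, the upper range for
  congeneric 16S copies, chosen so 200–400 bp reads each cover several
  diagnostic sites.  Reads are uniform windows with i.i.d. substitution
  errors.
- **Mappings**: uniform candidate reads over an annotated genome;
  reads overlapping an HGT-flagged gene survive with probability
  `1 − hgt_depletion`.

All randomness flows from integer seeds through numpy Generators;
every output is bit-reproducible for a fixed seed.

What the generator does *not* emulate — and hence what green tests do
not claim about real data: flowgram-level error structure (homopolymer
indels), chimeric reads, within-genome GC heterogeneity, classifier
biases correlated with taxonomy, and real 16S secondary-structure
constraints.  The generator validates the *algorithms'* recovery
properties under controlled conditions, not the instruments.

## Pipeline and reproducibility

`run_pipeline` chains generate → qc → profile → function → diversity →
variants → coverage from one config (YAML or programmatic), with
per-stage enable flags.  The global seed is split into per-stage
substreams via numpy's `SeedSequence`, so stages are individually
reproducible; the manifest records per-stage parameters, counts and
sha256 checksums of every output, and reruns are byte-identical.  A
stage failure aborts with the stage named and leaves a `.partial`
marker in the run directory.  The bundled demo (20,000 reads,
breakpoint at 400 bp, 10% duplicates, 5% classifier noise, 7 variants,
80% HGT depletion) runs in well under a minute and satisfies every
conservation law; test and demo problem sizes throughout were chosen
so the whole suite completes in a few minutes on one CPU.

## Open parameters and known limitations

- The marker-hit E-value cutoff is not recoverable from the source
  description and is configuration (default 1e-5, inclusive).
- Whether the original endpoint scan refit progressively or tested
  against the initial window only is not documented; both modes are
  exposed (`fixed_window`), with progressive refitting the default for
  the degrees-of-freedom reason above.
- Whether subsampled Shannon refiltered per subsample or subsampled
  the already-filtered assignments is likewise open; both exist
  (`mode="read"` refilters; `mode="category"` is the fast equivalent).
- Dataset-scale results from the original study (filtering thresholds
  of 262/535 bp, Shannon 1.90/2.51/2.58, 39.8–45.4% genome coverage)
  require the deposited sequencing runs and are reference points, not
  desk-scale test targets; the synthetic conditions here are chosen to
  exercise the same machinery at comparable magnitudes.
- Variant binning cannot link read groups separated by a coverage gap,
  and reads whose errors hit their own diagnostic sites may remain
  unclustered singletons; both are reported honestly in group output
  rather than forced into clusters.
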
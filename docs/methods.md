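# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `rpa`. Everything empirical stated here is computed by
the test suite or by `scripts/acceptance.py`.

## The unit of analysis: read profiles

Small processed RNAs leave characteristic stacks of reads at their host
locus. We call a stack a *block* and the ordered set of blocks at a locus in
one sample a *block group* or *read profile*. Differential processing is a
change in the **shape** of the profile between sample groups — which block
dominates, how reads are arranged within blocks — not a change in overall
abundance. All genomic coordinates are 0-based half-open; strand is always
explicit.

## Block detection

Reads separated by less than `max_gap = 50` nt belong to one locus (typical
short-RNA reads are 17–40 nt, so a ≥ 50-nt read-free gap separates
independent transcriptional units). Within a locus, blocks are found by an
iterative Gaussian-peak procedure: each read contributes a Gaussian density
centred at its midpoint with σ = `scale × read_length` (`scale = 0.5`),
weighted by its collapsed count; densities are evaluated on integer
positions only. The highest peak (leftmost on ties — determinism) seeds a
block; a read joins it when its midpoint lies within ± `2 × scale ×
read_length` of the peak centre, a capture window that absorbs one read
stack while separating stacks more than ~2σ apart. The window factor is
configurable. The procedure is validated against an exhaustive brute-force
peak search at 1-nt resolution (oracle tests), not against bit-identity to
any particular external implementation.

Block groups with fewer than `min_cluster_height = 10` reads are discarded;
blocks holding less than `rel_block_cutoff = 10%` of the group's reads are
removed (measured against the pre-filter group total). The relative — not
absolute — cut-off keeps profiles comparable across libraries sequenced to
different depths; an absolute mode (`abs_block_height`) exists for
compatibility.

## Cross-sample harmonization

Only loci with an overlapping (same strand, ≥ 1 nt) block group in **every**
sample are analyzed. Consensus block coordinates are built by greedy
merging, processing blocks by descending height (the merge order is
otherwise undefined, and height order makes the result deterministic and
anchored on the strongest signals): a block joins an existing coordinate at
reciprocal overlap ≥ 90%, else it seeds a new one, so any two consensus
coordinates overlap < 90%.

Each sample's profile is then rebuilt on the consensus coordinates: one
dummy pseudoread (count 1, flagged) plus all raw reads whose **midpoint**
falls inside the coordinate. Midpoint assignment prevents a read on the
boundary from being counted in two adjacent coordinates. This restores raw
expression to blocks that the 10% cut-off had removed in some samples, and
guarantees every profile has the same block structure. The single
pseudocount also acts as a continuity correction for empty blocks in the
exact tests below; it is excluded from entropy and size-factor computations.

When every profile at a locus has exactly one block, a shared dummy block is
appended (10 nt downstream of the consensus block, 20 nt wide, expression
10% of the parent group's raw total, rounded up): the profile aligner needs
at least two blocks, and a block that is identical in every sample by
construction cannot drive between-sample differences. Width, gap and side
are not biologically meaningful; neutrality by construction is the design
criterion. Harmonization is idempotent.

## Profile alignment

The similarity of two profiles is scored in two tiers. Tier 1 scores block
pairs: with h the block height divided by the profile total and p the
block's count-weighted distribution over (read start − modal read start,
read length),

σ(x, y) = (1 − |h_x − h_y|) · max_s Σ_u min(p_x(u + s), p_y(u)),  |s| ≤ 3.

The modal-start anchor makes σ translation invariant; the small-shift
maximization absorbs the anchor's ambiguity when two start positions carry
nearly equal weight (without it, two samples of the *same* jittered
distribution can anchor 1 nt apart and lose a third of their overlap mass).
Tier 2 chains block scores with a global match/skip dynamic program that
preserves block order (no crossing matches — genomic collinearity) and
charges nothing for skips; the final score is 2·(matched σ)/(m + n) for
block counts m, n. The scorer satisfies, and is property-tested for:
S ∈ [0, 1]; symmetry; S(a, a) = 1; invariance under joint translation and
under scaling one profile's read counts. Any scorer with these properties
can be plugged in behind `align_block_groups(similarity=...)`; the pipeline
depends only on the [0, 1] contract.

Profile entropy is the base-2 Shannon entropy of read start positions
weighted by count, dummy reads excluded; it is computed per block group.
Base 2 matches the ≤ 2-bit threshold used on the ~4-position profiles of
precisely processed RNAs; both scope and base are configurable.

## Differential processing

The locus's alignment score matrix S (all-vs-all, each pair computed once)
is clustered: objects are matrix columns, dissimilarity 1 − Pearson
correlation, average linkage — the conventional defaults for this kind of
similarity-profile clustering; both are configurable. Cluster support uses
multiscale bootstrap resampling: feature rows are resampled with replacement
at scale ratios r ∈ {0.5, …, 1.4}, BP_r(cluster) is the fraction of
resampled trees containing the cluster, and approximately-unbiased support
is fitted by weighted least squares on the probit scale
(z_r = Φ⁻¹(1 − BP_r) ≈ v√r + c/√r, AU = 1 − Φ(v − c)), each z_r weighted by
the delta-method variance BP(1 − BP)/(n φ(z)²). Two numerical guards: (a)
when BP is pinned at 0/1 across scales the regression degenerates, so the
reported support never falls below the plain BP at r = 1; (b) when all
pairwise distances are exactly tied (all profiles identical) the tree shape
is purely a tie-breaking artifact and no cluster receives support. A
`bp`-only mode (support = BP at r = 1) is available for speed. Everything is
deterministic given the seed.

For each supported cluster k (p = 1 − AU < 0.05, root excluded),
X_k = max(0, S̄_in(k) − S̄_out(k)) where S̄_in averages scores within k and
S̄_out averages in-vs-out pairs. S̄_in − S̄_out can be negative for poorly
supported clusters; clamping at 0 keeps the locus score X = mean_k X_k in
[0, 1] (clamping is logged). Candidates require **X ≥ 0.15**. With
replicates ("combined" mode), a cell line whose two replicates straddle a
cluster is excluded from that cluster's score, and candidacy additionally
requires a supported cluster with ≥ 4 member profiles (two per line).

## Expression validation

Size factors are computed once from the harmonized consensus-block counts of
*all* analyzed loci (dummy contributions excluded): s_j = median over
all-positive rows i of k_ij / (Π_m k_im)^{1/m}. Rows containing a zero are
skipped (the geometric-mean ratio is undefined there); if no row is usable
the computation fails loudly rather than silently degrading.

For a candidate locus, normalized block expressions b̂_ij = b_ij / s_j
(consensus blocks only; the +1 pseudocount included) are compared between
every sample pair with a two-sided exact conditional test of independence on
the m × 2 table, after rounding to the nearest non-negative integers (exact
tests need counts; rounding-boundary behaviour is unit-tested). For m = 2
the hypergeometric distribution is enumerated exactly; for m > 2 the p-value
is a Monte Carlo estimate of the exact conditional test using Patefield
sampling of tables with the observed margins and the conservative add-one
estimator (1 + hits)/(1 + 10⁴), which bounds the estimate away from
spuriously small values. A locus is a validated DPL iff in at least one
supported cluster a strict majority (> 50%) of in-cluster samples is
significant (p < 0.05) against **every** out-of-cluster sample; in combined
mode the majority is counted over cell lines, a line qualifying only when
both replicates do. Loci with a single consensus block cannot exhibit
differential block usage and never validate. No multiple-testing correction
enters the verdict; the summary carries an informational Benjamini–Hochberg
q-value column (`fisher_min_q`) over the candidates' smallest pairwise
p-values.

## Coherence

A locus is a coherently processed locus (CPL) when the mean of its
off-diagonal alignment scores is ≥ 0.8 (inclusive). A profile is *short and
precise* when it has exactly one non-dummy block, entropy ≤ 2 bits and a
non-dummy span ≤ 40 nt; dummy blocks are harmonization plumbing and are
ignored for the block count and span but kept in alignment, where, being
identical across samples, they cannot depress the mean score.

## Enrichment statistics

ncRNA labels need ≥ 1 nt same-strand overlap (larger overlap breaks ties);
genomic-region labels need > 50% coverage of the locus, maximum overlap
winning, else "intergenic". Feature enrichment uses the dart-throwing null:
hit probability = merged feature length / genome size (merging prevents
overlapping intervals from double-counting the null), p-value = upper
binomial tail of the observed ≥ 1-nt overlap count. The TSS metaprofile
splits ±1000 nt around each TSS into 100 bins of 20 nt and averages the
percent of each bin covered, separately for sense and antisense intervals;
minus-strand TSS are flipped so downstream is positive, and an interval near
two TSS contributes to both (contribution counts are reported). Chromatin
states and DHS-like features are treated as strandless.

## Synthetic data

The simulator emulates the phenomena the pipeline targets, with defaults
matching the study conditions of the bundled benchmark: 9 cell lines × 2
replicates; arm-switch loci with two ~22-nt blocks 44 nt apart (start to
start), dominant fraction 0.8, and 3 switched lines whose fractions are
mirrored; arm-loss loci where the minor arm falls below the 10% cut-off in
a subset; coherent loci (identical fractions everywhere; the one-block kind
uses ~17-nt reads, the short/precise regime); noise loci with per-sample
Dirichlet block usage and 3× start jitter; and depth-imbalance controls
(identical shape, a subset 5× deeper at the locus). Per-block counts are
multinomial in the line's fractions at depth 200 × a per-sample multiplier
drawn once per dataset from U(1, 5) (depth is a library property, so it
applies at every locus); read starts are jittered uniformly over ± 1 nt by
default (profile entropy is monotone in the jitter width — property-tested);
read lengths vary ± 1 nt around the mode (0.2/0.6/0.2). Replicates are
independent multinomial draws from the same line parameters — sampling noise
only; a Dirichlet-multinomial overdispersion switch is available on the
fractions. Everything is deterministic given the seed.

What the simulator does **not** emulate: sequence content and mapping
artifacts (multi-mapping, GC bias), cross-contamination between loci,
overdispersion beyond the optional Dirichlet switch, annotation complexity,
and biological covariation between loci. Passing the benchmark therefore
demonstrates that the statistical machinery recovers planted processing
differences under realistic depth variation and replicate noise — not that
real-data detections are free of mapping or library-preparation artifacts.

## Problem sizes and runtime choices

The bundled benchmark uses 55 loci (20 arm-switch, 20 coherent, 10 noise, 5
depth controls), 18 samples and 500 bootstrap replicates per scale — sizes
at which the full run takes on the order of a minute on one CPU and every
rate estimate has a denominator of 20 or more. The null calibration uses 50
same-condition loci. Unit tests use smaller n_boot (60–300) where only the
mechanism, not the support resolution, is under test.

## Known limitations

- The per-block scorer is this package's own realization of the published
  [0, 1] alignment-score contract; absolute score values are not comparable
  with other aligners, only the contract properties are guaranteed.
- AU support from 10 scales and moderate n_boot is a coarse estimate; near
  the 0.05 boundary decisions can flip between seeds. The benchmark effect
  sizes are far from the boundary.
- Size factors assume most blocks are not differentially expressed across
  samples, as median-of-ratios normalization always does; with very few
  analyzed loci the median is noisy.
- Combined-mode majority counting over cell lines (both replicates must
  qualify) is an interpretation choice; the per-sample alternative is
  available in independent mode.
- Multi-mapping reads are dropped (BAM secondary/supplementary flags); loci
  dominated by repetitive sequence are under-covered by construction.
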
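# Methods

This note documents the models and procedures `clonemap` implements,
the defaults it ships, and what its synthetic fixtures do and do not
establish about real data.

## Morphological grouping of cell clusters

Cell clusters on a stained section are the unit of both isolation and
analysis: genetic subclones express themselves in collective growth
morphology (size, elongation, orientation, spatial position) rather
than in single-nucleus appearance.  Connected components
(8-connectivity) of the segmentation mask yield one record per cluster
with four features: centroid position (x, y), pixel area, the
major/minor axis ratio of the second-central-moment ellipse fit, and
the angle of the minimum-area bounding rectangle's longer side against
the horizontal, folded into [0, 180).

A candidate partition into groups is scored as between-group mean
separation divided by within-group spread times a spatial-coherence
penalty:

- difference between groups: Σ over ordered pairs of groups (n ≠ m) and
  features i of |μ_{i,m} − μ_{i,n}| — each unordered pair is counted
  twice exactly as the formula is written; the double counting cancels
  in comparisons;
- variance within groups: Σ_m Σ_i σ_{i,m}, with σ the per-group
  standard deviation (the symbol σ, not σ², is what enters);
- neighbor ratio: Σ_m Σ_{p∈m} 2^(NDC/NSC) / N_m, where NSC and NDC
  count the same-/different-group clusters among the ten nearest
  neighbors of cluster p by raw centroid distance.  A cluster with all
  ten neighbors in other groups (NSC = 0) contributes 2^10, keeping the
  score finite while preserving the strong penalty.

Numerical conventions: features are z-score standardized before
weighting (pixels, ratios and degrees are not commensurable; without a
common scale the weight sweep is meaningless); both position
coordinates share the fixed unit position weight; a single-member group
contributes σ = 0; if the total within-group spread is exactly 0 with a
positive between-group difference the score is +∞ (no ε is silently
added); an all-one-group assignment scores 0.  The angle feature is
treated linearly, not circularly — a known simplification that matters
only for groups whose orientations straddle the 0/180 wrap.

The optimizer sweeps the three free feature weights over 0.1–10 in
steps of 0.25 (40 values each; ~40³ combinations) and candidate group
counts 2–8, running Ward hierarchical clustering on the weighted
standardized features for each combination and keeping the score
arg-max; ties break toward fewer groups, then the lexicographically
smaller weight vector.  Because the full grid is expensive, a
`sweep_stride` subsamples it and a budget warning fires when the grid
exceeds `grid_budget` combinations.  Recovery runs in this repository
use stride 13 (weights {0.1, 3.35, 6.6, 9.85}); with well-separated
geometry the optimum is flat in the weights and the strided sweep finds
the same partition the full grid would.

## Amplification and coverage QC

AST is the earliest time the median-smoothed fluorescence exceeds
baseline mean + 10 × baseline SD and stays above for two consecutive
samples, linearly interpolated between the bracketing points.
Baseline statistics use the first five *raw* samples — the smoother
shrinks noise and would make a smoothed-baseline threshold overly eager
on flat negative-control curves.  The smoother is a width-3 median
filter with nearest-edge padding so a crossing at the final sample
survives.  The pass gate defaults to AST ≤ 40 min and alignment ratio
≥ 0.2; Lorenz-AUC and bulk-correlation floors exist but default off
(their project-specific cutoffs are set by the user).

The Lorenz curve sorts bins by ascending count and plots cumulative
read fraction against cumulative bin fraction; the trapezoid-rule area
is exactly 0.5 for uniform coverage and 1/(2B) when all reads fall in
one of B bins.  With this orientation higher AUC means more uniform
coverage, and the statistic is invariant to bin order and count scale
and monotone under equalizing single-read moves.

## Copy-number profiling and subclone clustering

**Binning.** The genome is divided into bins holding an equal expected
number of uniquely mapped reference reads: bin counts are apportioned
to chromosomes by read totals (largest remainder), and within a
chromosome boundaries sit at read-position quantiles, with each edge
placed midway between the two flanking reads, so expected per-bin
counts differ by at most one read.  This equalizes mappability the same
way the variable-binning approach does at production scale (10,000
genome-wide bins); the fixtures run 100–500 bins over a 2 × 5 Mb
synthetic genome, which exercises the identical mathematics at seconds
scale.

**Normalization.** Per-bin counts are divided by a Lowess fit of count
on GC (span 0.3, rescaled to preserve the mean; skipped when GC is
constant, where no bias is identifiable).  Copy ratios divide by the
median normalized depth of the reference DNA after mapping the
sample's median bin onto the reference's median bin.  The median — not
the total — carries the library-size correction: with a fixed
sequencing budget, large gains dilute every other bin, and the median
(majority, copy-neutral) bin is the stable anchor.  The reference
against itself has median ratio exactly 1.

**Segmentation.** Profiles are segmented jointly on the absolute
copy-number scale (ratio × reference ploidy 2), minimizing the summed
squared deviation from per-sample segment means plus γ per breakpoint,
γ = 20, with breakpoints shared across samples and never crossing a
chromosome boundary.  The minimizer is an exact O(n²) dynamic program;
on instances of ≤ 30 bins it provably equals exhaustive breakpoint
enumeration.  The copy-number scale matters: a one-copy event is a
unit-height step there, which is the effect size the γ = 20 penalty is
calibrated against; on the ratio scale the same event has height 0.5
and arm-scale events would be under-segmented.

**MergeLevels.** A level-reduction utility merges the closest pair of
segment levels while a Mann–Whitney rank test between their pooled bin
values has p > 10⁻⁴ or the level gap is below 0.1.  This re-specifies
the classical level-merging procedure (rank test plus absolute floor)
rather than porting it verbatim; the default subclone pipeline encodes
events directly from the joint segmentation and uses MergeLevels as an
optional simplification step.

**Events and clustering.** Each segment per sample becomes +1 (gain)
if its level exceeds the reference median by more than 25% relative,
−1 (loss) below, else 0 — 0.25 splits diploid from single-copy events
at the ratio midpoints 1.25/0.75.  Samples are clustered on the
Pearson correlation of their event vectors (distance 1 − r, average
linkage); copy-ratio matrices are accepted as the clustering input as
well.

**Cluster support.** AU p-values come from multiscale bootstrap: the
feature axis (bins or segments) is resampled with replacement at
scales r ∈ {0.5, …, 1.4} (10 values), `n_bootstrap` times per scale
(production default 10,000; tests and the acceptance run use 100–1,000,
which is sufficient at the clean separations the fixtures plant).
Per-clade bootstrap probabilities BP(r) feed the probit model
z(r) = v√r + c/√r with z = Φ⁻¹(1 − BP), fit by weighted least squares
with binomial-variance weights, and AU = Φ(c − v).  Two boundary cases
are resolved explicitly: a clade recovered in every replicate at every
scale has maximal support (AU = 1; the probit fit is undefined on a
constant), and a clade never re-formed is flagged degenerate with
AU = 0.

## Somatic SNV consensus

Consensus operates on per-caller per-sample call sets (three callers)
plus a paired normal, with per-base pile-up depth tables per sample.
Depth tables must declare the upstream read filter (mapping quality
≥ 30, supplementary alignments excluded); the declaration is validated,
not re-applied, since the toolkit consumes depth tables rather than
alignments.  Steps, in order: exact-key germline subtraction;
intra-sample double-called sites (≥ 2 of 3 callers — suppresses
caller-specific sequencing-error calls); confident sites (double-called
in ≥ 2 samples — suppresses amplification artifacts, which are private
to one sample's WGA reaction); Fisher confirmation.  The 2×2 table
compares the alt depth against the *largest* other non-reference base
depth (the most conservative comparator), one-sided for enrichment,
threshold p < 10⁻⁴.  At a confident site, any sample in which at least
one caller detected the variant is tested — this per-sample rescue
reading lets a true variant confirmed in two samples be recovered in a
third where only one caller fired.  Indels are excluded after
normalization; multi-allelic records are split on read.

## SSCS validation

UMI families below 3 reads are dropped; a family's consensus base must
carry ≥ 90% of its reads or the family is discarded as ambiguous —
the single-strand-consensus conventions of the duplex-sequencing
literature (duplex consensus itself is out of scope: the library
design this validates amplifies before tagging and retains only
single-strand information).  Target loci (where an SNV was detected)
are compared against background loci (no SNV detected): the background
non-reference SSCS fractions form an empirical null, each target gets
the add-one empirical p-value (1 + #{background ≥ observed)}/(1 + n),
which avoids p = 0, and targets are validated at Benjamini–Hochberg
FDR < 0.05.

## Spatial mapping

Cluster coordinates (x, y in source pixels, optionally scaled to μm)
joined with subclone labels; the third dimension is section index ×
700 μm (serial-section spacing, configurable).  The join is lossless
for matched ids, unmatched ids on either side are counted and
reported, and unassigned clusters are kept and labeled.  A contiguity
statistic (mean same-label fraction among 5 nearest 3D neighbors)
quantifies spatial segregation of subclones.  Export is TSV, with
optional per-section scatter figures; colors are stable per subclone
label.

## Synthetic fixtures: what they emulate and what they do not

All generators are pure functions of parameters and a seed.

- **Masks**: analytically filled, non-overlapping elliptical blobs (a
  rejection sampler with a 3-px margin; analytic fill guarantees one
  connected component per blob).  Groups differ in anchor position,
  area (≈ 200/450/700 px), elongation (≈ 1.3/2.5/3.7) and orientation
  (≈ 15°/70°/125°) — separations of several within-group SDs,
  emulating clearly distinct collective morphologies.  Not emulated:
  histology texture, touching clusters, segmentation errors.
- **Binned depth**: two chromosomes × 5 Mb, 100–500 bins; expected
  count ∝ copy state × bin fraction × GC bias; Poisson or
  negative-binomial (dispersion 0.1, matching the overdispersion of
  amplified single-cell libraries).  The GC track is a deterministic
  two-sinusoid "isochore" pattern with sub-Mb periods so GC is
  uncorrelated with the multi-Mb planted events, as in real genomes;
  the planted bias is a monotone quadratic in GC.  Subclone profiles
  plant 2 arm-scale events (25–50 bins) per subclone at ±1 copy —
  the scale at which real subclones in this workflow differ.  Not
  emulated: focal events below the γ = 20 detection limit, replication
  timing, allele-specific states.
- **Caller call sets**: per-sample DNA truth = germline ∪ subclone
  somatic ∪ Poisson(10) private WGA artifacts; callers detect DNA
  variants independently at their sensitivity and add Poisson false
  calls per Mb; pile-up depths are negative-binomial around 80× with
  small error counts on the two untouched bases.  Caller errors are
  independent across callers — real callers share failure modes, so
  real double-calling is less effective than the independent-model
  arithmetic suggests.
- **UMI reads**: one template per family, alt with the planted allele
  fraction; per-read errors uniform over the other three bases at
  10⁻³–10⁻²; family sizes Poisson(5), at total depths ≤ a few hundred
  families per locus rather than the ~18,000× of the real assay.
- **Amplification curves**: flat baseline before the planted start
  time, then a saturating-exponential rise to plateau — sigmoidal
  overall with the take-off exactly at the planted AST, which makes the
  noiseless threshold-crossing recoverable to machine precision;
  Gaussian noise throughout.

Passing tests on these fixtures demonstrates that the algorithms
recover planted structure under the stated noise models at desk scale;
they do not certify performance on real tissue, where segmentation
quality, caller error correlation, and amplification artifacts are
harsher than the generators assume.

## Problem sizes and determinism

Tests and the acceptance script run at 100–500 bins, 9–10 samples,
20-seed replication for recovery rates, 100–1,000 bootstraps per scale
for AU support, and ≤ 500× UMI depth; these sizes were chosen so the
full suite completes in a few minutes while every statistical check
retains its power.  Every stochastic step takes an explicit seed, and
the demo pipeline is byte-identical across repeated runs at a fixed
seed.
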
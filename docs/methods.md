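# Methods

## Coordinate conventions

Genomic coordinates are 0-based half-open internally; bedGraph/BED files use
their native 0-based half-open convention and CTSS tables the 1-based CAGE
convention, with conversions confined to the I/O boundary.  TSS-relative
offsets put the TSS at 0 and all analysis windows are inclusive at both ends,
so "100 bp centered on the TSS" is the 101-position interval [-50, +50] and
the 81 bp TBP-typing window is [-40, +40].  For minus-strand promoters the
offset axis is reversed and the coverage strands swapped during profile
extraction, so "sense" always denotes the transcribed strand.

## Coverage model and normalization

Stop-base coverage is stored per strand as dense per-base arrays.  Replicates
are scaled to reads per million of their aligned reads (RPM) and pooled by
the per-base arithmetic mean, so a pooled track is on the same scale as a
single replicate.

## CAGE normalization and TSS clustering

Per-position tag counts are mapped onto a reference power law: the sample's
reverse-cumulative distribution (number of positions with count >= x) is fit
by ordinary least squares on log-log scale over counts in [3, 40000], and
each count is carried through its fitted rank onto the reference law
`r(x') = k_ref * x'^(-1.19)` with `k_ref = 1e6 / zeta(1.19)` — the constant
that gives the reference distribution a total of 10^6 tags, making the
output a tags-per-million (TPM) scale.  The map is strictly monotone, so
ranks are preserved; counts below the fit range pass through the same map.

CTSSs within 30 bp on the same strand form tag clusters.  Interquantile
boundaries use a left-continuous step-function convention: the 10% (90%)
boundary is the first position, in ascending genomic order, at which
cumulative signal reaches 10% (90%) of the cluster total; the interquantile
region therefore contains at least 80% of the signal by construction.  Tag
clusters with TPM >= 0.5 in at least one replicate are aggregated across
replicates when their interquantile regions lie within 100 bp on one strand;
the consensus cluster spans the union of the constituent interquantile
regions, and its quantiles and dominant TSS are recomputed on per-position
signal summed over replicates.  Because the consensus span is the union of
*central* regions, the refined interquantile bounds can sit strictly inside
the constituent bounds even for identical replicates; consensus records carry
both the recomputed mean TPM and the largest constituent TPM, since the two
scales answer different filtering questions.  The dominant TSS is the argmax
of summed signal, ties broken toward the 5' end.  Single-position clusters
need TPM >= 3 to count as active; clusters with interquantile width < 11 bp
are flagged narrow and form the promoter set used by all footprint analyses.

## Core element scanning and promoter typing

The ten positioned elements ship as IUPAC consensus strings with inclusive
TSS-relative windows; a motif is present when a placement lying entirely
inside its window matches with at most the element's mismatch allowance (one
for the TATA box, zero otherwise).  An `N` in the genome mismatches every
non-N consensus code.  Requiring full containment is the strictest reading of
a positional window; scanning agrees with a brute-force regex expansion of
the IUPAC codes (property-tested).

Type rules: TATA promoters need only the TATA box and TCT promoters only the
TCT motif (other elements do not exclude them); DPR promoters need MTE, DPE
or PB and none of TATA/TCT/DRE/Ohler; housekeeping (HK) promoters need DRE or
an Ohler element and none of TATA/TCT/MTE/DPE/PB.  A promoter can satisfy
several rules; the full label set is retained and a primary label is resolved
by the fixed priority TATA > TCT > DPR > HK (the handling of, e.g., TATA+TCT
promoters is not dictated by the rules themselves, so the priority is a
package convention).  Element enrichment per cluster always rescans at zero
mismatches, uses the ratio of in-cluster to out-of-cluster presence
fractions, a two-sided Fisher exact test (one-sided available), and
Benjamini-Hochberg correction across all cluster-by-element tests.  PWMs use
a 0.5 pseudocount per base; the pseudocount affects logos only, never
presence calls.

## Footprint geometry

Peak calling on average (meta)profiles: boxcar smoothing with halfwidth 1
(window of 3), local maxima strictly above both neighbors with plateaus
resolved to the raw-profile argmax within the plateau extended by the
smoothing halfwidth (leftmost on raw ties), and a height floor of 0.2 times
the smoothed profile maximum.  All of smoothing, threshold and pairing
distance are exposed in config, since average-profile peak calling has no
canonical parameterization.  Each sense-strand peak pairs with the nearest
antisense-strand peak strictly downstream within 25 bp; the footprint
midpoint is the arithmetic mean of the two peak offsets rounded toward zero.
Rounding toward zero (rather than flooring) makes midpoint calling exactly
antisymmetric under the strand-swap/offset-negation mirror, a symmetry the
test suite checks exactly.  Midpoints map to the six canonical regions —
R1 = [-150,-50], R2 = -30, R3 = [-18,-14], R4 = +10, R5 = +19, R6 = +32 —
by containment for interval regions and by distance <= 5 bp for point
regions, nearest region winning ties.

Factor modules: each factor's average sense+antisense profile over
[-50, +50] (both strands concatenated; strand handling is not canonical, and
concatenation keeps the strand asymmetry that distinguishes paired
footprints) is min-max normalized, the factor-by-position matrix is centered
but not scaled, decomposed by PCA, and k-means (k = 4) on the first two
principal coordinates assigns module membership.

## De novo TBP typing

Narrow promoters in the top 90% of total TBP signal over the 81 bp window
(ties at the boundary kept) are rank-transformed row-wise: each promoter's
162 feature values (81 positions x 2 strands) are ranked smallest-to-largest
with average ranks for ties and divided by the column count, making each row
a shape descriptor invariant to any monotone rescaling of its signal.
Row-wise ranking follows from dividing by the number of columns; the
column-wise alternative is available behind a flag.  Lloyd k-means with
k = 4, 100 random restarts and at most 30 iterations per restart (the
interpretation adopted for the clustering iteration cap) keeps the
best-of-restarts solution by total within-cluster sum of squares
(scikit-learn's Lloyd implementation, which also handles empty clusters by
relocation).  Clusters are named by the element family (TATA, DPR, TCT/HK)
of their most significantly enriched element (BH q < 0.05, ratio > 1);
when two clusters resolve to TCT/HK they are told apart by mean raw signal
amplitude (diffuse vs low); clusters with no significant enrichment are
reported "unresolved" rather than guessed.

## Occupancy statistics

Transcription normalization divides each promoter's binding signal (summed
over [-50, +50], both strands by default — the per-promoter strand
convention is configurable since either choice is defensible) by its CAGE
expression score over [-150, +150]; promoters without positive CAGE score
are excluded, never emitted as NaN.  Group comparisons use the two-sided
Wilcoxon rank-sum test (exact for small tie-free samples).  Factor
similarity is Pearson correlation of log2(x+1) binding totals across
promoters, converted to 1-r distances and clustered with the classic Ward
update applied to those distances directly (the hclust "ward.D" convention,
emulated by feeding sqrt-distances to scipy's ward and squaring the merge
heights); Ward variants differ, so the convention is fixed and documented.
The condition contrast correlates each factor's binding total with TBP
signal summed in an upstream [-25, -10] and a downstream [+25, +40] window
(bracketing the -18 and +32 TBP footprints; the windows are unspecified
upstream choices and fully configurable) per condition and reports
PCC(control) - PCC(triptolide).

## Paused Pol II half-lives

Promoters qualify as paused when mean Pol II signal over [-100, +100] (both
strands; the assessment window is a package default) exceeds the threshold,
the antisense maximum lies 0-80 bp downstream of the sense maximum, and the
pause position (midpoint of the two maxima) falls in [0, 80) bp.  Signal in
the 51 bp window centered on the pause position is fitted per promoter to
`S(t) = S0 exp(-k t)` by unweighted nonlinear least squares initialized from
a log-linear regression on the positive signals; non-decaying fits and
half-lives above 60 min are floored to 60 min and flagged.  Quintiles are
assigned on ascending half-life with ties broken by promoter id; when n is
not divisible by five the extra promoters go to the extreme quintiles first,
so the short- and long-pausing sets are never the ones shortened.

The pipeline fits the decay on raw (depth-matched) counts rather than
per-time-point RPM: in the synthetic time course nearly all reads come from
the decaying pause signal, so rescaling each time point to its own depth
would cancel the decay itself.  On real data, where stable genome-wide
coverage dominates the library, per-time-point depth normalization and
depth-matched counts nearly coincide; the selection threshold is therefore
configured per dataset (20 RPM for genome-scale data, 1.0 on the synthetic
scale).

## Synthetic data generator

The generator emulates the statistical structure each stage consumes, on a
single synthetic contig (default 200-400 promoters spaced 700 bp apart,
random strands).  Each promoter carries exact consensus instances of its
type's defining elements at legal window offsets (IUPAC codes sampled
uniformly within class) and is rejection-sampled until no excluded element
matches anywhere in the scan window at classification stringency, so planted
types are recoverable by construction.  Expression is lognormal (median 20,
sigma 1); CAGE replicate totals are negative-binomial (size 10) around
expression and tags spread normally around the TSS (sd 1.2 bp narrow,
10 bp broad); stop counts are Poisson at archetype peak offsets with +/-1 bp
jitter over sparse uniform background; occupancies share a lognormal latent
factor per structural module (sd 0.5, factor noise sd 0.15), so
factor-similarity clustering can recover modules; time-course signal decays
exponentially with multiplicative Gaussian noise (sd 5%).  Footprint
archetypes follow the canonical region geometry: downstream-module factors
at +10/+19/+32, middle module straddling the TSS, narrow upstream module at
-30/-18, broad upstream module diffuse over the -150/-50 region; the
upstream TBP footprint is exclusive to TATA promoters, the downstream TBP
footprint is strongest at DPR promoters and absent under triptolide.  All
randomness flows from one root seed through named SHA-256-derived
substreams (genome, occupancy, ctss-rep*, nexus-*, timecourse-*), so any
modality regenerates independently and byte-identically.

What the generator does **not** emulate: sequence-dependent crosslinking
efficiency, nucleosomes and flanking gene structure, overlapping or
bidirectional promoters, mappability artifacts, replicate-specific biases,
and genome-scale background complexity.  Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
assumptions, not performance on real libraries.  Dense-profile archetypes
used in the typing recovery study add Gaussian noise scaled to the global
signal amplitude, which is what makes the low-amplitude promoter class
noise-dominated in rank space — the property that separates "diffuse" from
"low" TCT/HK clusters.

## Problem sizes and numerical choices

Recovery studies run at 400 promoters (classification, typing), 500 decay
curves, 200 metaprofiles and 500-promoter correlation panels; the end-to-end
pipeline demonstration uses 200 promoters, chosen so a full study remains a
few seconds of compute while every statistic retains comfortable power.
Decay fits converge to relative tolerance ~1e-8 (scipy trust-region least
squares with tightened ftol/xtol); k-means determinism comes from seeding
every restart; ties are broken by fixed, documented rules throughout
(leftmost plateau base, 5'-most dominant TSS, promoter-id order in
quintiles).  Degenerate inputs fail loudly (constant vectors in min-max
normalization, zero-signal clusters, all-zero decay signals) or are excluded
with a warning (zero CAGE scores, constant factors in correlation).

## Known limitations

- bedGraph is the only on-disk coverage format; bigWig input is not
  implemented.
- Per-promoter (single-locus) footprint calling on raw noisy coverage is out
  of scope; peaks are called on averaged profiles only.
- The power-law normalization's reference constant uses the zeta-function
  total; other implementations choose the constant differently, which shifts
  the TPM scale by a global factor but not ranks or slopes.
- Gene annotation is optional; without it promoters are anonymous clusters
  and the one-cluster-per-gene rule is skipped.
- De novo motif discovery is not implemented; sequence logos come from
  TSS-aligned PWMs.
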
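# Methods

## The mixture dosage model

Seed-coat-enriched DNA from a first-generation (M1) mutant is a cell
mixture: a fraction *m* of cells carries a de novo heterozygous deletion
(copy number 1 over the deleted interval), and the remaining 1 − *m*
contaminating cells (endosperm, embryo) are unmutated (copy number 2).
The local copy number over the deletion is therefore c = 2 − *m*, and
everywhere else c = 2.

Sequencing depth is summarized in non-overlapping bins (default 100 kb)
tiling each of the five nuclear chromosomes from coordinate 0; the last
bin of a chromosome keeps its true, shorter width.  The relative read
depth of a bin is

    RRD = mean depth in bin / median per-bin mean depth over all bins.

The median is taken over every bin of all five chromosomes, so the median
RRD is exactly 1 by construction.  Organellar sequences are excluded from
the layout because they would distort a nuclear-genome median.  Over a
deletion, E[RRD] = c/2 = (2 − *m*)/2, so the mosaic mutant fraction is
recovered by inverting the mixture:

    m = clamp(2 · (1 − RRD), 0, 1).

At *m* = 0.7 the deleted plateau sits at RRD 0.65; a pure heterozygote
(*m* = 1) sits at 0.5.

Per-base depth input is averaged over all positions of a bin, with
positions absent from the input counting as depth 0 (depth tools usually
omit zero-coverage positions; dropping them would bias sparse bins
upward).

## Deletion calling and boundary refinement

`call_deletions` reports maximal runs of consecutive bins with
RRD < `threshold` (default 0.8) of length ≥ `min_bins` (default 3), per
chromosome, optionally merging runs separated by at most `gap`
above-threshold bins (default 0).  Each call carries its bin-aligned
interval, size, mean RRD and implied mutant fraction.  The defaults place
the threshold roughly midway between the deleted plateau (0.65 at
*m* = 0.7) and the normal level 1.

Thresholding alone is noisy at realistic depth.  With per-bin depths
modeled as Poisson draws (see below) at mean 50, a truly deleted bin at
level 0.65 crosses the 0.8 threshold with probability ≈ 0.11, and a
normal bin falls below it with probability ≈ 0.065.  A 19-bin deletion
therefore survives as one unbroken run in only ≈ 0.89¹⁹ ≈ 10% of samples,
and run edges wander by a bin or two — raw threshold runs systematically
fragment and mis-size Mb-scale deletions.  `call_deletions_refined`
addresses this the way segmentation-based CNV callers do: each raw run's
boundaries are re-placed within a local window (default ±8 bins) by
maximizing the two-level Poisson profile likelihood (depths inside the
candidate segment at the segment's mean, outside at the genome median);
refined calls that come to overlap are merged (re-uniting fragments of
one deletion), the refine-merge step is iterated (default twice), and the
threshold/min-bins filter is re-applied.  A one-bin boundary error costs
≈ 3.5–4 nats at depth 50, so refined boundaries are correct to ±1 bin in
≈ 89% of simulated samples — close to the change-point localization limit
for independent Poisson bins, which is why the residual uncertainty is
handled by replication (below) rather than further algorithmics.  About
0.3 spurious ≥3-bin calls per genome survive at this depth; they are
reported honestly rather than suppressed, since downstream classification
only asks whether a call overlaps a marker locus.

## qPCR copy-ratio model

Quantification follows the comparative-Ct convention with amplification
efficiency fixed at 2 (perfect doubling per cycle): replicates are
averaged to a mean Ct per target, ΔCt = Ct(TT4) − Ct(TT8) per sample, and
the control-normalized ratio is 2^−(ΔCt_sample − ΔCt_control).  A
per-replicate variant computes one ratio per replicate and reports their
mean ± SE, matching how replicate qPCR ratios are usually presented.

The forward model rests on the screening cross's allele structure: the
TT4 qPCR target exists on only one control allele (the other carries a
pre-existing deletion removing it), so the control has one copy; the TT8
target survives on both alleles (the mutant allele differs by a
single-nucleotide lesion), so the control has two.  In mutant cells the
wild-type allele at the mutated locus is lost.  Mixing cell populations
gives relative template copies 1 − *m* (TT4 target, tt4-type mosaic) and
(2 − *m*)/2 (TT8 target, tt8-type mosaic), hence control-normalized
TT4:TT8 ratios of 1 − *m* and 2/(2 − *m*): 0.25 at *m* = 0.75 and ≈ 1.54
at *m* = 0.7.  The ratio is monotone in *m* in opposite directions for
the two mutant types, which is what makes it diagnostic.

Classification combines both lines of evidence: a deletion call
overlapping a marker locus, or a ratio outside the guard band
[1/1.25, 1.25], votes for the corresponding type; conflicting or absent
evidence stays unclassified.  The guard band keeps replicate noise around
1 from forcing a call; its width (25%) is comfortably below the smallest
diagnostic effect in the model (ratio 1.54 at *m* = 0.7).

## Screening statistics

Class counts are tested with exact binomial tail sums (scipy's exact
implementation; no normal approximation).  The two-sided p-value uses the
minlike convention — the sum of all outcome probabilities not exceeding
the observed outcome's — which reduces to doubling the smaller tail under
a symmetric null.  The length-weighted null probability for a hit in the
target gene is l_target/(l_target + l_other); it is used at full
precision (1789/6432), with 0.28 as a display rounding only.  Mutation
frequency is reported as a percentage to one decimal place.

Because the test is exact, its size is below the nominal α at small
counts; the type-I calibration test therefore simulates screens large
enough (≈ 1300 mutants) that the discrete size (0.048 at α = 0.05) is
close to nominal, and checks the empirical rejection rate against that.

## Survival model

S(D) = 1 − (1 − e^{−D/D₀})^N with D₀ > 0, N ≥ 1.  Fitting is unweighted
least squares on the linear survival scale with those bounds, initialized
from the terminal slope of log-survival (−1/D₀) and its dose-0 intercept
(ln N); both initial values can be overridden.  The fit refuses fewer
than three distinct doses and degenerate (all-survive/all-die) data.  The
shoulder dose is implemented as the quasi-threshold dose Dq = D₀·ln N,
the standard quantitative counterpart of the verbal "dose where survival
starts to drop from ≈ 100%"; for D₀ = 10 Gy and N = 20 it is 29.96 Gy,
i.e. a ≈ 30 Gy shoulder.

## Synthetic data: what it does and does not emulate

`simulate_bins` draws each bin's depth as one Poisson variate with mean
λ·c/2 (λ = expected depth of a copy-number-2 bin, default 50; partial end
bins draw proportionally fewer counts and rescale, keeping the
expectation right at any width).  Bins overlapping a deletion edge scale
their copy number by the overlap fraction.  A gamma-Poisson
overdispersion parameter exists but defaults to 0, since pure Poisson is
the assumption the dosage analysis itself makes.  `simulate_qpcr` places
Ct at base_ct − log₂(relative copies) plus Gaussian noise;
`simulate_screening` is one multinomial draw over {tt4-type, tt8-type,
none}; `simulate_survival` draws binomial survivors at the model's S(D).
All simulators are bit-reproducible given their seed.

Real sequencing data differs in ways the simulator deliberately ignores:
mappability and GC bias make real bin depths overdispersed and locally
correlated; library contamination fractions vary between samples; and
breakpoints need not align to bin edges.  Passing tests therefore show
that the analysis correctly inverts its own generative model at realistic
noise levels — parameter recovery, not field validation on real
libraries.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; per-base depth TSVs are
  accepted 1-based (the common depth-tool convention) and converted on
  read.  Deletion calls are written BED-like.
- Default genome layout: the five nuclear Arabidopsis chromosome lengths,
  with TT4/TT8 at their reference gene positions; all coordinates are
  configuration values, not hard-coded assumptions.
- The normalization median includes partial end bins and zero-depth bins;
  an all-zero median raises an error rather than dividing by zero.
- Simulation sizes in tests and in the acceptance script are chosen to
  keep Monte-Carlo error well below each quantity's tolerance: RRD
  plateau levels are averaged over 8 replicate genomes (single-replicate
  sd of a 15-bin deleted mean is ≈ 0.03, the size of the tolerance
  itself), the called deletion size is the median over 9 replicates
  (per-replicate ±1-bin recovery ≈ 0.89), and the mutant-fraction
  round-trip averages 8 replicates (single-replicate sd ≈ 0.05 for a
  20-bin deletion).
- The survival-fit initializer needs at least two doses with fractional
  survival; with fewer it falls back to coarse defaults and relies on the
  bounded optimizer.

## Known limitations

- No overdispersion or GC-correction in the default dosage model; real
  whole-genome libraries will need the overdispersion parameter or
  pre-normalized bins.
- Breakpoint resolution is one bin (100 kb by default); intragenic
  rearrangements, inversions and copy-neutral events are invisible to
  dosage by design.
- The qPCR model assumes perfect amplification efficiency for both
  targets; an efficiency parameter exists on the simulation side only.
- The exact binomial tests assume pre-specified hypotheses; no
  multiple-testing machinery is included.
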
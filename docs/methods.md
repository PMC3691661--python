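# Methods

## The occupancy model

Each MNase-protected fragment is evidence for one nucleosome whose
dyad lies at the fragment's center.  The per-base occupancy score
spreads that evidence with a truncated Gaussian kernel:

    w(d) = exp(-0.5 * (d / sigma)^2)   for 0 <= d <= dmax,  else 0

with `sigma = 10` bp and `dmax = 25` bp by default.  A fragment of
odd length has a unique central base and deposits one full kernel
there.  A fragment of even length has two equally plausible central
bases (offsets L/2 - 1 and L/2); it deposits half a kernel at each,
so total mass per fragment is 1 regardless of length parity.  An
alternative reading of the even-length rule — half-weight kernels
that are then halved again, total mass 0.5 — is available as
`build_occupancy(..., even_read_literal_halving=True)`; we default to
the mass-conserving interpretation because a fragment's evidentiary
weight should not depend on whether its length is even.

The track is computed as a convolution of the per-base center-mass
vector with the kernel, and equals the naive read-by-read,
position-by-position double loop to 1e-9 (tested on random instances).

Fragment length windows select the single-nucleosome population:
55–65 bp for archaeal histone-fold tetramer footprints, 137–157 bp
for eukaryotic octamer footprints.  Both windows, the kernel
parameters, and everything below are plain function arguments (and
CLI flags), with these values as defaults.

## Dyad calling

"Well-defined peak" is operationalized as three simultaneous
conditions on the occupancy track:

* height at or above the 0.60 quantile of the track,
* topographic prominence >= 0.25 (prominence is the standard
  quantitative reading of peak "steepness": height above the highest
  saddle connecting the peak to a taller one),
* greedy non-overlap thinning, tallest peak first, so no two called
  dyads are closer than `min_separation` (50 bp archaeal / 120 bp
  eukaryotic suggested).

Plateau maxima report their leftmost index; height ties in the
greedy pass break leftmost.  Both choices are arbitrary but make the
caller fully deterministic.  Peak detection itself (local maxima,
prominence, plateaus) is delegated to `scipy.signal.find_peaks`; the
quantile filter and thinning are ours and verified against a
brute-force enumeration oracle.

Each called peak is then snapped to the center of a nearby read of
preferred length: lengths are tried in the fixed order 60, 61, 59,
62, 58 (147-centered analogue for eukaryotic mode), and within a
length class the candidate center nearest the peak wins, with
distance ties broken leftmost.  Even-length reads offer both
candidate centers.  If no candidate lies within ±5 bp, the peak
position itself is kept (source `peak-fallback`).

## Single-end pseudo-pairing

Single-end libraries observe only fragment 5' ends.  With `w_i` the
Watson tag count at i and `c_j` the Crick tag count stored at the
half-open fragment-end coordinate j, a Watson tag fans out to
fragments [i, i+k) for k = a..b with weight

    w_i * c_{i+k} / sum_{j=a..b} c_{i+j},      a = 51, b = 68,

and Crick tags fan out mirror-symmetrically.  Storing Crick tags at
the exclusive end coordinate makes "a fragment [i, i+k)" and "a
Crick tag at i+k" the same statement, which keeps the conversion and
its inverse (the simulator's tag emission) exactly consistent.
Total emitted weight plus dropped weight equals the total tag count
to floating-point accuracy.  A tag whose opposite-strand window sums
to zero is undefined under the formula; it is dropped and counted
rather than imputed, because inventing a uniform end distribution
would fabricate fragments at positions with no opposite-strand
evidence.

## Dinucleotide profiles, period, phase

For 2H-bp windows centered on called dyads (H = 30 archaeal, 73
eukaryotic), the AT-group {AA, AT, TA, TT} and GC-group
{CC, CG, GC, GG} frequencies are computed at each dinucleotide start
offset -H..H-2 (a 2H-bp window holds 2H-1 dinucleotide starts).
Both groups are closed under reverse complement, so a single strand
pass suffices.  Offsets whose dinucleotide contains N are excluded
from that offset's denominator.  Optional post-processing: a 3-bp
centered moving average, and symmetrization about the dyad (offset o
averaged with offset -o-2, its reverse-complement image); both are
on by default for display.

The period estimator detrends the profile (subtract mean), computes
the normalized autocorrelation over lags 2..20 bp, takes the maximum
and refines it by parabolic interpolation before rounding to integer
bp.  Two guards report "no oscillation" instead of a period:

* peak autocorrelation < 0.2, and
* detrended RMS amplitude < 5% of the profile's mean level.

The second guard exists because normalized autocorrelation is
scale-free: a profile that is pure sampling noise (finite window
count) can reach autocorrelation 0.2 by chance, and a 3-bp moving
average deterministically injects lag-2/3 autocorrelation into noise.
For the same reason the pipeline estimates period and phase from the
*raw* (unsmoothed) frequencies even though the exported profile is
smoothed.  The phase offset is the circular lag in [0, period) that
maximizes the cross-correlation of the detrended AT and GC profiles;
antiphase helical repeats yield period/2 = 5 bp.

## Pentamer enrichment

All 4^5 = 1024 pentamers are counted on both strands of (a) the
dyad-centered windows and (b) the background, making the count
vector exactly reverse-complement symmetric, consistent with
treating ATATA and TATAT as the same signal.  Counts receive a
pseudocount of 1 before normalization to relative frequencies
P_nucleosome and P; the statistic is their ratio.  Windows with N
are skipped.  The default background is the genomic complement of
the merged read intervals — the literal reading of "non-nucleosomal
DNA" — with the whole genome available as an alternative
(`--background genome`); with deep coverage the complement
concentrates in exactly the refractory regions, which is what a
linker-DNA background should do.  The class summary counts A/T-only
pentamers (32 of them) with ratio < 1 and G/C-only pentamers (32)
with ratio > 1, and reports the global minimum-ratio pentamer (ties
broken lexicographically).

## Metagene and NDR

The metagene profile averages the occupancy track over ±500 bp
around each annotated start codon, read right-to-left for minus
strand genes so positive offsets always point into the ORF, then
divides by the genome-wide mean occupancy; a uniform track maps to
exactly 1.0 everywhere.  Genes near contig edges contribute only
their in-bounds offsets (ragged averaging) rather than being
excluded, which avoids biasing dense microbial gene sets toward long
genes.  Overlapping genes are all included.  NDR depth is
mean(relative occupancy over [+50, +250)) minus mean over [-150, 0);
positive values mean upstream depletion.  `region_profile` exports a
locus slice with its mean relative to the genome-wide mean, so
refractory regions score near 0.

## The synthetic study

The generator is deliberately generative — an explicit placement
energy plus Boltzmann sampling — rather than the descriptive
statistics run backwards, so recovery of the planted parameters is a
genuine test of the pipeline.

**Genome.**  Alternating spacer/gene segments on one contig
(defaults: 200 kb, 150 genes, 120-bp spacers, strands alternating so
every start codon abuts a spacer).  Gene bodies draw dinucleotides
two bases at a time with class probabilities 0.25·(1 ± m·cos(2πi/P))
for the AT/GC groups (m = 0.8, P = 10, phase in absolute
coordinates so the rotational frame is genome-wide coherent), mixed
dinucleotides taking the rest.  Spacers are i.i.d. bases at 85% A+T
with stamped-in A/T tracts of length ≥ 5: half alternating (AT)n,
a quarter poly-A, a quarter poly-T.  Alternating tracts dominate so
that the most common A/T-only pentamer in linker DNA is ATATA/TATAT,
the configuration the enrichment statistic should single out as most
disfavored.  A 5-kb "rDNA-like" zone (45–47.5% of the genome by
default) is filled with alternating AT and is excluded from
placement outright.

**Energy.**  score(i) = α·Σ_{j=-W..W-1} cos(2πj/P)·(1[AT dinuc at
i+j] − 1[GC dinuc]) − γ·#(bases in [i−W, i+W) inside A/T runs ≥ 5),
W = 30.  Defaults α = 1, γ = 0.25.  Window-clipped positions score
−∞.  Verified against a position-by-position brute-force oracle.

**Placement.**  Sequential Boltzmann sampling at inverse temperature
β = 4: draw a dyad ∝ exp(β·score) over admissible positions, block
everything within 60 bp, repeat to ~3,000 dyads.  Implemented as an
exponential-clock race (E_i ~ Exp(1)/w_i, accept in increasing-E
order while unblocked), which is distributionally identical to
draw–renormalize–exclude by memorylessness and runs in O(n log n).

**Reads.**  200,000 fragments (≈60× coverage): dyad chosen
∝ exp(read_beta·score) with read_beta = 0.05, length uniform on
[55, 65], center = dyad + discretized Gaussian jitter (sd 2 bp,
truncated ±4 — MNase trimming variability).  Read depth uses a much
gentler temperature than placement on purpose: placement decides
*where* nucleosomes sit and must be sharp, while per-site sequencing
depth in real MNase libraries varies only a few-fold; reusing β = 4
would concentrate >90% of reads on a single best site.  Single-end
mode emits each fragment's two 5' ends as stranded tags and withholds
the fragment records.

All stages derive their generators from one seed via fixed per-stage
spawn keys, so runs are byte-reproducible and stages can be rerun
independently.

**What the simulation does not emulate:** MNase sequence cleavage
bias, sequencing error, mappability gaps, copy-number variation,
transcription-coupled remodeling, and real linker-length
distributions.  Passing recovery tests therefore demonstrates that
the estimators are correct and well-calibrated for data whose only
structure is the positioning code itself — not that real libraries
are free of these confounders.

## Problem sizes and determinism

Unit tests run on 0.4–40 kb toy genomes; the end-to-end recovery
tests and the acceptance script use the full default study (200 kb,
200k reads), which completes in a few seconds.  All stochastic tests
are seeded; hypothesis property tests draw seeds from a fixed
strategy.  Degenerate inputs have defined behavior throughout:
empty read sets give zero tracks, all-zero tracks give empty peak
lists (not errors), empty pentamer input sets and empty profile
windows raise `ValueError`, and out-of-bounds reads name the
offending record.

## Known limitations

* The peak-caller thresholds (quantile 0.60, prominence 0.25) are
  package defaults, not values inherited from any reference dataset;
  for real libraries they should be tuned against a fragment-size
  ladder or spike-in.
* The single-end conversion assumes fragment start and end positions
  are independent given the nucleosome, which underestimates length
  correlation in heavily trimmed libraries.
* Pentamer ratios are not GC%-corrected; in genomes with strong
  regional composition gradients the complement background partially
  absorbs, but does not remove, composition confounding.
* The period estimator searches lags 2–20 bp only and reports a
  single dominant period; mixtures of periods are out of scope.
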
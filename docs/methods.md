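# Methods

## Experimental model

The pipeline assumes a population of cells imaged simultaneously with a
ratiometric Ca²⁺ indicator (Fura-2 340/380; the ratio rises with
intracellular Ca²⁺) under an ordered perfusion protocol of condition
epochs.  The built-in preset is 80 minutes at 10-second sampling
(480 timepoints): 20 min low (3 mM) glucose → 30 min high (20 mM)
glucose → 15 min low glucose → 10 min KCl (30 mM) depolarization → 5 min
low glucose.  Epoch intervals are half-open `[start, end)` in minutes so a
boundary sample belongs to exactly one epoch; gaps between epochs are
legal and excluded from every statistic.  Timestamps are taken from the
file and never assumed uniform; quantities "per time step" use the median
sampling interval.

Two per-cell reference levels anchor everything:

* baseline *b* — median signal over the first low-glucose epoch;
* KCl normaliser *N* = median(KCl-epoch signal) − *b*, the cell's maximal
  depolarization-driven Ca²⁺ influx.

Normalising by *N* makes all features dimensionless and affine-invariant
(trace ↦ a·trace + b, a > 0, leaves every feature unchanged), which is the
correct invariance for ratiometric data with per-cell dye loading and gain
differences.

## Drift estimation

Long acquisitions show a mild, approximately linear drift.  The slope is
estimated per cell from the baseline epoch only (the one window known to be
unstimulated) and subtracted, anchored at the first timestamp so *b* is
preserved.

The default estimator is Theil–Sen: the median of all pairwise slopes
(x_j − x_i)/(t_j − t_i) within the baseline window.  A simpler "median of
successive differences / sampling interval" estimator is available
(`method="first-diff"`) but not recommended: at 10-second sampling the
per-step drift increment (~3×10⁻⁴ ratio units) is two orders of magnitude
below the noise of a single difference, so that estimator's error
(≈ 1.25·σ/(Δt·√n) ≈ 0.02 ratio units/min at 2% noise) exceeds the drift it
removes tenfold and imposes spurious ramps of ±1.5 ratio units over 80
minutes.  Theil–Sen keeps the same robust median character (insensitive to
isolated baseline transients) with near-OLS efficiency
(error ≈ 3×10⁻⁴/min under the same conditions).

Even so, any slope fitted on a 20-minute window is extrapolated ~50
minutes to the KCl epoch; at 2% noise the 2σ band of that extrapolation is
about ±0.05 ratio units.  This matters for QC (below).

## Quality control

A cell is removed when (median KCl signal − *b*)/*b* < threshold (default
0.05, strict inequality), evaluated on the drift-corrected trace; cells
with non-positive baseline are removed outright.  The threshold may
instead be applied in absolute ratio units (`mode="absolute"`).  QC must
run on drift-corrected traces: an uncorrected drift of 0.002/min alone
lifts a dead-flat cell ~13% over baseline by the KCl epoch and would let
every non-excitable cell pass.  The flip side is that the drift
extrapolation error sets the resolution of the 5% rule — at measurement
noise of 2% of the KCl step, a truly unresponsive cell's measured response
is centred on 0 with σ ≈ 0.023, so roughly 1–2% of such cells per run land
marginally above the 0.05 cut.  Sensitivity reaches 100% as noise → 0.
QC is idempotent: filtering an already-filtered dataset removes nothing.

## The nine features

For a QC-passing cell (all normalised by *N*; MAD is the raw median
absolute deviation, no consistency constant; features never emit NaN):

| feature | definition | degenerate convention |
|---|---|---|
| high_glucose_response | (median high-glucose − *b*)/*N* | — |
| high_glucose_oscillation | MAD(high-glucose)/*N* | — |
| low_glucose_oscillation_pre | MAD(first low-glucose)/*N* | — |
| low_glucose_oscillation_post | MAD(second low-glucose)/*N* | — |
| response_speed (min⁻¹) | 1/(time from high-glucose onset to first peak) | 0 if no peak; first-sample peak → one sampling interval |
| counted_peaks | number of qualifying high-glucose local maxima | — |
| oscillation_frequency (min⁻¹) | 1/mean inter-peak interval | 0 if < 2 peaks |
| return_to_baseline | (min(second low-glucose) − *b*)/*N* | may be negative |
| kcl_response | (max(KCl) − *b*)/*N* | ≥ 1 by construction |

"Low-glucose oscillation" is deliberately two features (before and after
the high-glucose epoch): the pre window captures spontaneous activity, the
post window captures incomplete return to baseline — the signature of
non-oscillating rapid responders.

**Peak detection.**  Local maxima are strict (greater than both
neighbours); a plateau of tied samples contributes one peak at its first
sample; an epoch endpoint counts when it exceeds its single interior
neighbour — all so the count is deterministic on discrete samples.  A
candidate qualifies as a true peak when its *topographic prominence*
within the epoch (height above the higher of the two minima separating it
from taller terrain or the epoch edge) is at least *N*/3.  Prominence is
the default because a height-above-baseline rule counts every
measurement-noise wiggle riding on an elevated plateau: a non-oscillating
responder sitting at 0.6 *N* would register dozens of spurious "peaks" at
the noise rate, inverting the frequency–magnitude relationship the method
is designed to expose.  Height-above-baseline and height-above-epoch-median
rules remain available (`qualification=`), and the threshold scales with
*N* in every mode, preserving affine invariance.  Oscillation frequency is
derived from peak periodicity (mean inter-peak interval), not from
peak count / epoch length, so it is unbiased by response latency.

## Clustering

**Trace space.**  d(i,j) = (1 − ρᵢⱼ)/2 with ρ the Spearman correlation of
the two full traces (average ranks on ties) — invariant under any strictly
monotone per-cell transform.  A constant trace has undefined ρ; it is
treated as ρ = 0 (d = 0.5) with a warning.  Classical (Torgerson) MDS
embeds the matrix by double-centring and eigendecomposition; dimensions are
ordered by eigenvalue, negative eigenvalues are clipped to zero, and each
axis's sign is fixed (largest-magnitude coordinate positive) so the
embedding is deterministic.  Field structure is screened per dimension:
the mean silhouette width of all cells on that single coordinate with
imaging fields as labels (a joint multi-dimensional silhouette is a
possible alternative; per-dimension was chosen because it pinpoints
*which* axes carry batch-like structure).

**Feature space.**  Cells: Ward linkage on Euclidean distance over
per-column z-scored features (constant columns dropped with a warning).
Features: average linkage on 1 − |Spearman| between columns.  Flat
clusters are cut with the `maxclust` criterion; the leaf order is kept
for heatmap rendering.

**Mixtures.**  `GaussianMixture` is fitted for every (K, family) pair,
K = 1..8 and families spherical/diagonal/tied/full, with 10 k-means-seeded
EM restarts per candidate and essentially no covariance regularisation
(reg 10⁻¹⁰).  Selection minimises BIC = −2 log L + p log n (note: some
ecosystems maximise the negated form; the sign convention is fixed here to
avoid ambiguity).  A candidate whose smallest component variance collapses
below 10⁻⁸ is discarded with a warning rather than regularised, keeping the
likelihoods of surviving candidates comparable.  The family search mirrors
mclust-style practice since the appropriate covariance structure is not
known a priori.  With K = 3 on (high_glucose_response,
high_glucose_oscillation), components are labelled: lowest mean response →
non-responder; of the rest, higher mean oscillation → oscillating
responder; exact ties break by cluster index with a warning.  The
responder proportion is (oscillating + non-oscillating)/(QC-passing cells).

## Inference

Spearman tests use the exact permutation null (full enumeration of
pairings) for n ≤ 10 and the two-sided t approximation
t = ρ√((n−2)/(1−ρ²)) beyond — a whole imaging run (hundreds of cells) is
firmly in approximation territory.  The field-homogeneity test is
Pearson's χ² on the fields × {responder, non-responder} table without
continuity correction; a likelihood-ratio (G) test and, for two fields,
Fisher's exact test are options.  The χ² default was chosen because it is
the standard k × 2 proportion-homogeneity test.  P-values are floored at
the smallest positive double (flagged when hit) so −log₁₀ P stays finite.
No multiple-testing correction is applied by default; a Bonferroni helper
exists.

## Synthetic data generator

The generator is the package's study-condition emulator: 300 cells,
3 imaging fields, 480 timepoints/80 min, sub-type weights
(0.40, 0.31, 0.24, 0.05) for oscillating responders, non-oscillating
responders, non-responders and KCl-dead cells.  Per cell: baseline
~N(1.0, 0.05) ratio units, KCl step amplitude A ~ N(1.0, 0.1), drift slope
~N(0.002, 0.001)/min, additive Gaussian noise σ = 0.02 (2% of the mean KCl
step).  All response amplitudes are fractions of A, matching the feature
normalisation.  Type kinetics: oscillators rise (latency ~1.2 min) to a
0.5 A plateau carrying a sinusoid of amplitude 0.25 A, period 3.5 min with
±10% per-cell jitter and random phase; non-oscillating responders rise
faster (latency ~0.4 min) through a first-phase overshoot (0.6 A, τ = 2
min — the textbook biphasic β-cell response, and what gives them a
defined "first peak" and hence a response speed) to a 0.6 A plateau, then
oscillate slowly (0.12 A) during the second low-glucose window instead of
returning to baseline; non-responders carry only small (0.05 A)
spontaneous low-glucose fluctuations plus the KCl step; KCl-dead cells
are flat.  Non-responders (and dead cells) are placed in fields with
probabilities (0.2, 0.2, 0.6) versus (0.4, 0.4, 0.2) for responders,
emulating inhomogeneous dispersion of the tissue.  Generation is
bit-identical for a fixed seed.

What the generator does **not** emulate: phase-0 dips at glucose onset,
bursting/electrophysiological fine structure, non-sinusoidal or
frequency-drifting oscillations, heavy-tailed or correlated noise,
photobleaching beyond linear drift, and within-field spatial correlation.
Consequently, passing tests demonstrate that the implementation computes
its definitions correctly and that the method separates populations with
this geometry; they do not certify performance on real recordings, where
sub-type overlap is larger (correlation strengths measured on synthetic
runs are accordingly stronger than those seen on real data, and the
responder proportion reflects the configured mixture, ~0.75 of QC-passing
cells).

## Problem sizes and numerical tolerances

Replication-based checks use 100 replicate seeds of the 300-cell preset
(QC agreement; BIC model selection, which selects K = 3 in 100/100
replicates, asserted ≥ 90).  Property checks use 1000 random affine
transforms, full permutation enumeration for n ≤ 7, planar MDS
reconstruction at relative stress < 10⁻⁶, noiseless-ramp drift flattening
to |slope| < 10⁻⁹, GMM mean recovery within 3 standard errors at ≥ 95%
label accuracy, and 1000-simulation type-I-error checks at α = 0.05 ± 0.02
for both tests.  EM uses at most 300 iterations at scikit-learn's default
tolerance.

## Known limitations

* The 5% QC rule's effective resolution is set by drift-correction
  extrapolation (±2σ ≈ ±0.05 ratio units at 2% noise); borderline
  unresponsive cells can slip through in either direction.
* Exact Spearman enumeration above n ≈ 8 is slow (n! pairings); the n ≤ 10
  switch point is a compromise and the t approximation takes over beyond.
* Fisher's exact option is limited to two fields.
* The generator ties oscillation magnitude and frequency only through
  sub-type membership; within-type frequency–amplitude coupling is not
  modelled.
* Only the 80-minute five-epoch protocol is generated synthetically
  (analysis accepts any valid protocol).
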
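# Methods

`midzone` re-implements, as a tested library, the quantitative analyses
used to characterize the anaphase spindle midzone of the *C. elegans*
one-cell embryo: microtubule interaction statistics on electron-tomography
tracings, microtubule polarity from combined second-harmonic-generation
(SHG) and two-photon (TP) imaging, spindle pole/chromosome tracking on
two-channel time-lapse movies, midzone intensity / EB-comet / FRAP
quantification, and single-molecule track summaries.  Because the raw
tomograms and movies such analyses are normally run on are large
microscope outputs, every stage is exercised on seeded synthetic data with
known ground truth; this note states each model, its assumptions and
parameters, and what the synthetic benchmarks do and do not demonstrate.

## Filament networks and the interaction statistic

Tracings are sets of 3D polylines in nm (`filaments.FilamentNetwork`),
read from Amira SpatialGraph ASCII or CSV.  Filaments shorter than 100 nm
are excluded before any statistic (`filter_short`), reflecting the minimal
reliable tracing length of the tomography pipeline the data model mirrors.
The bounding volume defaults to the tight axis-aligned box of all points
(its volume in um³ is the denominator of the density statistic); when a
specific sub-volume was used to delimit a reconstruction it must be passed
explicitly, since nothing in the file format records it.

An *interaction* is a contiguous stretch of one microtubule lying within a
center-to-center distance `d_max` (default 100 nm) of another microtubule
for at least `l_min` (default 100 nm) of arc length.  The implementation
resamples the source filament at a uniform arc step (`resample_step`,
default 20 nm, well below both thresholds), computes the exact
point-to-polyline distance at each sample, takes maximal in-threshold
runs, and refines the two run boundaries by linear interpolation of the
distance profile across the threshold crossing.  Runs shorter than `l_min`
after refinement are dropped; a single out-of-threshold sample splits a
run (no gap bridging).  No angle restriction is applied.  The reported
angle of a pair is measured between the lines through each filament's
start and end points, in [0, 180] degrees with 180 = antiparallel (a
folded [0, 90] variant exists for orientation-agnostic summaries).

Interactions are ordered-pair records — the parts of the *source* near
the *target* — so a mutually overlapping pair contributes two records, and
interaction counts are counts of ordered-pair runs.  A `symmetric` mode
deduplicates to one direction per unordered pair; because the two
directions' runs live on different filaments' arc-length axes, a literal
union is not well defined, so symmetric mode keeps the direction with the
larger total run length (ties toward the smaller id).

Pairwise filament distances are exact minima over all segment pairs
(closed-form segment-segment distance, vectorized); nearest-neighbor
queries prune with bounding-box lower bounds without changing the result.
A uniform 3D grid over segments accelerates the interaction scan: with
cell size ≥ `d_max` only the 27-neighborhood of a sample's cell needs
visiting, smaller cells simply widen the search ring, and the
out-of-threshold samples that bracket each run are re-evaluated with a
full scan so boundary interpolation is bit-compatible with the unindexed
path.  Equivalence with a dense 1 nm brute-force scan is asserted in the
test suite over 50 seeded random networks.

Summary statistics use the population standard deviation (divisor N).
Distance-bin fractions default to 5 nm bins over 25–100 nm plus an
overflow bin, mirroring the common red(25 nm)→white(>100 nm) color coding
of interaction maps.  With zero interactions the interaction statistics
are reported as absent (`None`), never as zero.

## Polarity and the SHG/TP imaging model

The polarity of a microtubule array over a region is
|n⁺ − n⁻| / (n⁺ + n⁻) of plus-end orientations relative to the spindle
axis: 1 for a parallel array, 0 for balanced antiparallel.  A region
containing no filaments has undefined (masked) polarity.

SHG is a coherent signal from a non-centrosymmetric arrangement and
depends on both polarity P and density ρ, while TP fluorescence reads
density alone.  The forward model used here is the minimal one consistent
with that physics:

    TP  = α·ρ + ε,    SHG = β·(ρ·P)² + ε,

quadratic in the net aligned dipole density ρ·P because SHG is coherent.
The exact imaging law of a given instrument (wave plates, Gouy phase,
focal-volume coherence) is out of scope; the model is isolated in
`shg_tp_forward` so a different law can be substituted without touching
the inversion interface.  Inversion is
P = clip(√(SHG / (κ·TP²)), 0, 1) with κ = β/α², evaluated only where TP
exceeds a floor and masked elsewhere — masking, not zero-filling, so
low-density pixels never contribute spurious polarity.  κ is calibrated as
the median of SHG/TP² over a reference region assumed fully parallel; the
median is robust to outliers and the region choice is an explicit input.

Axial profiles average the polarity map in slabs perpendicular to the
pole-pole axis, positions in um relative to the spindle center.  The
*overlap width* is the full width of the central polarity dip at a
fractional depth (default 0.5) between the minimum and the mean of the two
flank maxima, with linear interpolation between samples; full width at
half depth is the standard, parameter-free-in-spirit choice where no
specific width definition is canonical, and the level is exposed.  The
width is invariant under uniform scaling of polarity values and
translation of positions.  The metric is defined on the dip of P (the
antiparallel zone); profiles that are monotone raise a no-dip error rather
than returning a number.

## Spindle tracking

Raw multi-channel movies are converted to 8-bit per channel by a global
(whole-movie) min-max mapping rounded half away from zero; global rather
than per-frame scaling keeps the fixed threshold bands stationary in time.
The top-fraction band (low = floor((1−p)·255), high = 255) reproduces
(191, 255) at p = 0.25 and (127, 255) at p = 0.5 — the pole and chromatin
bands.

Embryo outlines come from watershed segmentation of the temporal median
projection of the tubulin channel (background and eroded-interior seeds on
the gradient image).  Poles are the two largest connected components of
the blurred (3×3 Gaussian, σ = 0.8 px — the kernel size is conventional,
σ is a documented choice) spindle channel in the top-25% band, localized
as intensity-weighted centroids; anterior is the smaller coordinate along
the embryo long axis by default and overridable.  Chromatin uses the
top-50% band; each leading edge is the extreme extent of thresholded
chromatin along the pole-pole axis relative to the midzone (the pole
midpoint), refined to sub-pixel by interpolating the band-maximum
intensity profile to the threshold crossing.  Frames where detection fails
are flagged invalid and never silently interpolated.

Anaphase onset is the last frame before visible chromosome segregation,
operationalized as the frame before the first run of `persist` (default 3)
consecutive frames in which the chromatin has ≥ 2 masses with an axial gap
above `gap_min` (default 1 um).  Both parameters are exposed because
"visible" is qualitative.  Segregation and spindle-elongation rates are
displacements of leading-edge separation and pole-pole distance over the
first 40 s after onset, divided by 40 s.

Kymographs resample each frame (bilinear) on a grid aligned with that
frame's pole axis, centered on the midzone, summing 2·5+1 rows — the
equivalent of rotating the frame so the axis is horizontal and band-summing
±5 px around the axis row.  Out-of-bounds pixels contribute zero; invalid
frames produce NaN sentinel rows.  Enhancement is local-mean adaptive
thresholding (foreground must exceed the local mean by 5% of the dynamic
range, suppressing background speckle) followed by skeletonization.

## Intensity, comets, FRAP

Midzone intensity is (mean(ROI) − mean(background ROI)) / mean(background
ROI).  Axial intensity profiles are means of an ROI box per axial bin;
peak widths are full width at half of (peak − background) with linear
interpolation, raising an error when the peak touches the domain edge.

EB-comet events are counted on a kymograph segment (defaults 4.5 um and
100 s) binarized at background + 10% of (max − background) — the "10%"
threshold is interpreted relative to the background-subtracted maximum,
a declared choice since percentage thresholds are tool-convention
dependent — and counted as 8-connected components of ≥ 2 px (the 2 px
minimum suppresses single-pixel noise and is a parameter).  Crossing
trajectories merge into one component; that is a documented limitation of
the component definition of an event.

FRAP recovery uses the single-exponential model
F(t) = F₀ + (F∞ − F₀)(1 − e^(−kt)), fitted by least squares with k ≥ 0;
the mobile fraction is (F∞ − F₀)/(prebleach − F₀).  A flat post-bleach
curve returns fraction 0 (k is then unidentified and reported as 0)
rather than failing.

## Single molecules

Track summaries consume particle-tracking output tables; detection and
linking are upstream.  The primary speed estimator is path length over
elapsed time — appropriate for processive motors — with net displacement
over time also reported.  Run length is the net start-to-end displacement.
Brightness-speed association is the Pearson r (with two-sided p) between
per-track median intensity and speed over tracks faster than a "moving"
floor of 0.075 um/s; the floor applies only to association analyses, never
to raw summaries.  Co-appearance fractions are exact count ratios at full
precision — counts of 39 in 70,670 evaluate to 0.0552%, and any coarser
printed rounding is left to the caller.

## Synthetic data

Generators are deterministic functions of (parameters, seed) and attach a
`SyntheticGroundTruth` sufficient to predict the paired analysis output in
closed form.  The noise model throughout is additive Gaussian read noise
plus a Gaussian approximation to Poisson shot noise (variance ∝ signal).
Default scales are the field's control-condition values: ~70 nm neighbor
spacing and ~0.9 um mean filament length for midzone-like networks,
14 um metaphase spindles elongating at 0.09 um/s with chromosomes
segregating at 0.13 um/s after onset, FRAP mobile fraction 0.34 at
k = 0.05 s⁻¹, single-molecule speeds around 0.2 um/s with 2 um mean run
length.  These presets define realistic test conditions; recovering them
demonstrates pipeline correctness on data of that character, not a
reproduction of any measured dataset.

Specific design points:

* **Overlap-pair networks** place isolated coaxial equal-length pairs, so
  the designed interaction length equals the filament length and the
  designed minimum distance equals the lateral spacing.  Unequal or
  staggered pairs would add end-cap extensions of √(d_max² − s²) to every
  run, which is why full overlap of equal extents is the geometry used for
  recovery benchmarks.
* **Mitosis movies** render the chromatin as one compact plate that splits
  at onset into two masses whose *outer* (leading) edges move continuously
  at the segregation rate while the inner gap opens immediately (default
  2·(1.5 − 0.9) = 1.2 um, i.e. visible segregation from the first
  separated frame).  This keeps leading-edge separation piecewise linear —
  so rate recovery is exact up to one frame-interval of onset quantization
  — while making onset detection unambiguous.  Pole transverse
  oscillation is anti-phase sinusoidal with a small default amplitude
  (0.2 um).
* **Comet kymographs** default to a canvas equal to the standard counting
  window (100 s × 4.5 um) with a minimum Chebyshev separation between
  trajectories, so the designed count is exactly the count in the analyzed
  segment.

What the synthetic benchmarks do *not* show: robustness to uneven
illumination, embryo drift or rotation beyond rigid motion, sample-to-
sample variation in chromatin morphology, tracing errors in real
tomograms, or the validity of the declared SHG law on a particular
microscope.  Quantities whose real values derive from such data (absolute
interaction-length or density means of real spindles, measured FRAP
fractions) appear here only as documented preset scales.

## Problem sizes and numerical choices

Test and benchmark sizes are chosen to exercise every code path at
desk scale: 50 random networks of 12 filaments for oracle equivalence
(the dense oracle samples at 1 nm), 20 movies of 80 frames at 0.25 um/px
(128×224) for tracking recovery, 50 noisy replicates for the imaging and
FRAP ensembles.  Tolerances follow from construction: interaction lengths
to 2× the resample step, tracked distances to one pixel, rates to 5%
(one frame-interval of onset quantization contributes 2.5% at the default
40 s window), onset to ±1 frame.  Ties in nearest-neighbor queries break
toward the smaller filament id; degenerate (point) segments are handled
exactly in the distance kernel; profile crossings interpolate linearly and
refuse to extrapolate past domain edges.
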
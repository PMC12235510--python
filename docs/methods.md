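# Methods

This note documents the models implemented in `fluoropaint`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Camera model and spot photometry

The sCMOS camera is linear: `ADU = baseline + gain · photons` with
`gain = sensitivity × quantum_efficiency`. Defaults (baseline 400 ADU,
sensitivity 2.75 ADU/e⁻, QE 0.82, 117 nm pixels) are typical
single-molecule TIRF values. Photon conversion preserves sub-baseline
(negative) values so that averaging stays unbiased.

Spot detection mimics the Picasso-localize approach: candidates are box
local maxima (default box 7 px) whose box-summed absolute finite-difference
gradient exceeds a threshold (default 3000, applied in the units of the
input frame — ADU for raw movies). Exact bit-compatibility with Picasso's
gradient score is not claimed. Fitting is a least-squares symmetric 2D
Gaussian plus constant, initialized from moments; reported photons are the
integrated amplitude `2π·A·σ²`. Non-convergent or degenerate fits return
`fit_ok = False`, never an exception.

Background extraction averages the central half of each axis (a "central
area" convention; half avoids vignetting and edge effects) over the first
10 frames, in photons after baseline subtraction. Because the background is
defined as the emission of *unbound* probes, pixels carrying immobilized
spot signal are masked first (robust threshold on the lightly smoothed
time-averaged crop, dilated 4 px). Without this, spot placement leaks a
field-of-view-dependent offset into the mean that swamps the small molar
backgrounds of strongly quenched probes; the linear regression's slope
would then be dominated by placement noise rather than concentration
response.

## Fluorogenic factor

`FF = S_N / B_N,mol` with `S_N = S_FQ / S_F` and
`B_N,mol = B_FQ,mol / B_F,mol`. Normalizing both numerator and denominator
to the same fluorophore-only reference cancels global brightness changes
(quantum-yield differences between ssDNA and dsDNA states, excitation
power), which the property suite verifies as exact gain invariance.

Brightness distributions are fitted as 1- or 2-component Gaussian mixtures
on the raw photon counts (bin-width independent); BIC selects the model.
Probes with non-functional quenchers emit at the reference level, so when a
reference mean is available any component within ±20% of it is excluded
(the exclusion window is a package choice; the underlying observation is
only that the contaminating population matches the F-only brightness). The
remaining highest-weight component supplies `S_FQ`. Molar backgrounds are
OLS slopes of background vs concentration; `se_FF` follows from first-order
propagation (relative errors in quadrature).

## Dwell-time kinetics

Traces are segmented by a two-state Gaussian-emission HMM (hmmlearn),
EM-trained from a k-means initialization of the level means and decoded by
Viterbi; the higher-mean state is "bound". Constant traces are returned as
flagged single-state results. Run lengths × frame time give dwells; the
first and last run of each trace touch the observation boundaries and are
excluded from fitting (kept separately) rather than modelled as censored —
this matches the truncated-likelihood formulation below.

Lifetimes maximize the truncated-exponential likelihood
`f(t) = (1/τ)e^(−t/τ) / (e^(−t_min/τ) − e^(−t_max/τ))` with `t_min` one
frame and `t_max` the trace duration. The likelihood depends on the data
only through the sample mean, so the MLE is a cheap 1-D bounded
minimization (stable log-space evaluation via `log1p`), and the seeded
nonparametric bootstrap (default 1000 resamples, percentile 95% CI) reuses
the same solver on resampled means. Two boundary pathologies are reported
as errors rather than silently returned: all dwells at `t_min` (τ → 0) and
a sample mean at or above `(t_min + t_max)/2` (the truncated model
degenerates toward uniform, τ → ∞).

Empirically (see the end-to-end kinetics tests), `t_min = 1 frame` is the
right truncation for HMM-decoded, frame-discretized dwells: the
majority-rule discretization alone would suggest an effective threshold of
half a frame, but Viterbi's transition prior slightly inflates run lengths
and the two effects cancel at the stated conditions. Two regimes limit the
chain and are deliberately reflected in the test conditions: dwells should
span several frames (frame-straddling transitions are inherently ambiguous)
and unbound sojourns should be long relative to a frame (sub-frame gaps
merge adjacent events and inflate τ).

## PAINT simulation

Binding events per segment follow a Poisson process; each event picks one
of the segment's docking sites, drawn once per segment uniformly over the
2D projection of the cylinder (a stadium: rectangle of width 2·radius plus
semicircular caps — the projection of a 3D rod onto the imaging plane).
Dwells are exponential; an event yields one localization in every frame it
overlaps by at least half the exposure (equivalently: every frame whose
midpoint it covers). Localizations get isotropic Gaussian error, cumulative
linear drift, and Poisson photon counts; nonspecific localizations are
single-frame events uniform over the FOV at a configured areal rate. The
closed form for the expected localization rate per segment,
`k_on (τ + Δ/2) e^(−Δ/(2τ)) / Δ`, is exposed (and verified against the
event log) so studies can be parameterized directly by localization rate.
One master seed spawns independent child streams (events, sites, errors,
nonspecific, photons); all outputs are bit-reproducible.

Not emulated: dye photophysics beyond Poisson shot noise (no blinking or
bleaching), 3D PSFs, FRET-distance physics (ground-truth `s_n`/`b_n` are
inputs, not derived from R₀ — no quantitative model links probe length or
R₀ to quenching), camera readout noise, and nonlinear stage drift. Passing
tests therefore demonstrate the correctness of the analysis chain under
these idealized conditions, not robustness to every artifact of real
microscope data.

## Drift correction

Localizations are rendered per 100-frame window as 10 nm histograms with a
light Gaussian blur and registered by subpixel cross-correlation
(skimage `phase_cross_correlation`, plain correlation, 20× upsampling).
Each window is pre-shifted by the running estimate and registered against
the *first* window, so estimation errors do not accumulate as a random
walk; the per-window increment is capped at 60 nm (the "max drift per
segment" convention). Window-center estimates are linearly interpolated per
frame. Windows with fewer than 10 localizations carry the previous estimate
forward with a warning.

## Clustering and on-rates

DBSCAN runs on nm coordinates with `eps = 0.5 × pixel` and
`min_samples = round(0.01 × frames)` unless overridden; a `min_samples`
that rounds below 1 is an error instructing an override. Localizations are
sorted by (frame, x, y) before clustering so border-point assignment is
deterministic. Clusters are kept when core-ratio > 0.8; the ambiguous
"component number" criterion sometimes applied alongside it is exposed only
as an optional user predicate (off by default) rather than guessed at. The
on-rate is raw localizations per cluster per second (an event-linking mode
that merges consecutive-frame localizations is reported separately on
request); mean ± SEM across clusters.

## Morphometry

Per cluster: localizations are rendered as unit-integral pixel-integrated
Gaussians (σ = 3.9 nm) on a 1.95 nm grid (σ/2; the rendering pixel is not
dictated by the source protocol), low-pass filtered by a radially symmetric
order-1 Butterworth, Gaussian-blurred (σ = 5.85 nm), binarized with the
exact-value ISODATA intermeans threshold (cross-checked against
scikit-image's histogram version), stripped of connected components larger
than 5000 nm², and thinned to a Hilditch skeleton (two-phase passes:
candidates from the pass-start snapshot, sequential deletion with a live
connectivity re-check — one boundary layer per pass, so erosion stays
symmetric). The spine is the longest geodesic between the two most distant
skeleton pixels (double Dijkstra, Euclidean step weights, lexicographic
tie-breaks); the radius is the median distance from spine pixels to the
subpixel marching-squares boundary contour, which equals the Euclidean
distance transform minus half a pixel on axis-aligned strips.

The Butterworth cutoff (0.02) is interpreted as **cycles per nm** (a 50 nm
cutoff period), i.e. the conventional value on a 1 nm rendering grid. This
keeps the filter invariant to the package's rendering-pixel choice;
interpreting it as cycles per 1.95 nm pixel doubles the blur, inflates
recovered radii by ~25%, and pushes many otherwise valid segments over the
5000 nm² area cap.

Known biases, measured by the test suite at the study conditions (16 nm
rods, 6 nm precision, ~150 localizations): the recovered median radius runs
about +1 nm high (blur/threshold widening partially cancelled by the
discrete spine sitting slightly off-center), well inside the ±3 nm band
expected from the localization precision; single-cluster radii carry ~1 nm
orientation/sampling scatter, so rotation robustness holds for medians over
clusters rather than per cluster; spine lengths are unbiased in the median
but individual rods scatter by ±10 nm.

## Fourier ring correlation

Clusters with ≥ 20 localizations are split at random into halves (random
splits rather than odd/even frames, because binding events span several
consecutive frames and would correlate the halves), each half rendered at
1 nm with σ equal to the localization precision (3.9 nm when unknown), and
the ring-normalized cross-spectrum averaged over 5 seeded splits. The curve
is fitted with `A·exp(−f/f₀)` (A clipped to [0, 1.05]; whether the source
protocol fixed A at 1 is unknown, so A is free) and the resolution read at
the 1/7 threshold, `resolution = 1/(f₀·ln(7A))`; a curve that never crosses
reports an undefined resolution rather than failing.

Because the rendering blur cancels in the ring normalization, FRC
resolution is bounded by the localization-error decorrelation
`e^(−(2πfσ)²)`: at σ = 6 nm the 1/7 crossing cannot reach 10 nm at any
realistic event count (the suite measures ~17 nm at 200 localizations and
verifies monotone improvement with N); sub-10 nm values require σ ≲ 3 nm,
which the suite demonstrates at that precision. Spurious-correlation
corrections and fixed-2σ threshold variants are out of scope.

## Problem sizes

The acceptance studies use 200 segments × 300 s at 20 ms frames (~79k
localizations) for the on-rate recovery, 100 rods × 150 localizations for
the radius recovery, and 2 × 5 movies of 256² px × 10 frames with 300
molecules for the FF recovery; the bootstrap-coverage check runs 200
replicates of 2000 dwells with 1000 bootstrap resamples each. These sizes
were chosen so each quantity's sampling error sits well below the tolerance
it is compared at.
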
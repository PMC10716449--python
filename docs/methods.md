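# Methods notes

This note records the models behind each module, the defaults that
matter, and the design choices made where more than one reasonable
implementation exists. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Generative model (simkit)

**Kinetic scheme.** Conformational dynamics are modelled as a
continuous-time Markov chain over discrete states, each with a mean FRET
efficiency. Trajectories are drawn with the Gillespie algorithm. The
initial state is drawn from the stationary distribution of the rate
matrix (molecules are observed at steady state); it can be overridden
per call. A state with no outgoing rates is absorbing, not an error.
For a two-state scheme the relaxation time of any linear observable is
1/(k₁₂ + k₂₁), which is the closed form used throughout the recovery
tests.

**Trace rendering.** Camera frames integrate the trajectory: the
efficiency entering a frame is the time-weighted mean of the state
efficiency over the integration window (100 ms frames straddle jumps at
the seconds-scale kinetics simulated here). The rendering convention is

    F_D = I · (1 − E),   F_A = γ · I · E + β · F_D

because it makes the corrected-efficiency formula an exact inverse of
the renderer — the one self-consistent choice. This identity is asserted
to 1e−12 frame-wise in the tests for arbitrary β ≥ 0, γ > 0.

**Photophysics.** Bleaching is single-step and irreversible, with
exponential bleach times per dye. After donor bleach both FRET channels
fall to background; after acceptor bleach the donor rises to the full
intensity I and the acceptor channel retains only bleed-through β·I.
Direct-excitation (ALEX) frames report the acceptor until it bleaches.
Blinking is omitted: the buffer system emulated here (Trolox/COT/NBA
with oxygen scavenging) suppresses it. Both are extension points.

**Noise.** Camera noise is Gaussian with variance
`excess_noise_factor · signal + background_sd²` on top of a constant
background offset. This approximates EM-multiplied detection (the
excess-noise factor of an EM register is ≈ 2) and is adequate at the
multi-thousand-count signal levels simulated; the full EM gain-register
cascade is deliberately not modelled, and the true camera statistics of
any specific instrument are not claimed. Defaults: 3000 counts/frame
total intensity (comfortably above the 2000-count selection threshold),
background 200 ± 30 counts, excess-noise factor 2.

**Timing.** The default illumination schedule is 100 ms integration,
0.3 ms inter-frame gap, and a cycle of 99 orange frames followed by one
far-red (direct acceptor excitation / reference) frame, repeated 40
times.

**Binding timelines.** Dark intervals are exponential with the apparent
on-rate; bright intervals are drawn from a mixture of exponentials
(fractions and ascending residence times), the generative inverse of
the bi-exponential residence-time distribution. The first and last
segments are censored. Frames straddling a transition receive the
time-weighted intensity.

**FRAP curves.** On the normalized scale the recovery is
R(t) = (1 − f)·(1 − e^(−t/τ)) with immobile fraction f. Raw curves add
a bleach depth (default 0.8 of the pre-bleach signal), multiplicative
acquisition photobleaching applied identically to the bleached and the
reference ROI (default 2·10⁻⁴ s⁻¹), and Gaussian noise (default 2% of
the pre-bleach intensity). Defaults use 5 pre-bleach and 200 post-bleach
frames at 7.2 s intervals, i.e. a ~24 min imaging window, matching the
regime where the slow recovery does not reach plateau.

**Movies.** Spots are symmetric Gaussians integrated over pixels (erf
form), rendered per channel at transform-mapped, drift-shifted
positions, with Poisson shot noise plus Gaussian read noise. Rendering
fixtures keep pairwise spot separations above 4 PSF widths. The
ground-truth registry (positions, traces) is returned alongside the
stack.

**Seeding.** Every stochastic function takes a seed or Generator; a
master seed derives per-molecule streams via `SeedSequence`. Same seed
gives bit-identical output.

## Trace extraction (imaging)

Coordinates are 0-based pixel-center, x along columns; all transforms
are in pixel units, which round-trips exactly with the renderer.

*Background*: grayscale opening with a disk (rolling-ball equivalent);
the residual is median-centred because the opening tracks the lower
noise envelope and would otherwise bias extracted intensities upward.
Parity is with the simulator's ground truth, not with any specific
ImageJ implementation.

*Detection*: local maxima above a robust (median/MAD) threshold with
non-maximum suppression, refined by least-squares symmetric 2-D Gaussian
fits; fits that fail, have vanishing amplitude, or exceed the PSF-width
cap (default 2.5 px — clusters and out-of-focus emitters) are rejected.

*Registration*: least-squares affine from ≥ 3 non-collinear matched
points (in practice 4–6 spots visible in both channels); collinear
input is rejected; the training residual RMS is reported.

*Drift*: image cross-correlation of each far-red reference frame
against the first (plain cross-correlation, not phase-whitened, which
is noise-sensitive on sparse spot images), linearly interpolated across
the intervening orange frames. Featureless frames carry the previous
offset forward with a warning.

*Extraction*: sum of pixels whose centers lie within a fixed radius
(default 2 px) of the drift-corrected position; positions whose disk
leaves the frame are flagged edge-clipped.

*Filtering*: forward–backward nonlinear (Chung–Kennedy) filter, default
window 8 frames and weighting exponent p = 2. Output is a weighted mean
of a causal and an anti-causal running mean with weights equal to the
local mean-squared prediction error to the power −p, which smooths
plateaus while preserving step edges; on noiseless piecewise-constant
input a second application changes nothing.

## smFRET analysis (fretkit)

Defaults β = 0.071 and γ = 0.463 are the calibration of the emulated
instrument for the Cy3B/Alexa647 pair; both are estimable from data
(`estimate_corrections`). β is the mean acceptor/donor ratio over
donor-only traces. γ is the ratio of acceptor drop to donor rise across
acceptor-bleach steps, measured on the *bleed-through-corrected*
acceptor channel: on the raw channel the acceptor-bleach step includes
the loss of the bleed-through term and the ratio would estimate γ − β
instead of γ.

**Bleach detection** (unspecified in most published pipelines) is a
two-plateau change-point: the split minimizing total squared error,
kept when the drop exceeds 4× the frame-to-frame noise, recursed once
so two-dye traces yield two steps. Dye-level events are then resolved
on two derived channels: donor bleaches are steps in the *total*
intensity F_D + (F_A − βF_D)/γ, which is invariant under FRET-state
changes and therefore immune to dynamics-induced false positives;
acceptor bleaches are steps in the corrected acceptor F_A − βF_D that
are (a) not coincident with a donor step (a donor bleach darkens both
channels) and (b) permanent — the corrected acceptor must stay at
background for the remainder of the trace, which separates a bleach
from a transient excursion to a low-FRET conformation.

**Selection** follows the standard criteria: initial total intensity
(donor plus γ-corrected acceptor) > 2000 counts over the post-donor-
bleach baseline; ≥ 5 s before the first bleach; a single bleach event
per dye; on acceptor-first bleaching the donor must rise to the
pre-bleach total level (tolerance 25%); on donor-first bleaching the
direct-excitation acceptor must remain fluorescent. ALEX validation
additionally requires the acceptor present at the start with at most
one downward ALEX step. The first violated criterion is the reported
rejection reason.

**Histograms** span [−0.1, 1.1] (noise pushes efficiencies outside
[0, 1]) with bin width 0.02; each trace longer than 5 s is normalized
to unit mass before averaging so every molecule carries equal weight;
across independent repeats the per-bin mean and SD are reported.

**Mixture fits** implement the component form A·exp(−((x−c)/σ)²)
exactly as conventionally printed for this assay — without the factor
½ in the exponent — so σ differs from a Gaussian standard deviation by
√2. With k unspecified, three components are preferred over two only on
a ≥ 5% residual improvement.

**Dynamic/static classification** quantifies "anticorrelated intensity
fluctuations" as: any 2-s window with donor–acceptor Pearson r < −0.3
*and* filtered fluctuation amplitude above 3× the filter-attenuated
shot-noise level. Both thresholds are exposed. Static traces split at
mean E = 0.2.

**Cross-correlation** is computed per trace on mean-subtracted channels
up to the first bleach, then averaged with SEM across traces (whether
published pipelines pool fluctuations or average per-trace correlations
is ambiguous; per-trace averaging is the default here, and SEM across
traces is then the natural error). Lags start at one frame interval.
The fit model is −a·e^(−τ/τ_R) + c, a single exponential with offset
and explicit sign. Fits whose decay over the observed lag range is
smaller than twice the mean SEM are reported as zero-amplitude
(static); fitted τ_R below two frame intervals is flagged unresolvable.

## Binding kinetics (kinetics)

Events are detected by thresholding the filtered trace (default:
background mean + 3 background SD, with the noise SD estimated from the
*raw* trace — the filtered trace is smoothed and correlated and would
put the threshold inside the noise band). Bright runs shorter than 2
frames are discarded: at 100 ms framing a single-frame crossing is
indistinguishable from noise. Bright segments whose plateau exceeds
1.8× the single-molecule unit intensity (the median bright plateau) are
flagged as overlapping double-binding events and excluded; first/last
segments are censored.

Survival curves are unbinned empirical complementary CDFs — fitting the
unbinned curve avoids an arbitrary bin-width choice and is statistically
dominant over binned histograms. The bi-exponential fit uses multi-start
initialization (time constants seeded from the sample means of the
below-/above-median dwells at {0.5×, 2×}) to avoid the classic local
minima; amplitudes are constrained non-negative and components ordered.
A fit with τ₂/τ₁ < 1.5 or with under 5% of the amplitude in one
component collapses to a mono-exponential and is flagged. Dwells are not
corrected for dye photobleaching (residence times are reported as
observed); frame discretization biases a 6.9 s time constant by under
3% at 100 ms frames (asserted against the geometric-vs-exponential
closed form). Condition comparisons report mean ± SD across replicate
fits and two-tailed unpaired t-tests on the slow residence time.

## FRAP (frap)

Double normalization: ratio to the unbleached reference ROI first
(cancels acquisition photobleaching exactly when both ROIs bleach at
the same rate — an identity asserted in the tests), then an affine
rescale of the ratio mapping the pre-bleach mean (all pre-bleach frames)
to 1 and the first post-bleach frame to 0. Frames with a non-positive
reference are dropped with a warning.

The recovery model is a single exponential (one lifetime); a
double-exponential is deliberately out of scope for the default
pipeline. The immobile fraction is 1 − M from the *fitted plateau*, not
the last measured point: at τ ≈ 971 s a ~24-min window does not reach
plateau, so the plateau-from-fit is the only consistent estimator.
Replicate curves are averaged pointwise (linear interpolation onto the
first curve's time base where grids differ) with SEM, and the mean is
fitted — matching the published procedure of fitting the averaged
trace.

## What the simulations do and do not show

The generator reproduces the statistical structure the analyses rely
on: exponential mixtures of dwells, Markovian FRET exchange,
frame-integration, single-step bleaching, homogeneous Gaussian/Poisson
noise, rigid stage drift, and exponential FRAP recovery with a shared
acquisition-bleach rate. It does not reproduce dye blinking, spectral
fluctuations, non-Markovian dynamics, heterogeneous molecule
brightness, spatially structured background, within-exposure drift, or
reaction–diffusion FRAP kinetics. Passing recovery tests therefore
demonstrates the correctness and calibration of the estimators under
the stated model, not robustness to every artifact of real microscopy
data.

## Problem sizes

Recovery suites use sizes at which the estimators' sampling error sits
comfortably inside the stated tolerances while the full test suite runs
in well under a minute of simulation per module: 500 traces × 60 s for
cross-correlation recovery (the regime where a 15% tolerance is ~5
standard errors), 2000 dwells per residence-time condition, 10⁴ samples
for histogram recovery, 20 curves per FRAP condition, and 100-frame
movies with 20 molecules for the imaging end-to-end checks.
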
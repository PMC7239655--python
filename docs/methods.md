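# Methods

This note documents the models, estimators and numerical choices behind
`exopore`, and what the synthetic-data generator does and does not emulate.

## Signal model and conditioning

Amperometric traces are currents in pA sampled gap-free at 25 kHz after a
2 kHz analog low-pass; capacitance traces are in fF. Internally all
amperometric algorithms work in pA and ms, so charge integrals come out in
fC and derivatives in pA/ms with no conversion factors; file I/O uses
seconds.

**Low-pass filter.** All digital smoothing uses a zero-phase Gaussian FIR
parameterized by its −3 dB cutoff `f_c`: the impulse response has
`sigma_t = sqrt(ln 2) / (2 pi f_c)` (66.2 µs at 2 kHz). The Gaussian was
chosen as the standard digital surrogate for the recording chain's analog
filter: it is non-ringing, zero-phase, and reproduces the known physical
limit of the chain — a unit step passed through the 2 kHz filter shows a
50–90% rise time of ~87 µs as measured by this pipeline (83–85 µs in the
continuous limit; the extra ~2 µs comes from the discrete kernel and linear
interpolation at a 40 µs sample interval). Edge handling is by reflection;
DC gain is exactly 1.

**Derivative.** Central differences scaled to pA/ms (one-sided at the trace
edges). At 25 kHz the attenuation of a 200 Hz component is < 0.05%.

**Baseline.** A centered rolling-median (default window 500 ms) over
non-excluded samples, linearly interpolated across excluded (event)
regions; noise SD is the robust estimate `1.4826 × MAD` of the residual.
Median/MAD was preferred over mean/SD because events bias moment-based
estimators; event regions are additionally masked on the second pass.

## Event detection and selection

Detection runs on the baseline-subtracted current:

1. candidate trigger: ≥ 3 consecutive samples above `4 × noise SD`;
2. boundaries: outward crossings of `1 × noise SD`, sub-sample
   interpolated (all threshold crossings in the pipeline are linearly
   interpolated between samples, since a 40 µs sample is coarse relative to
   the 83 µs scale being measured);
3. window merging: candidate windows separated by < 1 ms are one event.
   Without this, recording noise can momentarily push a pre-spike foot
   below the boundary level and split a single fusion event into a
   "foot event" plus a "spike event";
4. selection: events are kept when the peak exceeds 4 pA and the charge
   (trapezoidal integral over the detected window) lies in 10–5000 fC.
   Events above 4 pA but at or below 7 pA count toward the event frequency
   only; waveform kinetics are reported only above 7 pA;
5. events closer than 3 ms are flagged `overlap_rejected` and excluded
   from kinetics (no deconvolution of overlapping spikes is attempted).

For noiseless traces the thresholds degenerate; a floor of 0.2 pA on the
boundary level keeps windows finite. This floor only matters on synthetic
noise-free input.

**Spike kinetics.** Amplitude is peak minus local baseline; the 50–90%
rise time and the half width (FWHM) use interpolated level crossings. When
fusion-pore flicker runs into the spike the rising phase can cross a level
more than once; the last crossing before the peak is used and the event is
flagged.

## Pre-spike foot and fluctuation statistics

The foot/spike boundary ("takeoff") is the baseline intersection of the
line through the interpolated 35% and 65% rise points of the main spike —
the established back-extrapolation convention in amperometric foot
analysis. The foot onset is the earliest preceding time at which the
current stays continuously above `baseline + 2 × noise SD`. Feet shorter
than 0.25 ms are not reported; feet must exceed 2 ms to enter the
fluctuation analysis.

Fluctuations are counted on the current derivative additionally low-passed
at 1.2 kHz. One fluctuation is one maximal contiguous excursion beyond
+6 pA/ms or below −6 pA/ms (counting excursions rather than samples keeps
the statistic independent of the sampling rate). The fluctuation frequency
is the count divided by the foot duration — in kHz when the duration is in
ms — and the rms noise is the SD of the same filtered derivative over the
same window, a threshold-free companion statistic. The ±6 pA/ms default is
the protocol's fixed value (about 4× the typical baseline derivative
noise); an adaptive mode using `4 × measured derivative noise` is
available.

Two caveats are inherent to the definition and shared with any
implementation: the foot-onset edge and the spike upstroke both produce
derivative transients that can contribute one count at the window borders,
and flicker transitions closer than the 1.2 kHz filter width (~0.3 ms)
can merge into a single excursion. In the telegraph-recovery validation
these effects stay within a few percent for transition rates of
0.1–0.5 /ms.

## Capacitance burst model

Flash-evoked responses are fitted with

    CM(t) = A0 + [t ≥ t_on] · ( A1 (1 − e^−(t−t_on)/τ1)
                              + A2 (1 − e^−(t−t_on)/τ2) + k (t − t_on) )

with `(A1, τ1)` the fast readily releasable pool, `(A2, τ2)` the slow
slowly releasable pool and `k` the sustained rate (fF/s; negative values
allowed, endocytosis). The onset `t_on` is a free parameter rather than a
post-processing step: the back-extrapolated fast exponential intersects the
baseline `A0` exactly at `t_on`, so the secretory delay is `t_on − flash`
and inherits a covariance estimate from the fit.

Fitting is bounded nonlinear least squares (τ1 ∈ [1, 500] ms,
τ2 ∈ [50, 10000] ms, amplitudes ≥ 0). Initialization is multi-start over a
τ grid ({10, 30, 100} × {200, 500, 1500} ms, two onset guesses); for each
grid point the amplitudes are seeded by linear least squares (the model is
linear in A0, A1, A2, k given the time constants), the starts are ranked by
that linear SSE, and the best three are refined; the lowest final SSE wins.
Components are relabeled after the fit so τ1 < τ2. The default fit window
is 200 ms before to 1000 ms after the flash; window length and flash-
artifact exclusion are configuration items. On noise-free synthetic bursts
all parameters are recovered to machine precision; at 5 fF noise (typical
for whole-cell recordings) the median errors over 100 runs are below 1% for
amplitudes, ~2% for time constants and ~0.15 ms for the delay.

## Colocalization

Channel images are threshold-subtracted: the default threshold is the modal
background (median) plus six robust SDs (1.4826 × MAD) of the baseline
noise, matching the granule-intensity criterion; pixels at or below the
threshold become zero, the rest are reduced by it. The Mander's weighted
coefficient of channel A on channel B is

    M_A = Σ_{p : B(p) > 0} A(p) / Σ_p A(p) ∈ [0, 1],

undefined (reported absent, not 0) when A is empty. Granules are
8-connected components of suprathreshold pixels; per-granule means are
taken over the original intensities. Expression-level quantification over
cell-minus-nucleus regions requires manually drawn ROI masks, which are
accepted as mask images, not computed — cell segmentation is out of scope.

## Cohort statistics

The cell is the unit of analysis: for each cell the median of every event
parameter is taken over the kinetics-eligible events ("mean of median"
protocol), fluctuation parameters only over feet that qualify (> 2 ms).
Cells enter group comparisons only with more than 20 events (n ≥ 21,
the strict reading); exclusions are always counted in the report. Groups
are compared on cell medians by one-way ANOVA with Tukey–Kramer pairwise
contrasts (unbalanced-safe, delegated to statsmodels) or the Mann–Whitney
rank-sum test for two groups; stars follow *, **, *** at p < 0.05, 0.01,
0.001. Under a three-group null the simulated family-wise error of the
Tukey–Kramer protocol stays at the nominal 5% level. No correction across
parameters is applied (the protocol applies none).

## Synthetic data generator

The generator provides ground truth for every stage; it is statistical,
not mechanistic (no pore-conductance modeling).

**Amperometric events.** One event is a pre-spike foot followed by a
spike. The foot is a plateau of amplitude `A_f` with a short linear onset
ramp (default 0.2 ms), optionally multiplied by a two-state telegraph
process (stationary, overall transition rate `r` per ms, open fraction
`p`); the realized transition times are part of the ground truth, and the
final state is forced open so the foot hands over to the spike
continuously. The spike is `e^{−u/τ_d} · [A_f + B (1 − e^{−u/τ_r})]`,
rising continuously from the foot level, with `B` solved so the maximum
equals the requested amplitude; its charge has a closed form
(`A_f τ_d + B τ_d² / (τ_r + τ_d)` plus the exact foot integral). The
continuous construction was chosen deliberately: a template with jump
discontinuities cannot satisfy percent-level agreement between its
analytic charge and its sampled trapezoidal integral at 25 kHz. That
agreement is within 0.1% for rise constants ≥ 0.25 ms and degrades to
~0.13% for the sharpest templates (τ_r 0.15 ms on a 0.8 ms decay) — a
discretization property of 40 µs sampling, stated here rather than hidden.

Event onsets are snapped to the sample grid and separated by a minimum gap
(default 50 ms) so ground truth is unambiguous. Recording noise is
Gaussian white noise shaped by the 2 kHz acquisition filter and calibrated
so the post-filter SD equals the requested value (within 5%, typically
0.5%). Event templates themselves are added unfiltered — they are already
band-limited shapes; the filter's rise-time floor is validated separately
on step inputs.

Default parameter ranges (spike amplitude 5–100 pA log-uniform, rise τ
0.15–0.6 ms, decay τ 0.8–8 ms, feet 0.5–10 ms of 1–10 pA with a 0.7
probability, post-filter noise SD ~1 pA) are plausible testing defaults
for chromaffin-cell recordings, not measured distributions. What the
generator does **not** emulate: electrode drift and fouling, overlapping
event clusters at high stimulation rates, multi-phasic "stand-alone foot"
events, or correlated (non-Gaussian) electrode noise — so passing
benchmarks demonstrate correctness of the estimators under the stated
model, not performance on every pathological recording.

**Capacitance bursts** follow the fitted model exactly (double exponential
plus ramp after an onset delay) with additive Gaussian noise — no flash
artifact, sine-wave cross-talk, or conductance transients.

**Image pairs** are Gaussian blobs (σ ≈ 2 px) of equal intensity on a
noisy baseline, placed with a minimum separation; a chosen count fraction
of channel-1 granules shares centers with channel-2 granules whose blobs
are slightly wider, so the realized intensity-weighted colocalized
fraction equals the requested value within 0.02 under the default
threshold. Realistic confounds (uneven illumination, chromatic offsets,
out-of-focus light) are not modeled.

## Problem sizes and determinism

All generators require an explicit seed and are bit-reproducible. The
validation suite uses desk-scale sizes chosen to give stable statistics:
50-event traces of 10 s for the detection benchmark, 100 seeded bursts for
capacitance recovery, 250 feet per rate for flicker recovery, and 1000
simulated cohorts for the family-wise-error calibration.
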
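# Methods

## The decay model

Two-photon fluorescence-lifetime imaging (2pFLIM) of a FRET sensor reads out
the fraction of donor fluorophores bound to an acceptor. The photon-arrival
histogram after each laser pulse is modelled as a two-state decay convolved
with a Gaussian pulse response:

    F(t) = F0 [ P_D H(t, t0, τ_D, τ_G) + P_AD H(t, t0, τ_AD, τ_G) ]

    H(t, t0, τ, τ_G) = ½ exp(τ_G²/(2τ²) − (t−t0)/τ)
                         · erfc((τ_G² − τ(t−t0)) / (√2 τ τ_G))

with τ_D the free-donor lifetime (default 2.6 ns), τ_AD the lifetime of the
acceptor-bound donor (1.1 ns), τ_G the pulse-response width (0.2 ns), t0 the
arrival-time offset and P_D + P_AD = 1 the amplitude fractions. H is an
amplitude kernel: ∫H dt = τ. The binding fraction P_AD/(P_D+P_AD) is the
activity readout; the amplitude-weighted mean lifetime is

    ⟨τ⟩ = (P_D τ_D² + P_AD τ_AD²) / (P_D τ_D + P_AD τ_AD),

and the mean photon arrival time of the model is ⟨t⟩ = t0 + ⟨τ⟩, so pixel
and ROI lifetimes are estimated as ⟨τ⟩ = ⟨t⟩ − t0 without any curve fit.

Numerical care: H is evaluated through the scaled complementary error
function (erfcx) on the branch where erfc underflows against the exploding
exponential, using the identity a − b² = −(t−t0)²/(2τ_G²); the kernel is
then finite and accurate for |t−t0|/τ of hundreds.

### Fitting

`fit_decay` minimizes the Poisson negative log-likelihood of channel counts
(correct for photon counting; weighted least squares available as a
cross-check). The expected count per TCSPC channel is the exact channel
integral of F, computed from closed-form CDF differences of the
exponentially modified Gaussian. Evaluating F at channel centers instead
(available as `channel_model="center"`) leaves the curve within 0.1% but
biases the estimated P_AD by ~0.015 at 10⁶ photons — the likelihood
concentrates its information in the steep rise, where the center
approximation is worst — so integration is the default.

The optimizer (bounded L-BFGS-B, up to 3 perturbed restarts) works on
unit-scaled parameters with a per-photon objective; without this rescaling
the finite-difference gradients stall several standard errors from the
optimum when F0 is large. Lifetimes are bounded to [0.1, 10] ns, the bound
fraction to [0, 1], t0 to [0, window]. P_D + P_AD = 1 is enforced by
construction (single-fraction parameterization), which removes the
degeneracy with F0. Uncertainties come from the inverse of a
central-difference Hessian at the optimum.

Two fit modes mirror practice: a whole-image fit with all parameters free
(used once per session, e.g. to estimate t0), and an ROI mode with
(τ_D, τ_AD, τ_G, t0) fixed at session constants. Because the imaging data
model stores only per-pixel photon counts and arrival-time sums, the
per-frame ROI binding-fraction readout inverts the two-state ⟨τ⟩ formula —
with lifetimes fixed, the first moment identifies P_AD exactly, so this is
the same estimand the fixed-lifetime fit would return from those
statistics.

Defaults assume a 12.5 ns window (one 80 MHz laser period) with 256
channels; both are configurable, and slow-tail wrap-around into the next
pulse period is ignored (τ_D ≪ window). `mean_arrival_time` is computed on
the truncated window; with the default parameters the truncation bias is
~0.19 ns, which is why sampling-based checks of the untruncated mean use a
50 ns window.

## Trace processing and event detection

ROI lifetime traces are processed with the standard chain: normalization to
the mean of the first 100 frames (yielding a lifetime-change trace),
centered moving-average smoothing (30 frames for display-style time
courses, 60 points before kinase event calling; edges use shrinking
windows, trailing mode available), and subtraction of a basal trend line
obtained by ordinary least squares on the pre-stimulus window. Missing
frames (zero ROI photons) are flagged and interpolated only inside the
smoothing filter, never in raw traces; every operation returns a new trace
with an appended provenance entry.

Ca²⁺ signals are ratio traces: dye intensity divided by the structural
channel (common multiplicative bleaching cancels), self-normalized to the
first 100 frames and shifted to a ΔF/F-style trace around 0.

Detection thresholds follow the k·SD rule: after detrending, an event is a
contiguous excursion above k = 3 baseline standard deviations, with
excursions closer than a minimum separation (2 s for Ca²⁺, matching the
width of plateau-associated transients) merged. Kinase (CaMKII) events are
called on the normalized, 60-point-smoothed trace with an additional
absolute floor of 0.01 ns on the peak lifetime change. An optional minimum
event width (used at 0.5 s by the pipeline for Ca²⁺) discards single-frame
noise crossings, which otherwise accrue at ~1.4 × 10⁻³ per frame on long
recordings; genuine transients span many frames, so the width criterion
costs no sensitivity.

Onset estimation deserves care under a centered 60-point filter. The first
threshold crossing is systematically early — up to half the filter width,
amplitude-dependently — and the 50%-of-peak crossing retains a ~0.9 s
advance from decay curvature. The default onset estimator therefore fits a
single least-squares change point to the *unsmoothed* normalized trace in a
window around the detected peak; measured against ground truth it is
unbiased (+0.04 ± 0.14 s). Both simpler definitions remain available.

Event-level summaries follow the figures they emulate: onset histograms in
10 s bins over 0–100 s (one first-event per recording by default;
out-of-range onsets are counted in a reported overflow bucket), cumulative
frequency curves, trapezoidal AUC over 30–40 s post-induction computed on
the normalized trace with no further baseline subtraction (the
photobleaching drift is deliberately left in, as in the averaged time
courses it mirrors — cohort AUC values are therefore interpreted as
stimulated-vs-control contrasts, not absolute areas), event-triggered
averages over ±5 s windows aligned to Ca²⁺ peaks, co-occurrence (kinase
change > 0.01 ns within ±5 s of a Ca²⁺ peak), dendrite/soma compartment
classification, and two-sample Kolmogorov–Smirnov comparisons with
Bonferroni adjustment.

## Potentiation and kinetics

EPSP/EPSC sweep series are normalized to the 0–5 min baseline mean; the
magnitude of potentiation is 100 × (mean over 25–30 min − 1). Sensor
kinetics are summarized by unweighted least-squares fits of
y = A·exp(−t/τ) + B to post-stimulus decay segments, and peak responses by
the trace maximum over an absolute-time or stimulus-indexed window.

## The synthetic-data generator

The generator emulates the acquisition (64×64 pixels at 7.8 Hz; 0.128 s
frames) and the statistics of the biology, with full ground truth and
bit-identical reproducibility under a fixed seed.

- **Photon sampler.** Each photon is t0 + Exp(τ_c) + N(0, τ_G²), the
  component drawn with its *photon* weight P·τ/(ΣPτ) (amplitude fractions
  weight photons by their time integral). Out-of-window arrivals are
  redrawn (rejection sampling preserves the in-window shape of F) or
  optionally wrapped.
- **FLIM stacks.** Per pixel and frame, counts are Poisson(rate) and the
  arrival-time sum is drawn from a normal approximation with the exact
  untruncated mixture moments, so the closed-form ⟨τ⟩ is the exact
  expectation of the lifetime estimator and 64×64 stacks generate in
  milliseconds. Window truncation at the photon level is exercised through
  the sampler, not the stack path. Events raise the bound fraction inside a
  circular ROI footprint; activation *shortens* the lifetime here, whereas
  the trace-level generators below use the activity sign convention
  (activation plotted positive).
- **Delayed-event cohorts.** Each recording is baseline (2.53 ns, the ⟨τ⟩
  of the default resting state) + linear photobleaching drift (−10⁻⁴ ns/s)
  + white noise (SD 0.01 ns), with one delayed event in a responder
  fraction (default 0.79) of recordings. Onsets are Gamma(17, 2.19 s) —
  mode 35 s, SD 9 s, ~43% of mass in the 30–40 s decade, support truncated
  to 0–100 s — so the modal decade is a resolvable feature of the ground
  truth at cohort sizes of ~200. Control (no-stimulation) cohorts use a
  lower responder fraction (0.20) with uniform onsets. Events are
  step-onset transients decaying with τ = 7.3 s.
- **Amplitude convention.** Event amplitudes (Gamma-distributed, mean
  0.02 ns) are specified on the scale of the *processed* readout
  (normalize + 60-point moving average), the scale on which such
  measurements are reported; the injected step height is obtained by
  dividing by the closed-form filter attenuation (τ/W)(1 − e^(−W/τ)) ≈ 0.62.
  Ground truth records both scales. The absolute scale is an
  order-of-magnitude choice consistent with the figures being emulated,
  not a measured value.
- **Pre-protocol baseline.** 60 s by default. The basal trend line must be
  estimated from the smoothed pre-protocol segment and extrapolated over
  the full recording; with a 30 s baseline the slope error reaches the
  0.01 ns floor at the end of a 180 s trace and produces spurious late
  calls, while 60 s (conservative relative to the 2–4 min baselines typical
  of such recordings) keeps it well below.
- **Ca²⁺/kinase co-recording.** Plateau-like events arrive as a Poisson
  process (0.2/min before, 1.5/min after induction), each producing a
  Ca²⁺ transient of 10 baseline-noise SDs (decay 1.5 s) and, with
  probability 0.57, a kinase event onset-aligned to the Ca²⁺ peak (jitter
  SD 0.5 s). The induction protocol itself (5 pulses at 1 Hz, 0.75 s
  delay, 0.3 s depolarization — timing only) adds sub-threshold
  protocol-locked transients at 30% of the delayed-event amplitude. Both
  channels share an exponential bleach that the ratio cancels.
- **EPSP series.** Sweeps every 15 s for 30 min, multiplicative noise of
  CV 10%, a step to (1 + 0.90) × baseline after the 5 min induction for the
  stimulated condition and no step for the adjacent condition.

What the generator does **not** emulate: mechanistic Ca²⁺/kinase dynamics
(only event statistics), motion and segmentation artifacts, detector
afterpulsing or pile-up, correlated (pink) noise, multi-event bursts
(responders carry one event by default), and condition-dependent amplitude
changes (the emulated biology changes event *frequency*, not amplitude).
Passing round-trip tests therefore demonstrates the estimators are correct
for data matching these statistics, not that real recordings meet them.

## Problem sizes and tolerances

Unit and acceptance tests run at sizes chosen to make their tolerances
meaningful while keeping the whole suite around a few seconds: 10⁶ photons
for sampler/model agreement (KS < 0.002) and single-fit recovery
(|ΔP_AD| ≤ 0.02), 50 replicates of 10⁵ photons for mean recovery error
(< 0.03), 200-recording cohorts for responder-fraction and onset-mode
round-trips (binomial 2·SE bands), ~35 co-recorded cells (~180 Ca²⁺ events)
for the co-occurrence round-trip, 50 stimulated/control cohort pairs for
the AUC contrast (≥ 48 wins expected), and 20–25 EPSP experiments for the
potentiation cohort (±2 SEM). Every stochastic routine takes an explicit
seed (package default 20241009); identical config + seed reproduces every
output byte-for-byte.

## Known limitations

- The Gaussian pulse response is an idealization; real instrument response
  functions have tails that bias t0 and τ_G estimates.
- The moment-based ROI binding-fraction readout assumes the session
  lifetimes are exactly known; errors in τ_D/τ_AD propagate linearly.
- The change-point onset estimator assumes a step rise; slowly rising
  events would be placed near the steepest ascent instead.
- AUC values include the photobleaching drift by design; only contrasts
  between conditions are interpretable.
- The false-positive behaviour of the bare k·SD rule grows linearly with
  recording length; the width criterion (or a stricter k) is advisable for
  recordings much longer than the defaults.
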
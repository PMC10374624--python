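# Methods

This note documents the models, estimators, and numerical choices behind
`wormquant`, and what the synthetic-data tests do and do not establish
about real recordings.

## Synthetic data model

All estimators are validated against generated data with known ground
truth, because the quantities of interest (event rates, drop durations,
conductances) are never directly observable in real recordings.

**Spontaneous Ca²⁺ traces.** A recording is 180 s at 1 Hz (the standard
3-min, 1-frame-per-second protocol for head-neuron GCaMP imaging).
Transient onsets follow a Poisson process (default 2 events·min⁻¹) thinned
by rejection-and-redraw so that no two onsets fall within
`min_event_sep_s` of each other. The default separation is 10 s: at the
default kinetics a transient stays above the 0.1 F/F0 detection level for
roughly 7 s, so a smaller separation would let consecutive transients chain
into one supra-threshold run and the truth labels would no longer map to
detectable events, defeating the purpose of thinning. Each transient is a
double-exponential kernel `(1 − e^(−t/rise)) · e^(−t/decay)`
(rise 1 s, decay 3 s — generic GCaMP6-like kinetics), peak-normalized so
the configured amplitude (mean 0.5, SD 0.1 F/F0) is the true excursion.
The truth duration attached to each event is the time the noiseless kernel
spends above 0.1 F/F0, solved by bracketed root finding.

Photobleaching is mono-exponential: `B(t) = F_base (1 − f·(1 − e^(−t/τ)))`
with `f = 0.3` and `τ = 200 s`, i.e. ~30% of the signal is lost over the
recording — a deliberately strong drift so the corrector is genuinely
exercised. Transients and noise act **multiplicatively** on the baseline,
`F(t) = B(t)(1 + Σ events + ε)`, `ε ~ N(0, 0.02²)`; this is the only
composition under which "amplitude in F/F0 units" is well defined at every
point of the bleach curve, and it makes the whole pipeline exactly
equivariant to rescaling the raw fluorescence.

**Coupled sets.** A master event train is drawn once; each event is either
copied to every neuron (probability `shared_fraction`, optional Gaussian
timing jitter) or replaced by an independent uniform onset per neuron.
Amplitudes are always per-neuron. This produces a clean dial from
independent to fully synchronous activity.

**Evoked drops.** A unit-baseline trace steps down by `drop_amp` at
stimulus onset, stays down for `drop_dur_s`, and recovers as a step, a
linear ramp over `recovery_s`, or an exponential with time constant
`recovery_s`. The truth records the analytic time at which 70% of the drop
has perished: the drop end itself (step), drop end + 0.7·`recovery_s`
(linear), or drop end − `recovery_s`·ln 0.3 (exponential).

**Choice assays** are binomial: each of `n_animals` ends at the PA14 spot
with probability `p_pa14`. **Junction sweeps** hold neuron #1 at −30 mV
and step neuron #2, so Vj = −30 mV − Vm₂; the current settles
exponentially (τ = 5 ms) to `g·Vj` where `g` is 1 nS for the declared
antidromic Vj sign and 0.1 nS for the other — a 10-fold rectification —
plus 0.5 pA Gaussian noise at 10 kHz. **Speed–learning points** are a line
plus Gaussian residuals. **Dose–response tables** follow a 4-parameter
logistic with IC50 = 5 mM.

What the generator does **not** emulate: motion artifacts, shot noise and
its intensity dependence, indicator saturation and nonlinearity, baseline
drift that is not monotone, overlapping-transient summation nonlinearity,
seal/leak instabilities in the recordings, and plate-to-plate overdispersion
in the behavioral counts. Passing tests therefore establish correctness of
the estimators under the stated model, not robustness to every failure
mode of real data.

## Bleach correction

Fluorescence is background-subtracted, then divided by an estimated
baseline. The baseline places one anchor per non-overlapping 30-s window —
a percentile of the (optionally event-masked) values, at the window
centre — and interpolates anchors with a cubic spline.

Two numerical details matter:

* **Quantile de-biasing.** The p-th percentile of baseline + Gaussian noise
  sits `z_p·σ` below the baseline. Anchors are de-biased by adding back
  `z_p·σ̂`, with σ̂ estimated per window from the median absolute deviation
  of first differences (insensitive to slow trends). At the default noise
  (σ = 0.02) an uncorrected 8th-percentile anchor would sit ~2.8% low —
  larger than the entire error budget of the corrector. For a noiseless
  window the correction is exactly zero, preserving the flat-trace fixed
  point F/F0 ≡ 1.
* **Edge handling.** Beyond the outermost anchors the baseline continues
  linearly with the secant slope of the two end anchors. Cubic
  extrapolation is unstable; holding the ends constant was tried first and
  contributes up to ~2% error over the first/last half-window at the
  default bleach rate, which alone exhausts the error budget.

The recommended entry point is the two-pass pipeline: pass 1 uses the
8th percentile (robust to transients occupying part of a window, de-biased
as above) and detects provisional events; pass 2 masks every detected
event (padded 2 s before onset and 6 s after offset — the decaying tail
stays above the resting level well after it falls below the detection
gate) plus every individual supra-threshold frame (covers runs too short
to be events, e.g. truncated at the recording edge), then re-anchors at
the **median** of the surviving frames. The median of a monotone trend is
unbiased at the window centre, unlike a low percentile, which is biased by
its position within the trend (~1.9% across a 30-s window at the default
bleach). A window with fewer than `max(3, window/6)` unmasked frames emits
no anchor; with fewer than 4 anchors in total the interpolation degrades
to linear, with a logged warning. On the default conditions (100 traces)
this pipeline achieves ~1% RMS relative baseline error and a resting-level
median within 0.002 of 1.

## Event detection and synchrony

An event is a maximal run of frames with F/F0 ≥ 1.1 lasting ≥ 3 s
(both gates configurable; amplitude = run maximum − 1; peak tie-breaks to
the earliest frame; half-open intervals so durations are exact frame
multiples). There is no hysteresis and no merging across sub-threshold
gaps — the simplest reading of a single-threshold, single-duration gate.
Raising the minimum duration is monotone (never adds events) for any
signal; raising the threshold is monotone for unimodal transients but can
in principle split a multi-peaked supra-threshold run, so the monotonicity
test is run on transient-like traces.

Synchrony between two corrected traces is the Pearson correlation, at zero
lag (the scalar used for comparisons) and across integer-sample lags up to
±30 s (the correlogram, for plotting). Each lag is normalized over its own
overlap, so every value is a true correlation coefficient in [−1, 1] and
r_ab(ℓ) = r_ba(−ℓ) exactly. The correlation runs on the continuous
F/F0 traces, not on binarized event trains; with the default transient
shapes the fully coupled, jitter-free condition yields mean r₀ ≈ 0.93.

## Evoked-drop metrics

ΔF/F0 = (F − F0)/F0 with F0 the mean fluorescence of the 10 s preceding
stimulus onset (distinct from the imaging *background*, which is
subtracted earlier — the two roles are deliberately kept as separate
quantities). Response amplitude is the signed mean of the first 20 s of
the stimulus. The drop onset is the first frame at/after stimulus onset
more than 3 pre-stimulus SDs below zero sustained for 2 consecutive
frames (both knobs configurable and recorded in the output); with a
noiseless pre-window the gate degenerates to "below zero", which is
correct for synthetic data. The trough is the post-onset minimum; the drop
ends at the first crossing of 30% of the trough depth after the trough,
located by linear interpolation between frames (so the worked example —
−0.5 plateau for 50 s, 10-s linear recovery — yields a duration of exactly
57 s). If the trace never recovers to that level the duration runs to the
end of the recording; if no onset qualifies the metrics carry a no-drop
flag. The 70% criterion is measured relative to the trough (the natural
reading of "the drop has perished"); a mean-level variant was considered
and rejected as ill-defined for non-square drops.

Training effects are `((trained/naïve) − 1) × 100%` on the amplitude
magnitude and on the duration. Group-level changes use group means of the
per-animal metrics (one percentage per panel); the same function accepts
single animals for paired designs. Magnitudes (not signed amplitudes) are
compared so that a shrinking Ca²⁺ drop reads as a negative change.

## Behavioral statistics

Choice index CI = (N_PA14 − N_OP50)/(N_PA14 + N_OP50); learning index
LI = CI_naïve − CI_trained; chemotaxis index analogously for odorant vs
diluent counts. These are the standard count contrasts of the two-spot
assay lineage: +CI is an innate PA14 preference and +LI a learned
aversion. All three are exact rational arithmetic.

Speed dependence is summarized by simple OLS (closed-form normal
equations). Two point sets are compared with the extra-sum-of-squares
F-test of one shared line for the pooled data against separate lines:
F = ((RSS_shared − RSS_sep)/2)/(RSS_sep/(n_a + n_b − 4)) with
(2, n_a + n_b − 4) degrees of freedom — slope and intercept jointly, which
is what a whole-fit comparison means; a slope-only (ANCOVA-style, 1 df)
variant is available behind a flag. Under a simulated null the test's
empirical size is ~0.05.

Dose–response curves are fit with a 4-parameter logistic
`bottom + (top − bottom)/(1 + (dose/IC50)^h)` by Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with deterministic initialization: top = mean
zero-dose response, bottom = min response clamped at 0, IC50 = the dose
whose response is nearest the midpoint, h = 1; bounds keep all parameters
non-negative and h ∈ [0.05, 20]. Non-monotone data still fit but are
flagged (`good_fit = False`) when R² < 0.8.

## Electrophysiology

Ij and sustained MRCs are the mean current over the last 100 ms of the
step/stimulus; Ij is referenced to the mean of the 100 ms preceding the
step, MRC metrics to the 50 ms preceding the stimulus (baseline handling
is stated in output provenance since acquisition software conventions
differ). Per-direction junctional conductances are through-origin OLS
slopes (pA/mV = nS) of the Ij–Vj points on each Vj sign; the
rectification ratio is antidromic over orthodromic slope — which Vj sign
is antidromic is declared in the protocol descriptor, never inferred from
the data — and a zero orthodromic slope reports an infinite ratio with an
explicit flag. MRC latency is the 10%-of-peak crossing, activation is
summarized as the 10–90% rise time (both linearly interpolated), and MRC
duration is the total time the baseline-subtracted current stays at or
above 10% of the peak magnitude. Paired-pulse analysis references each
pulse to its own immediately preceding 50 ms and reports peak2/peak1.

## Problem sizes and determinism

The validation suites use 100 traces for baseline/event recovery, 20 pairs
per coupling level plus 200 independent pairs for synchrony, 1000/500
replicates for F-test size/power, 50 replicates for noisy IC50 recovery,
and 10-step Vj protocols — sizes at which every Monte-Carlo band in the
tests is comfortably wider than its standard error while the whole suite
runs in seconds. Every random quantity flows from an explicit seed
(`numpy.random.default_rng`); generators called twice with the same config
are bit-identical, and both end-to-end pipelines are byte-deterministic
(output tables carry package version and resolved parameters, never
timestamps).

## Known limitations

* The baseline anchor rule (windowed percentile + cubic spline) is one
  reasonable operationalization of "corrected baseline by cubic
  interpolation"; other anchor choices would differ in detail.
* Event boundaries use a single threshold; closely spaced transients whose
  inter-event trough stays above the gate are counted as one event.
* The cross-correlation runs on continuous traces by default; an
  event-train mode would weight large-amplitude events differently.
* The drop-onset rule (3σ, 2 frames) is a detection heuristic; at 1 Hz it
  cannot resolve onsets finer than the frame interval.
* The 4PL fit assumes a monotone dose–response; it flags but does not
  model non-monotone (e.g. biphasic) curves.
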
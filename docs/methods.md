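# Methods

## Problem and signal model

A half-facepiece industrial respirator instrumented with an environmental
sensor in its dead space yields three slow time series at 10 Hz — absolute
pressure P (kPa), temperature T (°C) and relative humidity rH (%) — plus a
reference airflow channel AF (arbitrary transducer units) from an external
flowmeter. Breathing modulates all four: inhalation lowers in-mask pressure
and draws in cooler, drier air; exhalation raises pressure and fills the mask
with warm, near-saturated air. Three operational questions are addressed from
these signals:

1. **Breathing rate.** The instantaneous rate between two consecutive
   same-kind breath events at times `t[i-1] < t[i]` is

       IBPM = 60 / (t[i] − t[i-1])   [breaths/min],

   timestamped at the later event.
2. **Fit state.** A loose respirator leaks, so the in-mask P and rH swings
   shrink; per-cycle peak-to-peak (p2p) amplitudes carry the effect.
3. **Filter clogging.** An occluded filter raises breathing effort, so the
   P swing grows — dramatically at full occlusion.

## Processing chain

Filter → differentiate → detect events → rate / p2p features → statistics.

* **Band-pass.** Zero-phase (forward–backward) Butterworth band-pass,
  low-pass prototype order 4, passband 0.16–0.36 Hz (≈ 9.6–21.6 breaths/min).
  Forward–backward application cancels phase, so event timings are
  preserved, and squares the magnitude response. Edges use scipy's default
  odd-reflection padding; a pad of only three filter orders (≈ 1 s at 10 Hz)
  is too short against the 0.16 Hz band edge, so the longer default is kept.
  The 22 BPM protocol rate (0.367 Hz) sits just above the passband edge; it
  is attenuated but, being noise-free in the rate-recovery setting and
  phase-preserved in general, its event times survive intact.
* **Event conventions.** For P and AF the inspiration onset is the falling
  inflection point of a cycle (minimum of the first derivative of the
  filtered signal) and the expiration onset the rising inflection; for T and
  rH the inspiratory/expiratory events are the local maxima/minima of the
  filtered signal itself. The derivative is a central difference
  (`np.gradient`); the band-pass has already removed what a smoothed
  differentiator would.
* **Peak detection.** `scipy.signal.find_peaks` with (a) a minimum
  separation of 1.5 s, capping the detectable rate at 40 BPM — far above
  the 22 BPM protocol maximum — and (b) a prominence threshold of 0.2 times
  the segment's interdecile range, a relative and outlier-robust scale that
  works unchanged across channels and units. Event kinds are forced to
  alternate; of two adjacent like-kind events the more extreme survives.
* **Sub-sample timing.** Each extremum's time is refined by parabolic
  interpolation through the three samples around it. This matters: at 10 Hz
  a 19 BPM breath spans 31.6 samples, so integer-sample event times quantize
  the median IBPM to 18.75 BPM — outside the pipeline's own ±0.1 BPM
  recovery tolerance. Refinement is exact for locally quadratic extrema and
  errs by milliseconds on band-limited breathing signals.
* **Per-cycle features.** A cycle runs between consecutive inspiratory
  events on the channel being measured (no cross-channel borrowing); its
  feature is max − min of the band-pass-filtered signal over the closed
  interval. One cycle at each end of every segment is trimmed
  (`trim_edge_cycles=1`): zero-phase filtering of a finite segment distorts
  amplitudes near its edges, and edge cycles would otherwise contribute a
  small systematic bias.
* **Rate agreement.** Test-channel rates are matched one-to-one to
  reference-channel (AF) rates by nearest-in-time greedy matching; a pair is
  admissible when the offset is under half the shorter of the two local
  breath periods, so estimates are only compared for the same breath.
  Agreement is summarized by the Pearson correlation, the mean difference
  (bias), the SD of differences, and Bland–Altman limits of agreement
  bias ± 1.96 SD. On constant series the correlation is reported as
  undefined rather than 1.0.

## Statistical evaluation

* **Fit protocol.** Per-subject mean p2p per condition (so a 10-subject
  panel gives paired tests with df = 9), then two-sided paired t-tests for
  initial↔loose, loose↔final and initial↔final at α = 0.05, each preceded by
  a Shapiro–Wilk check on the paired differences. Normality failures warn
  and proceed. Equivalence of the two fitted phases is read from a
  non-significant initial↔final test.
* **Clogging protocol.** One-way ANOVA across occlusion levels per channel,
  followed by Tukey's HSD (studentized-range distribution, pooled
  within-group variance). The 100 % level is excluded from the **pressure**
  channel's ANOVA and Tukey comparisons by default: its p2p distribution is
  an order of magnitude above the rest and would dominate the pooled
  variance, masking the separability of the remaining levels. Tukey
  p-values are reported raw; a `clip_legacy` display mode saturates
  them into [0.001, 0.900] as some legacy statistics packages do.
* No multiple-testing correction is applied across channels or comparisons;
  every report carries a note saying so.
* Elementary statistics are delegated to scipy (`shapiro`, `ttest_rel`,
  `f_oneway`, `tukey_hsd`); the test suite checks each against independent
  closed-form sums, the two-group q = √2·|t| identity, statsmodels, and R's
  `shapiro.test`, at 1e-8.

## Synthetic recording generator

No public dataset of in-mask recordings exists, so a generator stands in for
the human-subject data. It is built backwards from the event geometry the
detector assumes:

* **Phase.** Breathing phase φ(t) advances 2π per cycle; cycle durations are
  60/rate perturbed by i.i.d. Gaussian jitter (CV 3 %, truncated at ±3 SD).
* **Waveforms.** AF ∝ −sin φ and P = baseline − amp·sin φ, making φ ≡ 0
  (mod 2π) the falling inflection of both. T and rH follow
  tanh(2·cos φ)/tanh(2) — plateau-shaped alternation, like exhaled-air
  saturation — smoothed by a zero-phase 1 Hz low-pass, peaking at the
  inspiratory event. On noise-free output all four channels date each
  inspiration within one sample, which the suite asserts.
* **Defaults.** fs 10 Hz; half-amplitudes 0.1 kPa (P), 0.5 °C (T), 5 %RH
  (rH), 1 a.u. (AF); baselines 101.3 kPa, 30 °C, 70 %RH; additive white
  noise with SD 5 % of each half-amplitude plus a Gaussian random-walk drift
  of 1 % per sample (removed by the band-pass); the temperature channel
  carries 1.5× relative noise, reflecting its weaker coupling to condition
  effects. In-mask pressure swings of order 0.1 kPa and a warm, humid mask
  microclimate are the physiologically plausible regime for a sealed
  half-facepiece.
* **Condition effects.** Loose straps multiply the P and rH amplitudes by
  `fit_leak = 0.4`; T is deliberately condition-independent so null findings
  are reproduced as well as positive ones. Clogging multiplies the P
  amplitude by {0→1, 20→1, 40→1, 60→1, 80→2.5, 100→12} — the fully occluded
  filter produces a ≥ 10-fold pressure swing — and attenuates AF only at
  100 % (×0.5). rH gets a leak effect but no clogging effect.
* **Panel.** Ten subjects; per-subject amplitude factor log-normal (σ 0.2),
  spontaneous rate uniform on 12–20 BPM.
* **Protocols.** (a) paced rates 10/13/16/19/22 BPM, 5 min each; (b) one
  15-min recording segmented 5 min fitted / 5 min loose / 5 min re-fitted
  (the re-fitted phase length is an interpretation of an ambiguous protocol
  timeline and is the package's default); (c) six 5-min recordings at
  0–100 % occlusion. Each recording starts with one 3× amplitude deep
  synchronization breath; labelled segments begin after it, plus a uniform
  random settle of under one breath. The settle de-phase-locks segment
  boundaries from the synchronization breath — without it every subject's
  first segment starts exactly at a waveform extremum, where odd-reflection
  filter padding systematically inflates edge-cycle amplitudes and biases
  the paired comparisons.

### What the generator does and does not emulate

It reproduces the event geometry, effect directions, noise floor and
protocol structure the analysis assumes — enough to validate the pipeline's
logic, calibration and power. It does not model leak airflow physics, lung
mechanics, sensor quantization, motion artefacts, posture, or breath-shape
variability beyond rate jitter; passing tests demonstrate correctness of the
method under its own assumptions, not field performance on real recordings.

## Verification scale and design choices

* Rate recovery is checked noise-free at all five paced rates to ±0.1 BPM on
  every channel; agreement at default noise over 10 subjects is held to
  |bias| ≤ 0.2 BPM and SD ≤ 1.5 BPM against AF.
* Type-I calibration switches all condition effects off (`fit_leak = 1`,
  flat clogging gains) and demands a 5 % ± 3 rejection rate over 500
  end-to-end replicates for the paired t-test, the ANOVA and the Tukey
  family-wise error. Calibration replicates use 60-second condition
  segments (~13–16 cycles each), the package's chosen desk-scale for a
  500-replicate study. The ANOVA null draws an **independent subject panel
  per level**: one-way ANOVA assumes independent groups, and with a shared
  panel the common per-subject amplitude factor inflates the within-group
  variance relative to the between-group variance, deflating the type-I
  error below nominal. The paired t-test keeps the shared panel — pairing
  is its sampling model.
* Degenerate inputs fail loudly: zero-variance samples raise rather than
  reporting infinite t or r = 1; physical-range violations in recordings
  are errors, not clips; exclusion maps that leave fewer than two clogging
  levels are rejected.
* AF units are treated as arbitrary throughout (the transducer's physical
  calibration is not part of the data model).

## Known limitations

* The greedy nearest-neighbour rate pairing is a package choice; windowed
  or interpolation-based pairing would differ slightly near missed breaths.
* The 22 BPM rate rides the upper band edge; with heavy noise its amplitude
  margin shrinks even though timing is preserved.
* Per-cycle features pool within subject before testing; cycle-level mixed
  models are out of scope.
* The clogging evaluation treats levels as independent groups, as the
  classical one-way ANOVA does, although the laboratory protocol is
  within-subject.
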
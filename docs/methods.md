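# Methods

## The measurement model

The analysis treats an extrasystole as a natural preload perturbation. A
premature beat (coupling interval ≤ 80 % of the reference sinus RR) ejects
poorly; the compensatory pause that follows lengthens diastolic filling, so
the next sinus beat — the post-ectopic beat — contracts under increased
preload. On the steep limb of the Frank–Starling curve this produces a
visible rise in arterial-pressure variables; on the plateau it does not.
The per-extrasystole statistic is

    Δv = v(post-ectopic beat) − median{ v over the 10 preceding sinus beats },

for v ∈ {SBP, PEP, PP, dP/dt_max}, on both the absolute and relative (%)
scale. The ten-beat median is deliberate: it averages out respiratory
modulation of beat-to-beat pressures. Per patient, the ≤ 10 most recent
eligible extrasystoles inside the lookback window (default 1800 s, ending at
the volume expansion) contribute, and the per-variable aggregate is their
median. Fluid responsiveness is a relative stroke-volume increase ≥ 10 %
(secondary threshold 15 %) from the 5-min pre-bolus SV average to the 5-min
post-bolus average; the comparison is non-strict (≥) by default and
configurable.

### Eligibility rules

An extrasystole enters the analysis only when

1. its ten immediately preceding beats are all sinus-labelled (no ectopic,
   post-ectopic or artifact beats in the baseline window),
2. its coupling ratio — coupling interval over the median RR of those ten
   sinus beats — is ≤ 0.80 (boundary inclusive, with a 1e-9 relative float
   tolerance so constructed boundary cases are kept), and
3. a post-ectopic successor beat exists.

The coupling reference is configurable (`median10`, the default, or `last`,
the single preceding sinus RR); the ambiguity between the two readings of
"80 % or less than the preceding sinus beat" is real, and `median10` was
chosen for consistency with the baseline window. Consecutive premature beats
are each labelled ectopic but can never be eligible (their baseline windows
are impure), which also excludes bigeminy/trigeminy patterns. Supra-
ventricular and ventricular extrasystoles are not distinguished — both are
analyzed; QRS morphology is ignored.

### Signal processing choices

- **Resampling.** Monitor exports at 125 Hz are interpolated to 1 kHz with a
  cubic spline evaluated strictly inside the input support (no
  extrapolation); the output grid runs 0 … (n−1)/fs in 1 ms steps and
  reproduces input samples at coincident points. The original description of
  this preprocessing step does not fix the interpolant; the spline choice is
  recorded in the record metadata.
- **R-peak detection.** Zero-phase 5–30 Hz band-pass, derivative, squaring,
  150 ms moving-window integration, fixed-fraction threshold (0.10 of the
  98th energy percentile), 250 ms refractory, then refinement to the local
  ECG maximum. The original detection was semi-automatic with visual review;
  here the manual step is replaced by QC rules: RR intervals ≤ 150 ms, or
  > 1.8× the rolling sinus median without a preceding ectopic, are labelled
  artifact and poison any baseline window containing them.
- **Pulse delineation.** The upstroke foot is found by the
  intersecting-tangent method (tangent at the maximum systolic upslope
  intersected with the horizontal through the preceding pressure minimum),
  searched within 400 ms of the R-peak; SBP is the maximum within 350 ms of
  the foot; dP/dt_max is the maximum of a zero-phase 25 ms
  boxcar-smoothed derivative between foot and peak — smoothing is a boxcar
  on the central difference precisely so the estimate can never overshoot
  the raw-gradient maximum on upsampled (staircase-prone) signals. PEP is
  the R-peak-to-foot interval and therefore *includes* the aortic-to-radial
  transit time (~80–100 ms): baseline values near 212 ms are expected, not
  an error. Search windows cover heart rates of roughly 30–180 bpm and are
  configurable.
- **Per-beat QC.** A beat with > 5 % of samples stuck at its minimum is
  flagged "waveform cut" (export clipping near the diastolic level); flat
  segments are "no upstroke". An invalid beat removes the affected
  variable(s) from any delta it participates in — per-variable exclusion,
  never whole-patient, and no imputation. A variable with zero surviving
  contributions joins the patient's `excluded_vars`.

### Statistics

AUC is the Mann–Whitney statistic (ties ½) with a DeLong
structural-component variance and normal-quantile CI clipped to [0, 1];
orientation is fixed a priori (larger post-ectopic increase ⇒ responder) for
all four variables — no auto-flip. The Youden threshold maximizes
sens + spec − 1 over midpoints of adjacent unique scores plus the two
boundary cut-points; the positivity rule is score **>** threshold; J-ties
break toward higher specificity, then lower threshold. Pooled-variance
Student's t accepts summary statistics directly, so printed group
means/SDs are checkable without raw data. PPV/NPV use sample prevalence.
Percentages are reported as integers (half-up) and p-values to two decimals
in the text report; machine output keeps full precision. No
multiple-testing correction is applied.

## The synthetic-data generator

Two tiers share the patient-summary schema, so the waveform pipeline's
output and the cohort generator's output are interchangeable inputs to the
statistics stage.

**Cohort tier.** Per-patient aggregated absolute deltas are drawn from
responder / non-responder normals whose defaults are the published group
statistics (SBP −0.1 (5.6) vs 5.9 (6.6) mmHg; PEP 4.0 (5.3) vs 7.5 (2.9) ms;
PP 4.0 (6.7) vs 10.6 (7.0) mmHg; dP/dt 0.08 (0.11) vs 0.16 (0.08) mmHg/ms;
20 non-responders, 6 responders). Baselines come from truncated normals with
the published baseline means/SDs, relative deltas are derived as
100·Δ/baseline, and the relative SV change is uniform on (−8, 8) % for
non-responders and (10, 30) % for responders.

**Waveform tier.** All functional forms are package inventions — the
underlying physiology is narrative, not formulaic — and are recorded in each
simulation's config sidecar:

- beat schedule: sinus RR = nominal (HR 90 min⁻¹ by default) + Gaussian
  jitter (SD 20 ms) + sinusoidal respiratory modulation (0.25 Hz, 20 ms);
  ectopics inserted per-beat (default probability 0.02, only after ≥ 12
  sinus beats so isolated extrasystoles dominate), coupling uniform on
  0.5–0.8 of the local RR; ventricular ectopics (default half) get a full
  compensatory pause (coupling + post-RR = 2·RR), supraventricular a partial
  one (post-RR = 1.5·RR − coupling/2);
- preload: x = RR_prev/RR_nominal, plus a residual-volume bonus after the
  ectopic's poor ejection (0.3 × its fractional SV deficit), plus the fluid
  bolus shift (+0.3) in the post-fluid state;
- stroke volume: logistic Frank–Starling SV = SV_max/(1+exp(−(x−p50)/k)).
  The responder preset operates on the steep limb (SV(1) ≈ 72 ml,
  bolus ΔSV ≈ +12 %), the non-responder preset on the plateau
  (ΔSV ≈ +2 %);
- pressures: PP = SV / compliance (1.24 ml/mmHg); diastole decays
  exponentially from the dicrotic-notch pressure (DBP + 0.10·PP) toward an
  asymptote of 50 mmHg with τ = 0.67 s, which pins the nominal beat at
  DBP ≈ 58 / SBP ≈ 116 mmHg and gives the post-ectopic beat a realistic
  2–3 mmHg diastolic dip after the pause; the systolic wave is a sine rise
  (≤ 110 ms) + cosine fall + small dicrotic hump;
- PEP = 212 ms − coef·(x − 1) + noise with coef = −15 ms per preload unit,
  so the post-ectopic PEP *lengthens* by several ms, matching the sign and
  scale of the published group deltas;
- ECG: Gaussian R templates (wider and taller for ventricular ectopics,
  cosmetic only) plus T waves and additive noise; output is rendered at
  125 Hz deliberately so the pipeline's resampling path is always exercised.

`calibrate_starling_slope` tunes k (co-adjusting p50 to keep the operating
SV fixed) until the *ground-truth* mean post-ectopic ΔSBP hits a target
(e.g. +6 mmHg), by bisection on the beat-domain model only; the parameter-
recovery suite then checks that the full waveform pipeline reproduces the
ground-truth per-patient aggregate within ±1 mmHg.

### What the simulator does not capture

Real arterial lines show damping/resonance artifacts, catheter flushes,
moving baselines, atrial fibrillation and pacing; the ECG template has no
morphology variability, and the Starling/windkessel surrogates are not
physiologically validated models. Passing tests therefore demonstrate that
the *pipeline* is correct and self-consistent under controlled conditions —
detection, eligibility, delineation and aggregation recover known ground
truth — not that the method's clinical accuracy generalizes. The published
cohort's headline discrimination is reproduced only in distribution (via the
cohort tier), since the patient-level dataset is not public.

## Problem sizes and numerical conventions

- Replicated-cohort AUC checks use 5000 replicate cohorts (Monte-Carlo SE of
  the mean ≈ 0.001); their expectation has a closed form,
  Φ(Δμ/√(σ₁²+σ₂²)), used as an independent convergence check.
- Parameter recovery runs 20 patients × 300 s records; the end-to-end
  discrimination suite runs 100 + 100 patients × 120 s records with the
  ectopic probability raised to 0.04 — shorter records simply contain fewer
  extrasystoles per patient, which the ≤ 10-most-recent aggregation rule
  already accommodates; 30-min records are the study condition and remain
  the default.
- Median of an even count is the mean of the two central values. Records
  with non-finite samples are rejected at read time (no gap repair).
  Seeds propagate through `numpy.random.SeedSequence` spawning; identical
  seeds give byte-identical outputs at both simulator tiers.

## Known limitations

- Absolute dP/dt thresholds are not comparable across published sources
  (inconsistent printed units); relative dP/dt deltas are unit-free and
  unaffected. dP/dt is retained in all outputs but not used for any
  calibrated check.
- WFDB input is not implemented; the delimited-text reader contract would
  host it.
- With a single responder (or none) in a cohort, ROC rows are reported
  missing rather than computed from a degenerate variance.
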
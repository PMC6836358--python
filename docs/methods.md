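# Methods

## Physiological model

The simulator integrates a linear single-compartment respiratory system
with a fixed-step forward-Euler scheme at the sampling rate (default
100 Hz):

    Paw(t) + Pmus(t) = R·V′(t) + Ers·V(t) + PEEP,

with volume `V` above the relaxation volume at PEEP and
`Ers = E_lung + E_cw`.  The model is linear and stiff-free, so a low-order
fixed-step integrator is accurate at 100 Hz and keeps runs exactly
reproducible; at the defaults the net volume drift per breath is well under
1 mL.

**Effort.**  Each breath is driven by a raised-cosine pressure pulse over
the neural inspiratory time (default 1.0 s, peak at the midpoint), with a
per-breath amplitude draw (default SD 3 cm H₂O).  The pulse shape is a
modeling choice: smooth rise and relaxation with a single peak, which is
all the downstream metrics depend on.  On flowing breaths the effort
applied to the system (and to the pleural space) is the quasi-static
amplitude times `dynamic_attenuation` (default 0.75) — the force–velocity
effect of shortening inspiratory muscle.  This attenuation is precisely
what the conversion factors k1/k2 encode, so its population distribution
(N(0.75, 0.05) between patients) pins the expected derived factors near the
external-validation defaults k1 = −3/4, k2 = 2/3.

**Ventilator.**  PSV is flow-triggered (0.1 L/s of patient-generated flow)
with a linear pressure ramp (default 0.15 s) and flow-cycling at 25% of
peak inspiratory flow; PCV/VCV are machine-triggered at the breath period
(assist-control timing) with a set inspiratory time / set tidal volume.
Default support is 5 cm H₂O above PEEP 5, which reproduces typical
pressure-support airway driving pressures (~5 cm H₂O) while effort drives
ΔP<sub>L,dyn</sub> well above ΔP<sub>aw</sub>.

**Occlusions.**  A scheduled occlusion closes a one-way valve for exactly
one breath: inspiratory flow is impossible, volume holds at its
end-expiratory value, and the airway inscribes
`Paw = PEEP + Ers·V_frozen − effort_qs(t)` — the full, unattenuated effort,
because no shortening occurs.  Expiratory relief below the end-expiratory
volume is not modeled (there is no gas to exhale at end-expiration).
Occluded breaths are chosen uniformly at random among interior breaths.

**Esophageal pressure and artifacts.**
`Pes = (baseline + Ecw·V − effort) × gain + cardiac + noise`.  The
multiplicative `pes_gain_error` emulates balloon miscalibration — the
failure mode the ΔP<sub>occ</sub>/ΔP<sub>es</sub> validity filter exists to
catch; during an occlusion the two deflections are equal up to this gain,
so the measured ratio is ≈ 1/gain.  The cardiac artifact is an additive
sinusoid on Pes only (1 cm H₂O at 80 beats/min) and the noise is white
Gaussian (SD 0.5 cm H₂O on Pes).  Flow and Paw are left clean: ventilator
pneumotachs and pressure lines are far less artifact-prone than esophageal
balloons, and the occlusion deflection is read from Paw.

**Edi** is proportional to the *unattenuated* effort profile on every
breath, so peak Edi is identical between occluded and non-occluded breaths
— the drive-invariance property that justifies using a single random
occlusion as an unbiased probe of effort.  Optional Gaussian Edi noise is
available.

**Cohorts.**  Between-patient parameters are drawn once per patient
(log-normal effort median 20 cm H₂O, log-SD 0.45, chosen so that dynamic
Pmus spans the 10/15 cm H₂O screening thresholds with most patient-days
above 10); day-level jitter is drawn per recording (effort log-SD 0.15,
Pes gain log-SD 0.15 on a patient-level log-SD 0.20, which makes roughly a
third of recordings fail the validity filter, mirroring the exclusion
burden reported with esophageal balloons).  Each patient receives an
independent spawned random substream, so enlarging a cohort never perturbs
earlier patients.

## Signal analysis

Breaths are segmented from flow (upward crossing of 0.02 L/s sustained
100 ms; inspiration ends at the next non-positive flow sample); occlusions
carry no flow and are delimited by the Paw deflection episode (> 1 cm H₂O
below set PEEP, extended to the deflection edges).  Set PEEP comes from
metadata, never from measured Paw.  Spans are 0-based, half-open; partial
edge breaths are discarded.

Extrema are taken on a conditioned copy of Pes (raw channels are never
overwritten):

1. **Cardiac subtraction.**  The artifact frequency is estimated from the
   pooled short-lag autocorrelation of quiet late-expiratory samples (the
   last 30% of each breath) — a local statistic that needs no long-range
   phase coherence — then refined via the phase progression of the fitted
   oscillation across consecutive quiet windows.  Amplitude and phase are
   refit per breath on the two quiet tails bracketing its effort and the
   fitted sinusoid subtracted over the breath span.  A 5 Hz low-pass alone
   cannot remove a ~1.3 Hz artifact, which is why this step exists; if the
   median fitted amplitude is below 0.15 cm H₂O nothing is subtracted.
2. **Low-pass.**  Zero-phase 2nd-order Butterworth at 5 Hz for broadband
   noise.

The ΔPes/ΔPL baseline is the last pre-inspiratory maximum of conditioned
Pes within 300 ms before the breath start, which captures effort beginning
before the ventilator triggers.  Tidal volume integrates flow with a linear
drift correction forcing end-expiratory volume back to baseline.
`Pmus(t) = Ecw·V(t) − (Pes(t) − Pes₀)` peaks over inspiration;
PTP<sub>mus</sub> integrates it over the inspiratory (flow-positive) window
with negative excursions clipped at zero (expiratory-muscle-like activity
is out of scope).  ΔP<sub>occ</sub> is the minimum of raw Paw minus set
PEEP over the occluded breath.

Chest-wall elastance defaults to a demographic prediction: chest-wall
compliance taken as 4% of predicted vital capacity per cm H₂O
(`Ecw = 25/pVC`, sex-specific linear height formulas, anchored at
5 cm H₂O/L for a 175 cm male).  The estimator is a pluggable contract — an
explicit override or any `formula(sex, height)` replaces it — because
empirical chest-wall prediction equations vary between labs.

**Validity filter.**  The per-recording ratio is the mean over occluded
breaths of ΔP<sub>occ</sub>/ΔP<sub>es</sub> *within* the same occlusion
(the quasi-static identity makes the two deflections equal there; whether
the original exclusion rule used within-occlusion or flowing-breath ΔPes is
ambiguous, and the within-occlusion choice is the physically grounded one).
The band 0.7–1.3 is inclusive at both ends, since exclusion is stated
strictly outside it.

## Prediction and screening

Three occlusions are sampled uniformly without replacement (seeded); their
ΔP<sub>occ</sub> mean enters the equations — for affine maps,
predict-then-average and average-then-predict coincide, so only the mean is
offered.  Threshold flags use strict `>`.  Prediction refuses
ΔP<sub>occ</sub> ≥ 0: without inspiratory effort the occlusion deflection
carries no information about ΔP<sub>L,dyn</sub>.  Screening refuses
recordings that failed the validity filter.

## Validation statistics

- **k1/k2 derivation:** per-recording ratios mean Pmus / mean ΔP<sub>occ</sub>
  and mean ΔP<sub>es</sub> / mean ΔP<sub>occ</sub> are modeled with an
  intercept-only patient-level random-intercept model (REML); the fixed
  intercept is the factor, with ±1.96 SE intervals.  Singular or degenerate
  fits (e.g. one recording per patient) fall back to unweighted
  patient-mean averaging with a t-interval, with a warning.
- **Cross-validation:** patients are split 50/50 per repetition (odd counts
  rounded toward derivation; the sets are disjoint by construction and
  asserted so), k1/k2 derived on one half, predictions made on the valid
  recordings of the other from 3 occlusions each; 100 repetitions by
  default.  Repetitions whose validation half holds a single exceedance
  class are reported undefined and counted, not imputed.
- **Repeated-measures Bland-Altman:** differences of log(predicted) −
  log(measured) (log transform for the multiplicative error structure) are
  decomposed into between-patient and within-patient components (REML, with
  a method-of-moments fallback for degenerate data; when every patient has
  a single pair the split is unidentifiable and all variance is reported as
  within).  LA<sub>%,within</sub> back-transforms 1.96 × the within-SD into
  a percent of the estimate.  Bias and its between-patient SD are also
  computed on the natural scale, and the total limit of agreement composes
  them as `1.96·SD_bias,btw + LA%,within · estimate`, which widens
  proportionally with the estimate.  The log-scale between-SD is exposed
  separately (`sd_log_between`).
- **Discrimination:** empirical AUROC (rank statistic, equal to concordant
  pair counting with half-credit ties), percentile bootstrap CI (2000
  resamples, patient-level when ids are supplied, seeded), and
  sensitivity/specificity at the measured-scale threshold plus a cutoff
  table.
- **PTP correlation:** between-subjects R² from patient means,
  within-subjects R² from patient-centered values (patients with ≥ 2
  recordings).

## Problem sizes and defaults

Defaults are the study conditions: 10-min recordings at 100 Hz, 15
occlusions per recording, 16 patients × 3 daily recordings, validity band
0.7–1.3, thresholds 10/15 (Pmus) and 15/20 (ΔP<sub>L,dyn</sub>) cm H₂O,
k1 = −3/4, k2 = 2/3, 3 occlusions per prediction, 100 cross-validation
repetitions.  The test suite runs the full cohort conditions where the
property under test needs them (conversion-factor recovery uses 20 complete
16 × 3 cohorts of 10-min recordings) and shorter 2–5 min recordings where
the property is recording-local (validity-filter and drive-invariance
sweeps over many seeds).

## What the simulator does and does not show

Passing tests demonstrate that the analysis pipeline recovers the
quantities the generative model defines: amplitudes, attenuation ratios,
calibration errors, drive invariance.  The simulator is an idealization —
single compartment (no pendelluft or regional mechanics), linear constant
elastance/resistance, a pure-sinusoid cardiac artifact, no expiratory
muscle activity, no intrinsic PEEP, no NAVA mode, stationary breath timing.
Real esophageal signals carry peristalsis, balloon-position drift and
non-sinusoidal cardiac artifacts; performance on such data is not
established by these tests.  Within-patient day-to-day effort variation is
modest at the defaults (log-SD 0.15), so the within-subject
ΔP<sub>occ</sub>–PTP<sub>mus</sub> R² computed by the acceptance script
varies more between cohort draws than the between-subject component.

## Numerical choices

Explicit Euler at the sampling rate (linear system; reproducibility over
order); trapezoidal integration for all metric integrals; REML convergence
via L-BFGS with fallbacks as above; seeded `numpy` Generators everywhere,
with spawned substreams per patient/repetition; threshold comparisons
strict; validity band inclusive.  The one-way valve holds volume constant
rather than resolving sub-millilitre expiratory relief.  Conditioned
channels are recomputed per call and never cached on the recording.
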
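# poccscreen

Non-invasive screening for excessive inspiratory effort and dynamic
transpulmonary driving pressure during assisted mechanical ventilation,
from the airway-pressure swing of a whole-breath end-expiratory occlusion.

## The problem

Spontaneously breathing ICU patients can generate injuriously large
inspiratory efforts (respiratory muscle pressure, P<sub>mus</sub>) and
dynamic lung stress (dynamic transpulmonary driving pressure,
ΔP<sub>L,dyn</sub>) that the ventilator's airway pressures do not reveal —
the negative pleural-pressure swing hides from P<sub>aw</sub>.  Direct
measurement requires an esophageal balloon.  A far simpler bedside signal
exists: briefly occlude the airway at end-expiration for one breath and read
the maximal P<sub>aw</sub> deflection below PEEP generated by the patient's
effort, ΔP<sub>occ</sub> (negative by convention).  Under the no-flow
(quasi-static) condition this deflection mirrors the pleural swing; on
flowing breaths the muscle's force–velocity relation attenuates the swing
by a roughly stable factor.  Two conversion factors map the occlusion
measurement to the dynamic quantities:

```
P_mus,predicted     = k1 × ΔP_occ                 (k1 < 0, default −3/4)
ΔP_L,dyn,predicted  = ΔP_aw,dyn − k2 × ΔP_occ     (k2 > 0, default 2/3)
```

Predictions are screened against thresholds for excessive effort
(P<sub>mus</sub> > 10 or > 15 cm H₂O) and stress (ΔP<sub>L,dyn</sub> > 15 or
> 20 cm H₂O).  The package implements, for researchers in respiratory
physiology and ventilator waveform analysis:

- a physiology-based **simulator** (single-compartment equation of motion,
  raised-cosine effort, PSV/PCV/VCV, one-way-valve occlusions, esophageal
  miscalibration, cardiac artifact) that generates multi-patient cohorts
  with per-breath ground truth;
- **waveform I/O and breath segmentation**, including occlusion-maneuver
  detection;
- the per-breath **reference metrics** (ΔP<sub>aw,dyn</sub>, ΔP<sub>es</sub>,
  ΔP<sub>L,dyn</sub>, tidal volume, P<sub>cw</sub>, P<sub>mus</sub>,
  PTP<sub>mus</sub>, ΔP<sub>occ</sub>, peak Edi) with the esophageal
  validity filter (recordings with ΔP<sub>occ</sub>/ΔP<sub>es</sub> outside
  0.7–1.3 are excluded);
- the **prediction equations and threshold screening** from three randomly
  selected occlusions;
- the **validation statistics**: k1/k2 estimation with patient-level random
  intercepts, repeated split-half cross-validation, repeated-measures
  Bland-Altman agreement, ROC discrimination, and between-/within-subject
  R² of the ΔP<sub>occ</sub>–PTP<sub>mus</sub> relationship.

## Worked example

```python
import poccscreen as pk

mech = pk.PatientMechanics(effort_amplitude_mean=24.0)
vent = pk.VentilatorSettings(mode="PSV", support_level=5.0, peep=5.0)
cfg = pk.SimConfig(duration=600.0, n_occlusions=15, seed=1)
rec = pk.simulate_recording(mech, vent, cfg).recording

breaths = pk.detect_occlusions(rec, pk.segment_breaths(rec))
metrics = pk.compute_metrics(rec, breaths)
summary = pk.summarize_recording(rec, breaths, metrics)
print(f"breaths={summary.n_breaths} occlusions={summary.n_occlusions} "
      f"ratio={summary.pocc_pes_ratio:.2f} valid={summary.valid}")
print(f"measured: mean Pmus={summary.mean_pmus:.1f}  "
      f"mean dPL,dyn={summary.mean_delta_pl_dyn:.1f}  "
      f"mean dPocc={summary.mean_delta_pocc:.1f}")
res = pk.screen(summary, rng=0)
print(f"predicted: Pmus={res.pmus_pred:.1f}  dPL,dyn={res.delta_pl_pred:.1f}")
print("flags:", res.flags)
```

prints

```
breaths=160 occlusions=15 ratio=0.99 valid=True
measured: mean Pmus=18.0  mean dPL,dyn=20.9  mean dPocc=-23.3
predicted: Pmus=19.3  dPL,dyn=22.2
flags: {'pmus>10': True, 'pmus>15': True, 'delta_pl>15': True, 'delta_pl>20': True}
```

The 10-minute recording contains 160 breaths, 15 of them occlusion
maneuvers.  The per-occlusion ΔP<sub>occ</sub>/ΔP<sub>es</sub> ratio of 0.99
says the esophageal signal is well calibrated, so the recording passes the
validity filter.  From three randomly chosen occlusions the equations
predict a muscle pressure of 19.3 cm H₂O against 18.0 measured and a
dynamic transpulmonary driving pressure of 22.2 against 20.9 — this patient
exceeds every excessive-effort and excessive-stress threshold, flagging a
risk of self-inflicted lung injury and load-induced diaphragm injury.

The same workflow is available from the shell:

```bash
poccscreen simulate --out cohort/ --seed 1
poccscreen segment  --in cohort/P01_d1.csv --out breaths.csv
poccscreen analyze  --in cohort/P01_d1.csv --out-metrics m.csv --out-summary s.csv
poccscreen predict  --summary s.csv --out predictions.csv
poccscreen run-all  --out run/ --seed 1
```

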
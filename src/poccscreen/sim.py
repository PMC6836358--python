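"""Synthetic ventilator-waveform simulator.

Generates physiologically structured recordings of assisted breathing with
patient effort and randomly interleaved whole-breath end-expiratory
occlusion maneuvers, so that every downstream analysis stage is testable
without clinical data.

Model
-----
A linear single-compartment respiratory system is integrated with a
fixed-step explicit (forward-Euler) scheme at the sampling rate:

    Paw(t) + Pmus(t) = R * V'(t) + Ers * V(t) + PEEP,

with volume ``V`` measured above the relaxation volume at PEEP and
``Ers = El + Ecw``.  Each breath is driven by a quasi-static effort
waveform: a raised-cosine pulse over the neural inspiratory time with a
per-breath amplitude draw.  On flowing (non-occluded) breaths the effort
acting on the system is scaled by ``dynamic_attenuation`` — the
force-velocity effect of shortening inspiratory muscle, which is the very
quantity the k1/k2 conversion factors encode.  On occluded breaths there is
no flow, so the full quasi-static effort inscribes itself on the airway:
``Paw = PEEP + Ers*V_frozen − effort(t)`` with volume held at its
end-expiratory value (one-way valve, no inspiratory flow).

Esophageal pressure is ``(baseline + Ecw*V − effort) * pes_gain_error`` plus
an additive cardiac sinusoid and Gaussian noise; the multiplicative gain
emulates esophageal-balloon miscalibration that the ΔPocc/ΔPes validity
filter must catch.  Edi is proportional to the *unattenuated* effort
profile on every breath, so peak Edi is drive-invariant between occluded
and non-occluded breaths.

Ground truth (per-breath amplitudes, realized tidal volumes, clean-signal
swings, occlusion flags) is returned alongside the waveforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .waveforms import RecordingMeta, WaveformRecording

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class PatientMechanics:
    """Respiratory mechanics and effort characteristics of one patient.

    Units: elastances cm H2O/L, resistance cm H2O*s/L, effort amplitudes
    cm H2O (quasi-static peak Pmus), times s, rate breaths/min, edi_gain
    uV per cm H2O.  ``dynamic_attenuation`` in (0, 1] is the ratio of
    flowing-breath effort amplitude to quasi-static amplitude;
    ``pes_gain_error`` > 0 is the multiplicative Pes miscalibration.
    """

    lung_elastance: float = 20.0
    chest_wall_elastance: float = 5.0
    resistance: float = 10.0
    effort_amplitude_mean: float = 20.0
    effort_amplitude_sd_within: float = 3.0
    neural_insp_time: float = 1.0
    respiratory_rate: float = 16.0
    dynamic_attenuation: float = 0.75
    edi_gain: float = 1.0
    pes_gain_error: float = 1.0
    sex: str = "M"
    height_cm: float = 175.0

    def __post_init__(self) -> None:
        for name in ("lung_elastance", "chest_wall_elastance", "resistance",
                     "neural_insp_time", "respiratory_rate", "edi_gain"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"{name} must be finite and > 0")
        _require(np.isfinite(self.effort_amplitude_mean)
                 and self.effort_amplitude_mean >= 0,
                 "effort_amplitude_mean must be finite and >= 0")
        _require(np.isfinite(self.effort_amplitude_sd_within)
                 and self.effort_amplitude_sd_within >= 0,
                 "effort_amplitude_sd_within must be finite and >= 0")
        _require(0 < self.dynamic_attenuation <= 1,
                 "dynamic_attenuation must lie in (0, 1]")
        _require(np.isfinite(self.pes_gain_error) and self.pes_gain_error > 0,
                 "pes_gain_error must be finite and > 0")

    @property
    def total_elastance(self) -> float:
        return self.lung_elastance + self.chest_wall_elastance


@dataclass
class VentilatorSettings:
    """Ventilator mode and settings.

    PSV is flow-triggered and flow-cycled (at ``cycle_fraction`` of peak
    inspiratory flow); PCV/VCV are machine-triggered at the breath period
    (assist-control timing) with a set inspiratory time / set tidal volume.
    """

    mode: str = "PSV"
    support_level: float = 5.0      # cm H2O above PEEP (PSV/PCV)
    peep: float = 5.0               # cm H2O
    trigger_flow_threshold: float = 0.1  # L/s
    cycle_fraction: float = 0.25
    rise_time: float = 0.15         # s
    set_insp_time: float = 1.0      # s (PCV)
    set_tidal_volume: float = 0.5   # L (VCV)
    set_flow: float = 0.5           # L/s (VCV)

    def __post_init__(self) -> None:
        _require(self.mode in ("PSV", "PCV", "VCV"),
                 f"mode must be PSV, PCV or VCV, got {self.mode!r}")
        _require(np.isfinite(self.peep) and self.peep >= 0, "peep must be >= 0")
        _require(np.isfinite(self.support_level) and self.support_level >= 0,
                 "support_level must be >= 0")
        _require(0 < self.cycle_fraction < 1,
                 "cycle_fraction must lie in (0, 1)")
        _require(self.rise_time >= 0, "rise_time must be >= 0")


@dataclass
class SimConfig:
    """Recording-level simulation settings.

    Defaults emulate a daily 10-min recording with 15 randomly interleaved
    occlusions.  ``noise_sd`` and the cardiac sinusoid apply to Pes only;
    ``edi_noise_sd`` adds Gaussian noise to Edi.
    """

    sampling_rate: float = 100.0
    duration: float = 600.0
    n_occlusions: int = 15
    noise_sd: float = 0.5           # cm H2O, on Pes
    cardiac_artifact_amplitude: float = 1.0  # cm H2O, sinusoid on Pes
    cardiac_rate: float = 80.0      # beats/min
    edi_noise_sd: float = 0.0       # uV
    effort_peak_fraction: float = 0.5   # peak position within neural Ti
    pes_baseline: float = 5.0       # cm H2O end-expiratory Pes
    seed: int | None = None
    max_insp_time: float = 3.0      # s, safety cycle

    def __post_init__(self) -> None:
        _require(np.isfinite(self.sampling_rate) and self.sampling_rate >= 50,
                 "sampling_rate must be >= 50 Hz")
        _require(np.isfinite(self.duration) and self.duration > 0,
                 "duration must be > 0")
        _require(self.n_occlusions >= 0, "n_occlusions must be >= 0")
        _require(self.noise_sd >= 0 and self.edi_noise_sd >= 0,
                 "noise SDs must be >= 0")
        _require(self.cardiac_artifact_amplitude >= 0,
                 "cardiac_artifact_amplitude must be >= 0")
        _require(0 < self.effort_peak_fraction < 1,
                 "effort_peak_fraction must lie in (0, 1)")


@dataclass
class SimulatedRecording:
    """A simulated recording plus its per-breath ground truth."""

    recording: WaveformRecording
    truth: pd.DataFrame
    mechanics: PatientMechanics
    vent: VentilatorSettings
    config: SimConfig


def _effort_pulse(tau: np.ndarray, amp: float, tn: float, peak_frac: float) -> np.ndarray:
    """Raised-cosine effort pulse: 0 -> amp at ``peak_frac*tn`` -> 0 at ``tn``."""
    out = np.zeros_like(tau)
    tp = peak_frac * tn
    rise = (tau >= 0) & (tau < tp)
    fall = (tau >= tp) & (tau <= tn)
    out[rise] = 0.5 * amp * (1.0 - np.cos(np.pi * tau[rise] / tp))
    out[fall] = 0.5 * amp * (1.0 + np.cos(np.pi * (tau[fall] - tp) / (tn - tp)))
    return out


def simulate_recording(mechanics: PatientMechanics, vent: VentilatorSettings,
                       config: SimConfig, *, rng: np.random.Generator | None = None,
                       patient_id: str = "P01", day: int = 1) -> SimulatedRecording:
    """Simulate one multi-channel recording.

    Returns the recording with noise/artifact applied and a ground-truth
    table holding, per breath: the quasi-static amplitude, the attenuated
    (dynamic) amplitude, realized tidal volume, clean-signal ΔPes / ΔPL /
    PTPmus, ΔPocc for occluded breaths, peak Edi and the occlusion flag.
    All "clean" quantities are read off the noise- and artifact-free
    channels (Pes gain error included, since it is part of the measurement
    chain the analyzer sees).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round(config.duration * fs))
    period = 60.0 / mechanics.respiratory_rate
    n_breaths = int(math.floor(config.duration / period))
    _require(n_breaths >= 1, "duration too short for a single breath")
    tn = mechanics.neural_insp_time
    _require(tn < period, "neural_insp_time must be shorter than the breath period")
    _require(config.n_occlusions <= max(0, n_breaths - 2),
             f"n_occlusions={config.n_occlusions} exceeds the number of "
             f"eligible breaths ({max(0, n_breaths - 2)})")

    onset_idx = np.array([int(math.floor(k * period * fs)) for k in range(n_breaths)]
                         + [n], dtype=int)
    amps = mechanics.effort_amplitude_mean + mechanics.effort_amplitude_sd_within \
        * rng.standard_normal(n_breaths)
    if mechanics.effort_amplitude_mean > 0:
        amps = np.clip(amps, 0.5, None)
    else:
        amps = np.zeros(n_breaths)
    occluded = np.zeros(n_breaths, dtype=bool)
    if config.n_occlusions > 0:
        eligible = np.arange(1, n_breaths - 1)
        occluded[rng.choice(eligible, size=config.n_occlusions, replace=False)] = True

    t = np.arange(n) * dt
    # quasi-static effort over the whole recording (pulses never overlap)
    pmus_qs = np.zeros(n)
    for k in range(n_breaths):
        s0, s1 = onset_idx[k], onset_idx[k + 1]
        tau = t[s0:s1] - onset_idx[k] * dt
        pmus_qs[s0:s1] = _effort_pulse(tau, amps[k], tn, config.effort_peak_fraction)

    ers = mechanics.total_elastance
    ecw = mechanics.chest_wall_elastance
    att = mechanics.dynamic_attenuation
    R = mechanics.resistance
    peep = vent.peep

    flow = np.zeros(n)
    paw = np.zeros(n)
    vol = np.zeros(n)
    pmus_eff = np.zeros(n)  # effort actually applied to the system
    V = 0.0
    rise_n = vent.rise_time
    for k in range(n_breaths):
        s0, s1 = onset_idx[k], onset_idx[k + 1]
        if occluded[k]:
            # one-way valve: volume held at end-expiratory level, no flow
            pmus_eff[s0:s1] = pmus_qs[s0:s1]
            paw[s0:s1] = peep + ers * V - pmus_qs[s0:s1]
            vol[s0:s1] = V
            continue
        pmus_eff[s0:s1] = att * pmus_qs[s0:s1]
        state = "PRE" if vent.mode == "PSV" else "INSP"
        i_trig = s0
        peak_flow = 0.0
        for i in range(s0, s1):
            pm = pmus_eff[i]
            if state == "INSP":
                ti = (i - i_trig) * dt
                if vent.mode == "VCV":
                    f = vent.set_flow
                    p = peep + ers * V + R * f - pm
                else:
                    frac = 1.0 if rise_n <= 0 else min(1.0, ti / rise_n)
                    p = peep + vent.support_level * frac
                    f = (p + pm - peep - ers * V) / R
                    peak_flow = max(peak_flow, f)
            else:  # PRE-trigger or expiration: ventilator at PEEP
                p = peep
                f = (pm - ers * V) / R
            # state transitions evaluated on the sample just computed
            if state == "PRE" and f >= vent.trigger_flow_threshold:
                state = "INSP"
                i_trig = i
                peak_flow = f
            elif state == "INSP":
                ti = (i - i_trig) * dt
                done = ti >= config.max_insp_time
                if vent.mode == "PSV":
                    done = done or (ti >= rise_n and f <= vent.cycle_fraction * peak_flow)
                elif vent.mode == "PCV":
                    done = done or ti >= vent.set_insp_time
                else:  # VCV
                    done = done or (V + f * dt) >= vent.set_tidal_volume
                if done:
                    state = "EXP"
            flow[i] = f
            paw[i] = p
            vol[i] = V
            V += f * dt

    pes_clean = (config.pes_baseline + ecw * vol - pmus_eff) * mechanics.pes_gain_error
    pl_clean = paw - pes_clean
    edi_clean = mechanics.edi_gain * pmus_qs

    # ground truth from the clean channels, before noise/artifact
    rows = []
    for k in range(n_breaths):
        s0, s1 = onset_idx[k], onset_idx[k + 1]
        seg_pes = pes_clean[s0:s1]
        seg_pl = pl_clean[s0:s1]
        vt = float(np.max(vol[s0:s1]) - vol[s0])
        # Pmus per its measurement definition, on the clean channels:
        # peak of Ecw*V(t) - (Pes(t) - Pes at onset)
        pmus_meas = float(np.max(ecw * (vol[s0:s1] - vol[s0])
                                 - (seg_pes - seg_pes[0])))
        # PTPmus is defined over inspiration: integrate the effort while
        # inspiratory flow is positive (whole effort on occluded breaths)
        seg_fl = flow[s0:s1]
        pos = np.flatnonzero(seg_fl > 0)
        if occluded[k] or pos.size == 0:
            ptp_sl = slice(s0, s1)
        else:
            after = np.flatnonzero(seg_fl[pos[0]:] <= 0)
            stop = pos[0] + (int(after[0]) if after.size else seg_fl.size - pos[0])
            ptp_sl = slice(s0, s0 + stop)
        rows.append({
            "breath": k,
            "onset_idx": int(s0),
            "occluded": bool(occluded[k]),
            "amp_qs": float(amps[k]),
            "amp_dyn": float(att * amps[k]) if not occluded[k] else float(amps[k]),
            "vt_true": vt,
            "pmus_meas_true": pmus_meas,
            "delta_pes_true": float(np.min(seg_pes) - seg_pes[0]),
            "delta_pl_true": float(np.max(seg_pl) - seg_pl[0]),
            "ptp_true": float(np.trapezoid(np.clip(pmus_eff[ptp_sl], 0.0, None), dx=dt)),
            "pocc_true": float(-amps[k]) if occluded[k] else np.nan,
            "edi_peak_true": float(mechanics.edi_gain * amps[k]),
            "attenuation": float(att),
            "ecw_true": float(ecw),
            "pes_gain_error": float(mechanics.pes_gain_error),
        })
    truth = pd.DataFrame(rows)

    pes = pes_clean.copy()
    if config.cardiac_artifact_amplitude > 0:
        fc = config.cardiac_rate / 60.0
        pes = pes + config.cardiac_artifact_amplitude * np.sin(2 * np.pi * fc * t)
    if config.noise_sd > 0:
        pes = pes + config.noise_sd * rng.standard_normal(n)
    edi = edi_clean
    if config.edi_noise_sd > 0:
        edi = edi + config.edi_noise_sd * rng.standard_normal(n)

    meta = RecordingMeta(patient_id=patient_id, day=day, peep=peep,
                         mode=vent.mode, sex=mechanics.sex,
                         height_cm=mechanics.height_cm)
    rec = WaveformRecording(time=t, flow=flow, paw=paw, pes=pes, edi=edi,
                            sampling_rate=fs, meta=meta)
    return SimulatedRecording(recording=rec, truth=truth, mechanics=mechanics,
                              vent=vent, config=config)


@dataclass
class CohortPopulation:
    """Between-/within-patient distributions over :class:`PatientMechanics`.

    Defaults emulate a mixed medical-surgical ICU cohort on assisted
    ventilation: quasi-static effort amplitudes log-normal between patients
    (median 20 cm H2O, log-SD 0.45, so that dynamic Pmus spans the 10 and
    15 cm H2O screening thresholds), day-to-day log-SD 0.15, breath-to-
    breath SD 3 cm H2O; force-velocity attenuation ~ N(0.75, 0.05); and a
    log-normal Pes calibration gain (between-patient log-SD 0.20, day
    log-SD 0.15) that makes roughly a third of recordings fail the
    0.7–1.3 ΔPocc/ΔPes filter, mirroring the exclusion burden seen with
    esophageal balloons in practice.
    """

    effort_median: float = 20.0
    effort_log_sd_between: float = 0.45
    effort_log_sd_day: float = 0.15
    effort_sd_breath: float = 3.0
    attenuation_mean: float = 0.75
    attenuation_sd: float = 0.05
    lung_elastance_mean: float = 20.0
    lung_elastance_sd: float = 4.0
    resistance_mean: float = 10.0
    resistance_sd: float = 2.0
    rr_mean: float = 16.0
    rr_sd: float = 2.5
    rr_day_sd: float = 1.0
    neural_ti_mean: float = 1.0
    neural_ti_sd: float = 0.12
    pes_gain_log_sd_between: float = 0.20
    pes_gain_log_sd_day: float = 0.15
    edi_gain_mean: float = 1.0
    edi_gain_sd: float = 0.2
    ecw_rel_sd: float = 0.08
    female_fraction: float = 0.44
    height_male: tuple[float, float] = (175.0, 7.0)
    height_female: tuple[float, float] = (162.0, 7.0)
    fixed_pes_gain: dict[int, float] = field(default_factory=dict)
    """Optional per-patient (0-based index) Pes gain overrides."""

    def __post_init__(self) -> None:
        for name in ("effort_log_sd_between", "effort_log_sd_day",
                     "effort_sd_breath", "attenuation_sd", "lung_elastance_sd",
                     "resistance_sd", "rr_sd", "rr_day_sd", "neural_ti_sd",
                     "pes_gain_log_sd_between", "pes_gain_log_sd_day",
                     "edi_gain_sd", "ecw_rel_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0 (degenerate "
                     "distributions with negative sd are not allowed)")


@dataclass
class SimulatedCohort:
    recordings: list[SimulatedRecording]
    truth: pd.DataFrame      # per-breath truth with patient/day keys
    patients: pd.DataFrame   # per-patient drawn parameters


def _predicted_ecw(sex: str, height_cm: float) -> float:
    # local copy of the default predicted-vital-capacity scaling; the
    # metrics module owns the user-facing version
    from .metrics import predicted_chest_wall_elastance
    return predicted_chest_wall_elastance(sex=sex, height_cm=height_cm)


def simulate_cohort(n_patients: int = 16, recordings_per_patient: int = 3,
                    population: CohortPopulation | None = None,
                    vent: VentilatorSettings | None = None,
                    config: SimConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Simulate a multi-patient cohort of daily recordings.

    Between-patient parameters are drawn once per patient from
    ``population``; day-level (within-patient) jitter is drawn per
    recording.  Each patient gets an independent child random stream
    (`numpy` spawning), so adding patients does not perturb earlier ones.
    """
    _require(n_patients >= 2, "n_patients must be >= 2")
    _require(recordings_per_patient >= 1, "recordings_per_patient must be >= 1")
    population = population or CohortPopulation()
    vent = vent or VentilatorSettings()
    config = config or SimConfig()

    master = np.random.default_rng(seed)
    patient_streams = master.spawn(n_patients)
    pop = population
    recs: list[SimulatedRecording] = []
    truth_frames = []
    patient_rows = []
    for p in range(n_patients):
        prng = patient_streams[p]
        pid = f"P{p + 1:02d}"
        sex = "F" if prng.uniform() < pop.female_fraction else "M"
        hmu, hsd = pop.height_female if sex == "F" else pop.height_male
        height = float(prng.normal(hmu, hsd))
        effort_pat = pop.effort_median * math.exp(
            pop.effort_log_sd_between * prng.standard_normal())
        att = float(np.clip(prng.normal(pop.attenuation_mean, pop.attenuation_sd),
                            0.5, 0.95))
        el = float(np.clip(prng.normal(pop.lung_elastance_mean,
                                       pop.lung_elastance_sd), 12.0, 35.0))
        res = float(np.clip(prng.normal(pop.resistance_mean, pop.resistance_sd),
                            6.0, 14.0))
        rr_pat = float(np.clip(prng.normal(pop.rr_mean, pop.rr_sd), 10.0, 24.0))
        ti = float(np.clip(prng.normal(pop.neural_ti_mean, pop.neural_ti_sd),
                           0.6, 1.5))
        ecw_true = _predicted_ecw(sex, height) * math.exp(
            pop.ecw_rel_sd * prng.standard_normal())
        if p in pop.fixed_pes_gain:
            gain_pat = float(pop.fixed_pes_gain[p])
        else:
            gain_pat = math.exp(pop.pes_gain_log_sd_between * prng.standard_normal())
        edi_gain = float(np.clip(prng.normal(pop.edi_gain_mean, pop.edi_gain_sd),
                                 0.5, 2.0))
        patient_rows.append({
            "patient": pid, "sex": sex, "height_cm": height,
            "effort_median": effort_pat, "attenuation": att,
            "lung_elastance": el, "resistance": res, "ecw_true": ecw_true,
            "pes_gain_patient": gain_pat, "edi_gain": edi_gain,
            "respiratory_rate": rr_pat, "neural_insp_time": ti,
        })
        day_streams = prng.spawn(recordings_per_patient)
        for d in range(recordings_per_patient):
            drng = day_streams[d]
            effort_day = effort_pat * math.exp(
                pop.effort_log_sd_day * drng.standard_normal())
            if p in pop.fixed_pes_gain:
                gain_day = gain_pat
            else:
                gain_day = gain_pat * math.exp(
                    pop.pes_gain_log_sd_day * drng.standard_normal())
            rr_day = float(np.clip(rr_pat + pop.rr_day_sd * drng.standard_normal(),
                                   10.0, 24.0))
            mech = PatientMechanics(
                lung_elastance=el, chest_wall_elastance=ecw_true,
                resistance=res, effort_amplitude_mean=effort_day,
                effort_amplitude_sd_within=pop.effort_sd_breath,
                neural_insp_time=ti, respiratory_rate=rr_day,
                dynamic_attenuation=att, edi_gain=edi_gain,
                pes_gain_error=gain_day, sex=sex, height_cm=height,
            )
            simrec = simulate_recording(mech, vent, config, rng=drng,
                                        patient_id=pid, day=d + 1)
            recs.append(simrec)
            tf = simrec.truth.copy()
            tf.insert(0, "patient", pid)
            tf.insert(1, "day", d + 1)
            truth_frames.append(tf)
    truth = pd.concat(truth_frames, ignore_index=True)
    return SimulatedCohort(recordings=recs, truth=truth,
                           patients=pd.DataFrame(patient_rows))


def cohort_truth_summaries(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-recording ground-truth summary: true mean dynamic Pmus, true mean
    ΔPocc, true mean ΔPes/ΔPL/PTP over non-occluded breaths, attenuation."""
    rows = []
    for (pid, day), g in truth.groupby(["patient", "day"], sort=True):
        non = g[~g["occluded"]]
        occ = g[g["occluded"]]
        rows.append({
            "patient": pid, "day": day,
            "true_mean_pmus": float(non["amp_dyn"].mean()),
            "true_mean_pmus_meas": float(non["pmus_meas_true"].mean()),
            "true_mean_delta_pes": float(non["delta_pes_true"].mean()),
            "true_mean_delta_pl": float(non["delta_pl_true"].mean()),
            "true_mean_ptp": float(non["ptp_true"].mean()),
            "true_mean_pocc": float(occ["pocc_true"].mean()) if len(occ) else np.nan,
            "true_mean_vt": float(non["vt_true"].mean()),
            "attenuation": float(g["attenuation"].iloc[0]),
            "ecw_true": float(g["ecw_true"].iloc[0]),
            "pes_gain_error": float(g["pes_gain_error"].iloc[0]),
            "n_occlusions_true": int(len(occ)),
        })
    return pd.DataFrame(rows)
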
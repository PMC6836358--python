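"""Per-breath reference quantities and per-recording summaries.

Implements the breath-level signal analysis: dynamic airway driving
pressure (peak Paw − set PEEP), inspiratory esophageal swing ΔPes, dynamic
transpulmonary driving pressure ΔPL,dyn (computed on PL = Paw − Pes, never
on Paw alone), tidal volume, chest-wall recoil pressure Pcw = Ecw·Vt,
respiratory muscle pressure Pmus(t) = Pcw(t) − (Pes(t) − Pes at effort
onset) with its peak and pressure-time product PTPmus, the occlusion
pressure ΔPocc (maximal Paw deflection below set PEEP during an occluded
breath), and peak Edi.  A per-recording summary averages over the proper
breath classes and applies the esophageal-validity filter: recordings with
ΔPocc/ΔPes outside [0.7, 1.3] (inclusive) are marked invalid.

Signal conditioning
-------------------
Pes carries cardiac oscillation and broadband noise.  Extrema are taken on
a conditioned copy (raw channels are never overwritten): an estimated
cardiac sinusoid is subtracted (frequency found by Lomb-Scargle on quiet
late-expiratory samples, amplitude/phase refit per breath), then a
zero-phase low-pass removes broadband noise.  The effort onset used as the
ΔPes / ΔPL baseline is the last pre-inspiratory maximum of conditioned Pes
within 300 ms before flow onset, which captures effort that begins before
the ventilator triggers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .waveforms import Breath, WaveformRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signal conditioning


def transpulmonary(paw_or_rec, pes: np.ndarray | None = None) -> np.ndarray:
    """Transpulmonary pressure PL(t) = Paw(t) − Pes(t), samplewise.

    Accepts a :class:`WaveformRecording` or two equal-length arrays.
    """
    if pes is None:
        rec: WaveformRecording = paw_or_rec
        paw, pes = rec.paw, rec.pes
    else:
        paw = np.asarray(paw_or_rec, dtype=float)
        pes = np.asarray(pes, dtype=float)
    if paw.shape != pes.shape:
        raise ValueError(f"channel length mismatch: {paw.shape} vs {pes.shape}")
    return paw - pes


def lowpass(x: np.ndarray, fs: float, cutoff: float = 5.0) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass."""
    sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _cardiac_frequency(windows: list[np.ndarray], fs: float,
                       band: tuple[float, float]) -> float | None:
    """Cardiac frequency from the pooled short-lag autocorrelation of quiet
    windows.

    Within-window autocorrelation needs no phase coherence across the
    recording (cardiac rate may drift, and periodically repeated windows
    alias any long-coherence estimate), so the oscillation period shows up
    as the first autocorrelation peak at lags inside the cardiac band.
    Parabolic interpolation gives sub-sample period resolution.
    """
    lag_min = int(np.floor(fs / band[1]))
    lag_max = int(np.ceil(fs / band[0]))
    usable = [w for w in windows if w.size > lag_min + 8]
    if not usable:
        return None
    lag_hi = min(lag_max, max(w.size for w in usable) - 4)
    if lag_hi <= lag_min + 2:
        return None
    lags = np.arange(lag_min, lag_hi + 1)
    num = np.zeros(lags.size)
    den = np.zeros(lags.size)
    for w in usable:
        y = w - w.mean()
        n = y.size
        for j, L in enumerate(lags):
            if n - L < 8:
                break
            num[j] += float(np.dot(y[:-L], y[L:]))
            den[j] += n - L
    ac = np.where(den > 0, num / np.maximum(den, 1), -np.inf)
    top = float(np.max(ac))
    if not np.isfinite(top) or top <= 0:
        return None
    # a pure oscillation correlates equally at multiples of its period:
    # among local maxima comparable to the global one, the shortest lag is
    # the fundamental
    peaks, _ = sps.find_peaks(np.where(np.isfinite(ac), ac, -1e30))
    peaks = peaks[ac[peaks] >= 0.8 * top]
    k = int(peaks[0]) if peaks.size else int(np.argmax(ac))
    if 0 < k < lags.size - 1 and np.isfinite(ac[k - 1]) and np.isfinite(ac[k + 1]):
        a0, a1, a2 = ac[k - 1], ac[k], ac[k + 1]
        denom = a0 - 2 * a1 + a2
        shift = 0.5 * (a0 - a2) / denom if abs(denom) > 1e-30 else 0.0
        lag = lags[k] + float(np.clip(shift, -1, 1))
    else:
        lag = float(lags[k])
    return fs / lag


def _refine_frequency(pes: np.ndarray, fs: float, quiet_idx: list[np.ndarray],
                      fc: float) -> float:
    """Refine the cardiac frequency from the phase progression of the
    fitted oscillation across consecutive quiet windows.

    A frequency error ``df`` makes the per-window fitted phase drift by
    ``2*pi*df`` per second of window spacing; the autocorrelation estimate
    is accurate enough (|df| well below half a cycle per breath period)
    for the unwrapped drift to be unambiguous.
    """
    w = 2 * np.pi * fc
    phases, centers, amps = [], [], []
    for qi in quiet_idx:
        tq = qi / fs
        design = np.column_stack([np.sin(w * tq), np.cos(w * tq),
                                  np.ones_like(tq)])
        (a, b, _), *_ = np.linalg.lstsq(design, pes[qi], rcond=None)
        amp = math.hypot(a, b)
        if amp <= 0:
            continue
        phases.append(math.atan2(b, a))
        centers.append(float(np.mean(tq)))
        amps.append(amp)
    if len(phases) < 4:
        return fc
    phases = np.unwrap(np.asarray(phases))
    centers = np.asarray(centers)
    med_amp = np.median(amps)
    keep = np.asarray(amps) > 0.3 * med_amp
    if keep.sum() < 4:
        return fc
    slope = np.polyfit(centers[keep], phases[keep], 1)[0]
    return fc + slope / (2 * np.pi)


def remove_cardiac(pes: np.ndarray, fs: float, breaths: list[Breath], *,
                   band: tuple[float, float] = (0.7, 3.5),
                   quiet_fraction: float = 0.3,
                   min_amplitude: float = 0.15) -> tuple[np.ndarray, dict]:
    """Estimate and subtract a cardiac oscillation from Pes.

    The artifact frequency is found from the pooled autocorrelation of
    quiet late-expiratory samples (the tail ``quiet_fraction`` of each
    breath, where respiratory effort is minimal).  Amplitude and phase are
    then refit for every breath on the two quiet tails *bracketing* its
    effort (previous breath's tail and its own), and the fitted sinusoid
    is subtracted over the breath span; bracketing keeps phase
    extrapolation short, so slow rate drift is tolerated.  If the median
    fitted amplitude is below ``min_amplitude`` (cm H2O) the signal is
    returned untouched.

    Returns (conditioned pes, info dict).
    """
    info: dict = {"applied": False, "frequency_hz": np.nan, "amplitude": 0.0}
    if not breaths:
        return pes, info
    quiet_idx = []
    for b in breaths:
        span = b.end - b.start
        q0 = b.end - max(2, int(round(quiet_fraction * span)))
        quiet_idx.append(np.arange(q0, b.end))
    if sum(q.size for q in quiet_idx) < 50:
        return pes, info
    fc = _cardiac_frequency([pes[qi] for qi in quiet_idx], fs, band)
    if fc is None or not (band[0] <= fc <= band[1]):
        return pes, info
    fc = _refine_frequency(pes, fs, quiet_idx, fc)
    w = 2 * np.pi * fc
    cleaned = pes.astype(float).copy()
    coefs = []
    for i, b in enumerate(breaths):
        qi = quiet_idx[i] if i == 0 else np.r_[quiet_idx[i - 1], quiet_idx[i]]
        tqb = qi / fs
        design = np.column_stack([np.sin(w * tqb), np.cos(w * tqb),
                                  np.ones_like(tqb)])
        coef, *_ = np.linalg.lstsq(design, pes[qi], rcond=None)
        coefs.append(coef)
    med_amp = float(np.median([math.hypot(c[0], c[1]) for c in coefs]))
    if med_amp < min_amplitude:
        return pes, info
    for b, coef in zip(breaths, coefs):
        tb = np.arange(b.start, b.end) / fs
        cleaned[b.start:b.end] -= coef[0] * np.sin(w * tb) + coef[1] * np.cos(w * tb)
    info.update(applied=True, frequency_hz=float(fc), amplitude=med_amp)
    return cleaned, info


@dataclass
class MetricsOptions:
    """Signal-conditioning knobs for metric extraction.

    ``lowpass_hz=None`` and ``cardiac_removal=False`` give raw-channel
    extrema (useful for analytically constructed test signals).
    """

    lowpass_hz: float | None = 5.0
    cardiac_removal: bool = True
    cardiac_band: tuple[float, float] = (0.7, 3.5)
    quiet_fraction: float = 0.3
    min_cardiac_amplitude: float = 0.15
    baseline_window_s: float = 0.3


def conditioned_channels(rec: WaveformRecording, breaths: list[Breath],
                         options: MetricsOptions | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, dict]:
    """Return (pes_conditioned, pl_conditioned, edi_conditioned, info).

    PL is computed from raw Paw minus conditioned Pes; Paw itself is left
    untouched (ventilator pressure carries no cardiac artifact).
    """
    options = options or MetricsOptions()
    pes = rec.pes
    info: dict = {}
    if options.cardiac_removal:
        pes, cinfo = remove_cardiac(pes, rec.sampling_rate, breaths,
                                    band=options.cardiac_band,
                                    quiet_fraction=options.quiet_fraction,
                                    min_amplitude=options.min_cardiac_amplitude)
        info["cardiac"] = cinfo
    if options.lowpass_hz is not None:
        pes = lowpass(pes, rec.sampling_rate, options.lowpass_hz)
    pl = transpulmonary(rec.paw, pes)
    edi = None
    if rec.edi is not None:
        edi = rec.edi
        if options.lowpass_hz is not None:
            edi = lowpass(edi, rec.sampling_rate, options.lowpass_hz)
    return pes, pl, edi, info


def effort_onset_index(pes_cond: np.ndarray, breath: Breath, fs: float,
                       window_s: float = 0.3) -> int:
    """Index of the effort-onset baseline: last maximum of conditioned Pes
    within ``window_s`` before the breath start (inclusive)."""
    w = int(round(window_s * fs))
    lo = max(0, breath.start - w)
    seg = pes_cond[lo:breath.start + 1]
    # last occurrence of the maximum = last pre-inspiratory local max for
    # a signal that decays into inspiration
    rev = seg[::-1]
    return breath.start - int(np.argmax(rev))


# ---------------------------------------------------------------------------
# per-breath metrics


@dataclass
class BreathMetrics:
    """Physiologic quantities of one breath (units: cm H2O, L, cm H2O*s, uV).

    ``delta_pes`` is negative for inspiratory effort; ``delta_pocc`` is
    defined (≤ 0) only on occluded breaths.
    """

    delta_paw_dyn: float
    delta_pes: float
    tidal_volume: float
    pcw_ei: float
    pmus_peak: float
    ptp_mus: float
    delta_pl_dyn: float
    delta_pocc: float
    edi_peak: float
    occluded: bool
    start: int
    insp_end: int
    end: int


def breath_metrics(rec: WaveformRecording, breath: Breath, ecw: float,
                   set_peep: float | None = None, *,
                   pes_cond: np.ndarray | None = None,
                   pl_cond: np.ndarray | None = None,
                   edi_cond: np.ndarray | None = None,
                   options: MetricsOptions | None = None) -> BreathMetrics:
    """Compute :class:`BreathMetrics` for one breath.

    ``ecw`` is the chest-wall elastance (cm H2O/L) used for the Pcw term.
    Conditioned channels may be passed in to avoid re-filtering per breath;
    otherwise they are computed for this breath alone.
    """
    if ecw is None or not np.isfinite(ecw) or ecw <= 0:
        raise ValueError("ecw must be a positive chest-wall elastance")
    if breath.insp_end <= breath.start:
        raise ValueError("empty inspiration span")
    if set_peep is None:
        set_peep = rec.meta.peep
    if set_peep is None:
        raise ValueError("set PEEP required (metadata or argument)")
    options = options or MetricsOptions()
    if pes_cond is None or pl_cond is None:
        pes_cond, pl_cond, edi_cond, _ = conditioned_channels(rec, [breath], options)
    fs = rec.sampling_rate
    dt = 1.0 / fs
    s0, s1, s2 = breath.start, breath.insp_end, breath.end
    b_idx = effort_onset_index(pes_cond, breath, fs, options.baseline_window_s)
    pes0 = pes_cond[b_idx]
    pl0 = pl_cond[b_idx]
    edi_peak = float(np.max(edi_cond[s0:s2])) if edi_cond is not None else np.nan

    if breath.occluded:
        span = slice(s0, s2)
        delta_pocc = float(np.min(rec.paw[span]) - set_peep)
        delta_pes = float(np.min(pes_cond[span]) - pes0)
        # no flow: volume-derived fields are zero; Pmus reduces to -dPes
        return BreathMetrics(
            delta_paw_dyn=float(np.max(rec.paw[span]) - set_peep),
            delta_pes=delta_pes, tidal_volume=0.0, pcw_ei=0.0,
            pmus_peak=-delta_pes,
            ptp_mus=float(np.trapezoid(
                np.clip(-(pes_cond[span] - pes0), 0.0, None), dx=dt)),
            delta_pl_dyn=float(np.max(pl_cond[span]) - pl0),
            delta_pocc=delta_pocc, edi_peak=edi_peak, occluded=True,
            start=s0, insp_end=s1, end=s2)

    fl = rec.flow[s0:s2]
    v_raw = np.concatenate([[0.0], np.cumsum((fl[1:] + fl[:-1]) * 0.5 * dt)])
    # drift correction: expiratory volume must return to baseline
    drift = v_raw[-1] / (len(v_raw) - 1)
    vol = v_raw - drift * np.arange(len(v_raw))
    n_insp = s1 - s0
    vt = float(vol[n_insp])
    pes_rel = pes_cond[s0:s1] - pes0
    delta_pes = float(np.min(pes_rel))
    pmus_t = ecw * vol[:n_insp] - pes_rel
    return BreathMetrics(
        delta_paw_dyn=float(np.max(rec.paw[s0:s1]) - set_peep),
        delta_pes=delta_pes,
        tidal_volume=vt,
        pcw_ei=float(ecw * vt),
        pmus_peak=float(np.max(pmus_t)),
        ptp_mus=float(np.trapezoid(np.clip(pmus_t, 0.0, None), dx=dt)),
        delta_pl_dyn=float(np.max(pl_cond[s0:s1]) - pl0),
        delta_pocc=np.nan,
        edi_peak=edi_peak, occluded=False, start=s0, insp_end=s1, end=s2)


def compute_metrics(rec: WaveformRecording, breaths: list[Breath],
                    ecw: float | None = None, set_peep: float | None = None,
                    options: MetricsOptions | None = None) -> pd.DataFrame:
    """Per-breath metrics table for a whole recording.

    ``ecw`` defaults to the demographic prediction from recording metadata.
    Channels are conditioned once for the whole recording.
    """
    options = options or MetricsOptions()
    if ecw is None:
        ecw = predicted_chest_wall_elastance(sex=rec.meta.sex,
                                             height_cm=rec.meta.height_cm)
    pes_cond, pl_cond, edi_cond, _ = conditioned_channels(rec, breaths, options)
    rows = []
    for i, b in enumerate(breaths):
        m = breath_metrics(rec, b, ecw, set_peep, pes_cond=pes_cond,
                           pl_cond=pl_cond, edi_cond=edi_cond, options=options)
        rows.append({"breath": i, **m.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chest-wall elastance prediction


def predicted_chest_wall_elastance(sex: str | None = None,
                                   height_cm: float | None = None,
                                   override: float | None = None,
                                   formula=None) -> float:
    """Chest-wall elastance (cm H2O/L) predicted from demographics.

    Default estimator: chest-wall compliance is taken as 4% of the
    predicted vital capacity per cm H2O, i.e. ``Ecw = 25 / pVC`` with a
    sex-specific linear height formula for predicted vital capacity.  The
    calibration anchor is a 175 cm male → pVC 5.0 L → Ecw 5.0 cm H2O/L.
    The estimator is pluggable (``formula(sex, height_cm) -> Ecw``) and an
    explicit ``override`` is returned unchanged.
    """
    if override is not None:
        if not (np.isfinite(override) and override > 0):
            raise ValueError("ecw override must be a positive number")
        logger.info("using explicit chest-wall elastance override %.3g", override)
        return float(override)
    if formula is not None:
        return float(formula(sex, height_cm))
    if sex is None or height_cm is None:
        raise ValueError(
            "sex and height are required to predict chest-wall elastance; "
            "pass an explicit ecw override instead"
        )
    s = str(sex).upper()[:1]
    if s == "M":
        pvc = 0.0600 * float(height_cm) - 5.50
    elif s == "F":
        pvc = 0.0466 * float(height_cm) - 4.40
    else:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if pvc <= 0.5:
        raise ValueError(f"implausible predicted vital capacity {pvc:.2f} L")
    return 25.0 / pvc


# ---------------------------------------------------------------------------
# per-recording summary and validity filter


VALIDITY_BAND = (0.7, 1.3)


@dataclass
class RecordingSummary:
    """Per-recording means over the proper breath classes plus occlusion
    statistics and the esophageal-validity verdict.

    ``pocc_pes_ratio`` is the mean over occluded breaths of ΔPocc/ΔPes
    taken *within* the same occluded breath (quasi-static identity: with a
    well-calibrated balloon the two deflections match, ratio ≈ 1).
    ``valid`` is True iff the ratio lies inside the band, inclusive.
    """

    patient_id: str
    day: int
    mean_pmus: float
    mean_delta_pes: float
    mean_delta_paw: float
    mean_delta_pl_dyn: float
    mean_delta_pocc: float
    mean_ptp_mus: float
    n_breaths: int
    n_occlusions: int
    pocc_pes_ratio: float
    valid: bool
    pocc_values: list[float] = field(default_factory=list)
    band: tuple[float, float] = VALIDITY_BAND


def summarize_recording(rec: WaveformRecording, breaths: list[Breath],
                        metrics: pd.DataFrame,
                        band: tuple[float, float] = VALIDITY_BAND
                        ) -> RecordingSummary:
    """Summarize a per-breath metrics table into a :class:`RecordingSummary`.

    Means of ΔPaw, ΔPes, ΔPL, Pmus and PTPmus are over non-occluded breaths
    only; mean ΔPocc is over occluded breaths.  With zero occlusions the
    ratio is undefined and the recording is marked invalid with a warning.
    """
    non = metrics[~metrics["occluded"]]
    occ = metrics[metrics["occluded"]]
    if len(non) < 1:
        raise ValueError("summary requires at least one non-occluded breath")
    ratios = []
    for _, row in occ.iterrows():
        if row["delta_pes"] < -0.1:  # guard against a vanishing denominator
            ratios.append(row["delta_pocc"] / row["delta_pes"])
    if len(occ) == 0:
        logger.warning("recording %s day %s has no occlusions: validity "
                       "ratio undefined, marked invalid",
                       rec.meta.patient_id, rec.meta.day)
        ratio = np.nan
        valid = False
    else:
        ratio = float(np.mean(ratios)) if ratios else np.nan
        valid = bool(np.isfinite(ratio) and band[0] <= ratio <= band[1])
    return RecordingSummary(
        patient_id=rec.meta.patient_id,
        day=rec.meta.day,
        mean_pmus=float(non["pmus_peak"].mean()),
        mean_delta_pes=float(non["delta_pes"].mean()),
        mean_delta_paw=float(non["delta_paw_dyn"].mean()),
        mean_delta_pl_dyn=float(non["delta_pl_dyn"].mean()),
        mean_delta_pocc=float(occ["delta_pocc"].mean()) if len(occ) else np.nan,
        mean_ptp_mus=float(non["ptp_mus"].mean()),
        n_breaths=int(len(metrics)),
        n_occlusions=int(len(occ)),
        pocc_pes_ratio=ratio,
        valid=valid,
        pocc_values=[float(x) for x in occ["delta_pocc"]],
        band=tuple(band),
    )


def summaries_frame(summaries: list[RecordingSummary]) -> pd.DataFrame:
    """Stack recording summaries into a DataFrame (pocc_values kept as lists)."""
    rows = []
    for s in summaries:
        d = {k: v for k, v in s.__dict__.items() if k != "band"}
        d["patient"] = d.pop("patient_id")
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Edi drive-invariance check


@dataclass
class EdiDriveReport:
    """Peak-Edi agreement between occluded and adjacent non-occluded breaths."""

    mean_difference: float  # uV
    loa: float              # ± uV (1.96 SD of the differences)
    n_occlusions: int
    differences: np.ndarray

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"peak Edi occluded-vs-adjacent: mean difference "
                f"{self.mean_difference:+.2f} uV, LoA ±{self.loa:.2f} uV "
                f"({self.n_occlusions} occlusions)")


def edi_drive_check(metrics: pd.DataFrame, min_occlusions: int = 3) -> EdiDriveReport | None:
    """Mean difference and limits of agreement of peak Edi, occluded vs
    adjacent non-occluded breaths.

    Respiratory drive should be untouched by a single randomly applied
    occlusion, so the mean difference should be ~0.  Returns None (with a
    log notice) when Edi is absent; requires at least ``min_occlusions``.
    """
    if metrics["edi_peak"].isna().all():
        logger.info("Edi channel absent: drive-invariance check skipped")
        return None
    occ_idx = metrics.index[metrics["occluded"]].to_numpy()
    non_idx = metrics.index[~metrics["occluded"]].to_numpy()
    if occ_idx.size < min_occlusions:
        raise ValueError(
            f"need at least {min_occlusions} occlusions, got {occ_idx.size}")
    diffs = []
    for i in occ_idx:
        before = non_idx[non_idx < i]
        after = non_idx[non_idx > i]
        neigh = []
        if before.size:
            neigh.append(metrics.loc[before[-1], "edi_peak"])
        if after.size:
            neigh.append(metrics.loc[after[0], "edi_peak"])
        if neigh:
            diffs.append(metrics.loc[i, "edi_peak"] - float(np.mean(neigh)))
    diffs = np.asarray(diffs, dtype=float)
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return EdiDriveReport(mean_difference=float(np.mean(diffs)),
                          loa=1.96 * sd, n_occlusions=int(occ_idx.size),
                          differences=diffs)
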
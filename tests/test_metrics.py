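"""Reference-metric correctness: closed-form constructions, oracle
agreement, validity filter, chest-wall prediction and Edi drive check."""

import numpy as np
import pandas as pd
import pytest

import poccscreen as pk
from poccscreen.metrics import (MetricsOptions, effort_onset_index,
                                predicted_chest_wall_elastance, transpulmonary)
from poccscreen.waveforms import Breath

RAW = MetricsOptions(lowpass_hz=None, cardiac_removal=False)
FS = 100.0


def _recording(flow, paw, pes, peep=5.0, edi=None):
    n = len(flow)
    return pk.WaveformRecording(
        time=np.arange(n) / FS, flow=np.asarray(flow, float),
        paw=np.asarray(paw, float), pes=np.asarray(pes, float),
        edi=None if edi is None else np.asarray(edi, float),
        sampling_rate=FS, meta=pk.RecordingMeta(peep=peep))


def _constructed_breath():
    """4-s recording: 1-s inspiration at constant 0.4 L/s (Vt = 0.4 L),
    Pes ramps linearly to -8 at end-inspiration, Paw ramps to PEEP+10."""
    n = 400
    start, insp_end, end = 100, 200, 350
    flow = np.zeros(n)
    flow[start:insp_end] = 0.4
    flow[insp_end:300] = -0.4  # symmetric expiration, volume returns to 0
    pes = np.zeros(n)
    ramp = np.linspace(0.0, 1.0, insp_end - start)  # hits 1 at insp_end-1
    pes[start:insp_end] = -8.0 * ramp
    pes[insp_end:insp_end + 50] = -8.0 * np.linspace(1.0, 0.0, 50)
    paw = np.full(n, 5.0)
    paw[start:insp_end] = 5.0 + 10.0 * ramp
    rec = _recording(flow, paw, pes)
    return rec, Breath(start=start, insp_end=insp_end, end=end)


class TestTranspulmonary:
    def test_samplewise_subtraction_and_offsets(self):
        paw = np.array([10.0, 0.0, 7.0])
        pes = np.array([-8.0, 0.0, 7.0])
        pl = transpulmonary(paw, pes)
        assert pl.tolist() == [18.0, 0.0, 0.0]
        assert np.array_equal(transpulmonary(paw + 3.0, pes + 3.0), pl)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            transpulmonary(np.zeros(3), np.zeros(4))


class TestBreathMetrics:
    def test_closed_form_construction(self):
        """Vt=0.4 L, Ecw=5 -> Pcw=2; Pes dip -8 synchronous with
        end-inspiration -> Pmus peak 10; ramp Pmus integrates to 5."""
        rec, breath = _constructed_breath()
        m = pk.breath_metrics(rec, breath, ecw=5.0, options=RAW)
        # step-function flow has half-sample trapezoid edges at 100 Hz
        assert m.tidal_volume == pytest.approx(0.4, abs=5e-3)
        assert m.pcw_ei == pytest.approx(2.0, abs=0.03)
        assert m.delta_pes == pytest.approx(-8.0, abs=1e-9)
        assert m.pmus_peak == pytest.approx(10.0, abs=0.05)
        # Pmus(t) = 2t + 8t rises linearly to 10 over 1 s -> PTP = 5
        assert m.ptp_mus == pytest.approx(5.0, abs=0.1)
        assert m.delta_paw_dyn == pytest.approx(10.0, abs=1e-9)

    def test_synchronous_extrema_identity(self):
        """When Paw peak, Pes minimum and PL maximum coincide,
        dPL,dyn = dPaw,dyn - dPes exactly."""
        rec, breath = _constructed_breath()
        m = pk.breath_metrics(rec, breath, ecw=5.0, options=RAW)
        assert m.delta_pl_dyn == pytest.approx(
            m.delta_paw_dyn - m.delta_pes, abs=1e-9)

    def test_effort_onset_baseline_precedes_trigger(self):
        """Effort beginning before the flow onset is captured through the
        pre-inspiratory Pes maximum."""
        n = 400
        flow = np.zeros(n)
        flow[120:200] = 0.3
        pes = np.zeros(n)
        pes[100:120] = -np.linspace(0, 2.0, 20)   # pre-trigger effort
        pes[120:200] = -2.0 - 6.0 * np.linspace(0, 1, 80)
        paw = np.full(n, 5.0)
        rec = _recording(flow, paw, pes)
        b = Breath(start=120, insp_end=200, end=350)
        idx = effort_onset_index(rec.pes, b, FS)
        assert idx <= 100 + 1
        m = pk.breath_metrics(rec, b, ecw=5.0, options=RAW)
        assert m.delta_pes == pytest.approx(-8.0, abs=1e-9)

    def test_rejects_bad_inputs(self):
        rec, breath = _constructed_breath()
        with pytest.raises(ValueError, match="ecw"):
            pk.breath_metrics(rec, breath, ecw=0.0, options=RAW)
        with pytest.raises(ValueError):
            Breath(start=10, insp_end=10, end=20)

    def test_pl_exceeds_paw_whenever_pes_swings_negative(self, noisy_analysis):
        """Dynamic transpulmonary driving pressure is higher than airway
        driving pressure on every effort breath."""
        _, _, metrics, _ = noisy_analysis
        non = metrics[~metrics.occluded]
        assert (non.delta_pes < 0).all()
        assert (non.delta_pl_dyn > non.delta_paw_dyn).all()

    def test_passive_breaths_have_near_zero_pmus(self):
        mech = pk.PatientMechanics(effort_amplitude_mean=0.0,
                                   effort_amplitude_sd_within=0.0)
        vent = pk.VentilatorSettings(mode="PCV", support_level=10.0)
        cfg = pk.SimConfig(duration=60.0, n_occlusions=0, noise_sd=0.0,
                           cardiac_artifact_amplitude=0.0, seed=0)
        sr = pk.simulate_recording(mech, vent, cfg)
        rec = sr.recording
        breaths = pk.segment_breaths(rec)
        m = pk.compute_metrics(rec, breaths, ecw=5.0, options=RAW)
        assert np.abs(m.pmus_peak).max() < 0.15

    def test_metrics_track_simulator_ground_truth(self, clean_sim,
                                                  clean_analysis):
        """Measured Pmus peak and PTPmus on clean simulated breaths stay
        within 2% of the simulator's clean-channel values."""
        _, _, metrics, _ = clean_analysis
        truth = clean_sim.truth
        non_m = metrics[~metrics.occluded]
        idx = np.abs(non_m.start.to_numpy()[:, None]
                     - truth.onset_idx.to_numpy()[None, :]).argmin(1)
        tm = truth.iloc[idx]
        assert np.allclose(non_m.pmus_peak, tm.pmus_meas_true, rtol=0.02)
        assert np.allclose(non_m.ptp_mus, tm.ptp_true, rtol=0.05, atol=0.2)


class TestChestWallPrediction:
    def test_anchor_and_monotonicity(self):
        assert predicted_chest_wall_elastance("M", 175.0) == pytest.approx(5.0)
        taller = predicted_chest_wall_elastance("M", 190.0)
        assert taller < predicted_chest_wall_elastance("M", 175.0)
        assert predicted_chest_wall_elastance("F", 160.0) > 0

    def test_override_passthrough_and_missing_demographics(self):
        assert predicted_chest_wall_elastance(override=6.2) == 6.2
        with pytest.raises(ValueError, match="override"):
            predicted_chest_wall_elastance(sex=None, height_cm=None)


def _dummy_rec():
    n = 10
    return pk.WaveformRecording(
        time=np.arange(n) / FS, flow=np.zeros(n), paw=np.zeros(n),
        pes=np.zeros(n), sampling_rate=FS, meta=pk.RecordingMeta(peep=5.0))


def _metrics_frame(occ_ratios, n_non=5):
    """Synthetic metrics table with given per-occlusion dPocc/dPes ratios."""
    rows = []
    for i in range(n_non):
        rows.append(dict(breath=i, occluded=False, pmus_peak=12.0,
                         delta_pes=-10.0, delta_paw_dyn=5.0,
                         delta_pl_dyn=15.0, tidal_volume=0.4, pcw_ei=2.0,
                         ptp_mus=6.0, delta_pocc=np.nan, edi_peak=10.0,
                         start=i, insp_end=i, end=i))
    for j, r in enumerate(occ_ratios):
        # delta_pes = -1 so the per-occlusion ratio equals r exactly
        rows.append(dict(breath=n_non + j, occluded=True, pmus_peak=np.nan,
                         delta_pes=-1.0, delta_paw_dyn=0.0,
                         delta_pl_dyn=np.nan, tidal_volume=0.0, pcw_ei=0.0,
                         ptp_mus=np.nan, delta_pocc=-float(r), edi_peak=10.0,
                         start=0, insp_end=1, end=2))
    return pd.DataFrame(rows)


class TestSummaryAndValidity:
    def test_well_calibrated_recording_passes(self, clean_analysis):
        *_, summary = clean_analysis
        assert summary.pocc_pes_ratio == pytest.approx(1.0, abs=0.05)
        assert summary.valid

    def test_gain_error_shifts_ratio_by_inverse_gain(self):
        """A 1.6x Pes gain gives dPocc/dPes ~ 1/1.6 = 0.625 -> excluded."""
        mech = pk.PatientMechanics(pes_gain_error=1.6)
        cfg = pk.SimConfig(duration=120.0, n_occlusions=5, seed=8)
        sr = pk.simulate_recording(mech, pk.VentilatorSettings(), cfg)
        rec = sr.recording
        breaths = pk.detect_occlusions(rec, pk.segment_breaths(rec))
        m = pk.compute_metrics(rec, breaths)
        s = pk.summarize_recording(rec, breaths, m)
        assert s.pocc_pes_ratio == pytest.approx(1 / 1.6, abs=0.05)
        assert not s.valid

    def test_band_is_inclusive_at_both_ends(self):
        rec = _dummy_rec()
        for ratio, ok in [(0.7, True), (1.3, True), (0.699, False),
                          (1.301, False)]:
            s = pk.summarize_recording(rec, [], _metrics_frame([ratio]))
            assert s.valid is ok

    def test_zero_occlusions_marks_invalid_with_warning(self, caplog):
        rec = _dummy_rec()
        with caplog.at_level("WARNING"):
            s = pk.summarize_recording(rec, [], _metrics_frame([]))
        assert not s.valid and np.isnan(s.pocc_pes_ratio)
        assert "no occlusions" in caplog.text

    def test_means_use_correct_breath_classes(self):
        s = pk.summarize_recording(_dummy_rec(), [], _metrics_frame([1.0] * 2))
        assert s.mean_pmus == 12.0         # non-occluded only
        assert s.mean_delta_pocc == -1.0   # occluded only
        assert s.n_occlusions == 2 and s.n_breaths == 7
        assert s.pocc_values == [-1.0, -1.0]


class TestEdiDriveCheck:
    def test_noise_free_difference_is_zero(self, clean_analysis):
        *_, metrics, _ = clean_analysis
        rep = pk.edi_drive_check(metrics)
        assert abs(rep.mean_difference) < 1e-6

    def test_doubled_occluded_drive_detected(self):
        m = _metrics_frame([1.0] * 4)
        m.loc[m.occluded, "edi_peak"] = 20.0
        rep = pk.edi_drive_check(m)
        assert rep.mean_difference == pytest.approx(10.0)

    def test_requires_three_occlusions_and_edi(self):
        with pytest.raises(ValueError, match="occlusions"):
            pk.edi_drive_check(_metrics_frame([1.0] * 2))
        m = _metrics_frame([1.0] * 4)
        m["edi_peak"] = np.nan
        assert pk.edi_drive_check(m) is None
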
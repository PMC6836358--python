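"""Shared fixtures: simulated recordings reused across test modules.

Expensive simulations are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

import poccscreen as pk


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, artifact-free recording with constant effort amplitude."""
    mech = pk.PatientMechanics(effort_amplitude_mean=12.0,
                               effort_amplitude_sd_within=0.0)
    vent = pk.VentilatorSettings()
    cfg = pk.SimConfig(duration=240.0, n_occlusions=8, noise_sd=0.0,
                       cardiac_artifact_amplitude=0.0, seed=7)
    return pk.simulate_recording(mech, vent, cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-conditions recording (Pes noise + cardiac artifact)."""
    mech = pk.PatientMechanics()
    vent = pk.VentilatorSettings()
    cfg = pk.SimConfig(duration=300.0, n_occlusions=10, seed=42)
    return pk.simulate_recording(mech, vent, cfg)


@pytest.fixture(scope="session")
def noisy_analysis(noisy_sim):
    rec = noisy_sim.recording
    breaths = pk.detect_occlusions(rec, pk.segment_breaths(rec))
    metrics = pk.compute_metrics(rec, breaths)
    summary = pk.summarize_recording(rec, breaths, metrics)
    return rec, breaths, metrics, summary


@pytest.fixture(scope="session")
def clean_analysis(clean_sim):
    rec = clean_sim.recording
    breaths = pk.detect_occlusions(rec, pk.segment_breaths(rec))
    metrics = pk.compute_metrics(
        rec, breaths, options=pk.MetricsOptions(cardiac_removal=False))
    summary = pk.summarize_recording(rec, breaths, metrics)
    return rec, breaths, metrics, summary


@pytest.fixture(scope="session")
def small_cohort():
    """6 patients x 2 short recordings, default noise conditions."""
    cfg = pk.SimConfig(duration=180.0, n_occlusions=8, seed=5)
    return pk.simulate_cohort(6, 2, config=cfg, seed=5)


def analyze_cohort(cohort, band=(0.7, 1.3)):
    summaries = []
    for sr in cohort.recordings:
        rec = sr.recording
        breaths = pk.detect_occlusions(rec, pk.segment_breaths(rec))
        metrics = pk.compute_metrics(rec, breaths)
        summaries.append(pk.summarize_recording(rec, breaths, metrics,
                                                band=band))
    return summaries


@pytest.fixture(scope="session")
def small_cohort_summaries(small_cohort):
    return analyze_cohort(small_cohort)
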
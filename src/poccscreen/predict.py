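"""ΔPocc prediction equations and threshold screening.

The occlusion pressure ΔPocc — the maximal airway-pressure deflection below
PEEP while the patient inspires against a briefly occluded airway — is a
quasi-static, non-invasive surrogate of respiratory muscle pressure.  Two
conversion factors map it to dynamic (flowing-breath) quantities:

    Pmus_predicted     = k1 * mean(ΔPocc)                       (k1 < 0)
    ΔPL,dyn_predicted  = ΔPaw,dyn − k2 * mean(ΔPocc)            (k2 > 0)

Defaults are the externally validated values k1 = −3/4 and k2 = 2/3;
cohort-specific factors (see :mod:`poccscreen.validation`) may override.
Predictions are screened against excessive-effort thresholds (Pmus 10 and
15 cm H2O; ΔPL,dyn 15 and 20 cm H2O) with strict inequality.  Prediction
requires ΔPocc < 0: without inspiratory effort the occlusion deflection
vanishes and the equations do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import RecordingSummary


@dataclass(frozen=True)
class ConversionFactors:
    """k1 (Pmus per unit ΔPocc, negative) and k2 (ΔPes per unit ΔPocc)."""

    k1: float = -0.75
    k2: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and self.k1 < 0):
            raise ValueError(f"k1 must be negative, got {self.k1}")
        if not (np.isfinite(self.k2) and 0 < self.k2 <= 1.3):
            raise ValueError(f"k2 must lie in (0, 1.3], got {self.k2}")


DEFAULT_FACTORS = ConversionFactors()


@dataclass(frozen=True)
class Thresholds:
    """Screening thresholds, cm H2O (strict '>' comparisons)."""

    pmus: tuple[float, float] = (10.0, 15.0)
    delta_pl: tuple[float, float] = (15.0, 20.0)


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class PredictionResult:
    """Predicted Pmus and ΔPL,dyn with threshold exceedance flags."""

    pmus_pred: float
    delta_pl_pred: float
    pocc_values_used: list[float]
    flags: dict[str, bool] = field(default_factory=dict)


def select_occlusions(pocc_values, n: int = 3,
                      rng: np.random.Generator | int | None = None) -> list[float]:
    """Uniform random sample of ``n`` ΔPocc values without replacement.

    Mimics bedside use of just three occlusion maneuvers.  With exactly
    ``n`` values all are returned regardless of the seed; with fewer an
    error advises the explicit full-set fallback.
    """
    values = [float(v) for v in pocc_values]
    if len(values) < n:
        raise ValueError(
            f"only {len(values)} occlusions available but {n} requested; "
            "pass n=len(values) explicitly to use the full set"
        )
    if len(values) == n:
        return values
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = np.sort(rng.choice(len(values), size=n, replace=False))
    return [values[i] for i in idx]


def _check_pocc(pocc_values) -> np.ndarray:
    v = np.asarray(list(pocc_values), dtype=float)
    if v.size == 0:
        raise ValueError("at least one dPocc value is required")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite dPocc value")
    if np.any(v >= 0):
        raise ValueError(
            "dPocc must be negative: a non-negative occlusion deflection "
            "indicates absent inspiratory effort, under which Pmus and "
            "dPL,dyn cannot be predicted from dPocc"
        )
    return v


def predict_pmus(pocc_values, factors: ConversionFactors = DEFAULT_FACTORS) -> float:
    """Pmus_predicted = k1 * mean(ΔPocc), cm H2O (non-negative)."""
    v = _check_pocc(pocc_values)
    return float(factors.k1 * np.mean(v))


def predict_delta_pl(delta_paw_dyn: float, pocc_values,
                     factors: ConversionFactors = DEFAULT_FACTORS) -> float:
    """ΔPL,dyn_predicted = ΔPaw,dyn − k2 * mean(ΔPocc), cm H2O."""
    if not (np.isfinite(delta_paw_dyn) and delta_paw_dyn >= 0):
        raise ValueError("delta_paw_dyn must be finite and >= 0")
    v = _check_pocc(pocc_values)
    return float(delta_paw_dyn - factors.k2 * np.mean(v))


def screen(summary: RecordingSummary,
           factors: ConversionFactors = DEFAULT_FACTORS,
           thresholds: Thresholds = DEFAULT_THRESHOLDS,
           n: int = 3,
           rng: np.random.Generator | int | None = None) -> PredictionResult:
    """Run occlusion selection and both predictions on a valid recording.

    Recordings that failed the esophageal-validity filter are refused.
    Flags use strict inequality, so a prediction exactly at a threshold
    does not count as exceeding it.
    """
    if not summary.valid:
        raise ValueError(
            "recording failed the esophageal-validity filter "
            f"(dPocc/dPes ratio {summary.pocc_pes_ratio!r} outside "
            f"[{summary.band[0]}, {summary.band[1]}]); screening refused"
        )
    used = select_occlusions(summary.pocc_values, n=n, rng=rng)
    pmus = predict_pmus(used, factors)
    dpl = predict_delta_pl(summary.mean_delta_paw, used, factors)
    flags = {}
    for t in thresholds.pmus:
        flags[f"pmus>{t:g}"] = pmus > t
    for t in thresholds.delta_pl:
        flags[f"delta_pl>{t:g}"] = dpl > t
    return PredictionResult(pmus_pred=pmus, delta_pl_pred=dpl,
                            pocc_values_used=used, flags=flags)
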
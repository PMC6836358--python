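"""Derivation/validation statistics for the occlusion-pressure method.

Covers: estimation of the conversion factors k1 = Pmus/ΔPocc and
k2 = ΔPes/ΔPocc from per-recording ratios with a patient-level random
intercept (repeated recordings within subjects); repeated patient-level
split-half cross-validation of the resulting screening test;
repeated-measures Bland-Altman agreement with within-patient limits
expressed as a proportion of the estimated value; ROC discrimination with
sensitivity/specificity; and between-/within-subject R² of the
ΔPocc–PTPmus relationship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .metrics import RecordingSummary, summaries_frame
from .predict import (ConversionFactors, Thresholds, DEFAULT_THRESHOLDS,
                      predict_delta_pl, predict_pmus, select_occlusions)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# variance components: patient-level random intercept


def _moments_components(y: np.ndarray, groups: np.ndarray
                        ) -> tuple[float, float, float]:
    """(mean, sd_between, sd_within) by method-of-moments.

    Patient means are unweighted.  When every patient contributes a single
    observation the between/within split is unidentifiable and all variance
    is attributed to within (no replication).
    """
    uniq = pd.unique(groups)
    gmeans = np.array([y[groups == g].mean() for g in uniq])
    sizes = np.array([(groups == g).sum() for g in uniq])
    mean = float(gmeans.mean())
    if np.all(sizes == 1):
        sd_w = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
        return mean, 0.0, sd_w
    ss_w = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in uniq)
    df_w = int((sizes - 1).sum())
    var_w = ss_w / df_w if df_w > 0 else 0.0
    if uniq.size > 1:
        var_means = float(np.var(gmeans, ddof=1))
        var_b = max(0.0, var_means - var_w * float(np.mean(1.0 / sizes)))
    else:
        var_b = 0.0
    return mean, float(np.sqrt(var_b)), float(np.sqrt(var_w))


def _mixed_components(y: np.ndarray, groups: np.ndarray
                      ) -> tuple[float, float, float, float]:
    """(mean, sd_between, sd_within, se_mean) via a REML random-intercept
    model; raises on failure so callers can fall back to moments."""
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, np.ones((y.size, 1)), groups=groups)
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        mean = float(fit.fe_params[0])
        var_b = float(np.asarray(fit.cov_re)[0, 0])
        var_w = float(fit.scale)
        se = float(fit.bse_fe[0])
    if not (np.isfinite(mean) and np.isfinite(var_b) and np.isfinite(var_w)
            and np.isfinite(se)):
        raise RuntimeError("mixed model produced non-finite estimates")
    return mean, float(np.sqrt(max(var_b, 0.0))), float(np.sqrt(max(var_w, 0.0))), se


def _intercept_estimate(y: np.ndarray, groups: np.ndarray
                        ) -> tuple[float, float, float, float, str]:
    """(mean, ci_low, ci_high, sd_between, method) for an intercept-only
    repeated-measures model, with a patient-mean fallback for degenerate
    data (single recording per patient everywhere, or zero variance)."""
    uniq = pd.unique(groups)
    sizes = np.array([(groups == g).sum() for g in uniq])
    degenerate = np.all(sizes == 1) or float(np.var(y)) < 1e-12
    if not degenerate:
        try:
            mean, sd_b, sd_w, se = _mixed_components(y, groups)
            return mean, mean - 1.96 * se, mean + 1.96 * se, sd_b, "mixed"
        except Exception as exc:  # singular fits, convergence failures
            logger.warning("mixed-effects fit failed (%s); falling back to "
                           "patient-mean averaging", exc)
    mean, sd_b, sd_w = _moments_components(y, groups)
    gmeans = np.array([y[groups == g].mean() for g in uniq])
    if uniq.size > 1 and float(np.var(gmeans)) > 1e-15:
        se = float(np.std(gmeans, ddof=1) / np.sqrt(uniq.size))
        tcrit = float(stats.t.ppf(0.975, uniq.size - 1))
    else:
        se, tcrit = 0.0, 0.0
    return mean, mean - tcrit * se, mean + tcrit * se, sd_b, "patient-means"


# ---------------------------------------------------------------------------
# conversion-factor derivation


@dataclass
class FactorEstimate:
    value: float
    ci_low: float
    ci_high: float
    method: str


@dataclass
class ConversionEstimate:
    """k1/k2 estimates with 95% CIs from a cohort of valid recordings."""

    factors: ConversionFactors
    k1: FactorEstimate
    k2: FactorEstimate
    n_recordings: int
    n_patients: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"factor": "k1", "estimate": self.k1.value,
              "ci_low": self.k1.ci_low, "ci_high": self.k1.ci_high,
              "method": self.k1.method},
             {"factor": "k2", "estimate": self.k2.value,
              "ci_low": self.k2.ci_low, "ci_high": self.k2.ci_high,
              "method": self.k2.method}]
        )


def _as_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return summaries_frame(list(summaries))


def derive_conversion_factors(summaries) -> ConversionEstimate:
    """Estimate k1 and k2 from per-recording ratios.

    Each valid recording contributes mean Pmus / mean ΔPocc and
    mean ΔPes / mean ΔPocc (means over non-occluded breaths; ΔPocc over
    occlusions).  Ratios are modeled with a patient-level random intercept
    (REML); the fixed-effect intercept is the factor.  Falls back to
    patient-mean averaging with a warning when the fit is singular.
    """
    df = _as_frame(summaries)
    df = df[df["valid"] & np.isfinite(df["mean_delta_pocc"])
            & (df["mean_delta_pocc"] < 0)]
    if df.empty or df["patient"].nunique() < 2:
        raise ValueError("need valid recordings from at least 2 patients")
    groups = df["patient"].to_numpy()
    r1 = (df["mean_pmus"] / df["mean_delta_pocc"]).to_numpy(dtype=float)
    r2 = (df["mean_delta_pes"] / df["mean_delta_pocc"]).to_numpy(dtype=float)
    m1, lo1, hi1, _, meth1 = _intercept_estimate(r1, groups)
    m2, lo2, hi2, _, meth2 = _intercept_estimate(r2, groups)
    return ConversionEstimate(
        factors=ConversionFactors(k1=m1, k2=m2),
        k1=FactorEstimate(m1, lo1, hi1, meth1),
        k2=FactorEstimate(m2, lo2, hi2, meth2),
        n_recordings=int(len(df)),
        n_patients=int(df["patient"].nunique()),
    )


# ---------------------------------------------------------------------------
# repeated-measures Bland-Altman


@dataclass
class AgreementReport:
    """Repeated-measures Bland-Altman agreement.

    ``bias_mean`` and ``sd_bias_between`` are on the measurement scale
    (cm H2O); ``la_pct_within`` is the within-patient limit of agreement as
    a percent of the estimated value, obtained by back-transforming
    1.96 x the within-patient SD of log differences.  ``total_loa(x)``
    composes both: 1.96*SD_bias,btw + LA%,within * x.
    """

    bias_mean: float
    bias_ratio: float
    sd_bias_between: float
    la_pct_within: float
    sd_log_within: float
    sd_log_between: float
    n_pairs: int
    n_patients: int
    method: str

    def total_loa(self, estimate: float) -> float:
        return 1.96 * self.sd_bias_between + self.la_pct_within / 100.0 * estimate


def bland_altman_repeated(predicted, measured, patient_ids) -> AgreementReport:
    """Agreement between predicted and measured values with repeated
    measures within patients.

    Differences of log values (log transform for the multiplicative error
    structure of pressure ratios) are decomposed into a between-patient
    bias SD and a within-patient residual; the within component is
    back-transformed into a percent-of-estimate limit of agreement.  Bias
    and its between-patient SD are additionally reported on the natural
    scale.  Values must be positive.
    """
    p = np.asarray(list(predicted), dtype=float)
    m = np.asarray(list(measured), dtype=float)
    g = np.asarray(list(patient_ids))
    if not (p.size == m.size == g.size) or p.size == 0:
        raise ValueError("predicted, measured and patient_ids must be "
                         "non-empty and equally long")
    if np.any(p <= 0) or np.any(m <= 0):
        raise ValueError("nonpositive values: log transform undefined")
    d_nat = p - m
    d_log = np.log(p) - np.log(m)

    def components(y):
        uniq = pd.unique(g)
        sizes = np.array([(g == u).sum() for u in uniq])
        within_var = float(np.mean([np.var(y[g == u]) for u in uniq]))
        if (np.all(sizes == 1) or float(np.var(y)) < 1e-15 or uniq.size < 2
                or within_var < 1e-15):
            return _moments_components(y, g) + ("moments",)
        try:
            mean, sd_b, sd_w, _ = _mixed_components(y, g)
            return mean, sd_b, sd_w, "mixed"
        except Exception:
            return _moments_components(y, g) + ("moments",)

    bias, sd_b, _, meth = components(d_nat)
    bias_log, sd_b_log, sd_w_log, _ = components(d_log)
    return AgreementReport(
        bias_mean=float(bias),
        bias_ratio=float(np.exp(bias_log)),
        sd_bias_between=float(sd_b),
        la_pct_within=float((np.exp(1.96 * sd_w_log) - 1.0) * 100.0),
        sd_log_within=float(sd_w_log),
        sd_log_between=float(sd_b_log),
        n_pairs=int(p.size),
        n_patients=int(pd.unique(g).size),
        method=meth,
    )


# ---------------------------------------------------------------------------
# discrimination (ROC)


@dataclass
class DiscriminationReport:
    auroc: float
    ci: tuple[float, float] | None
    threshold: float
    sensitivity: float  # % at cutoff == threshold (predicted > threshold)
    specificity: float  # %
    cutoffs: pd.DataFrame | None = None


def _sens_spec(pred: np.ndarray, labels: np.ndarray, cutoff: float
               ) -> tuple[float, float]:
    pos = pred > cutoff
    tp = np.sum(pos & labels)
    fn = np.sum(~pos & labels)
    tn = np.sum(~pos & ~labels)
    fp = np.sum(pos & ~labels)
    sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    return float(sens), float(spec)


def discrimination(predicted, measured=None, threshold: float = 10.0, *,
                   labels=None, patient_ids=None, n_boot: int = 2000,
                   seed: int | None = 0) -> DiscriminationReport:
    """ROC discrimination of predictions against a binary reference.

    The reference is ``measured > threshold`` (or explicit ``labels``).
    AUROC is the empirical rank statistic; the CI is a seeded percentile
    bootstrap (patient-level when ``patient_ids`` is given, 2000 resamples
    by default, ``n_boot=0`` to skip).  Sensitivity/specificity are
    reported at the measured-scale threshold applied to the predictions,
    plus a cutoff table over the observed prediction range.
    """
    pred = np.asarray(list(predicted), dtype=float)
    if labels is None:
        meas = np.asarray(list(measured), dtype=float)
        labels = meas > threshold
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    auroc = float(roc_auc_score(labels, pred))
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        if patient_ids is not None:
            pid = np.asarray(list(patient_ids))
            uniq = pd.unique(pid)
            groups_idx = [np.flatnonzero(pid == u) for u in uniq]
        aucs = []
        for _ in range(n_boot):
            if patient_ids is not None:
                take = rng.integers(0, len(groups_idx), len(groups_idx))
                idx = np.concatenate([groups_idx[i] for i in take])
            else:
                idx = rng.integers(0, pred.size, pred.size)
            lb = labels[idx]
            if lb.all() or not lb.any():
                continue
            aucs.append(roc_auc_score(lb, pred[idx]))
        if aucs:
            ci = (float(np.percentile(aucs, 2.5)),
                  float(np.percentile(aucs, 97.5)))
    sens, spec = _sens_spec(pred, labels, threshold)
    cut_grid = np.unique(np.r_[np.quantile(pred, np.linspace(0.05, 0.95, 19)),
                               threshold])
    table = pd.DataFrame(
        [(c, *_sens_spec(pred, labels, c)) for c in cut_grid],
        columns=["cutoff", "sensitivity_pct", "specificity_pct"])
    return DiscriminationReport(auroc=auroc, ci=ci, threshold=float(threshold),
                                sensitivity=sens, specificity=spec,
                                cutoffs=table)


# ---------------------------------------------------------------------------
# PTPmus correlation


@dataclass
class CorrelationReport:
    between_r2: float
    within_r2: float
    n_patients: int
    n_obs: int


def ptp_correlation(df: pd.DataFrame, x: str = "mean_delta_pocc",
                    y: str = "mean_ptp_mus", patient: str = "patient"
                    ) -> CorrelationReport:
    """Between- and within-subject R² of the x-y relationship.

    Between-subjects: squared correlation of patient means.  Within-
    subjects: squared correlation of patient-centered values (patients
    with at least two recordings).  Either component is NaN when the data
    cannot support it.
    """
    d = df[[patient, x, y]].dropna()
    if d[patient].nunique() < 2:
        raise ValueError("need at least 2 patients")
    gm = d.groupby(patient)[[x, y]].mean()
    between = np.nan
    if len(gm) >= 2 and gm[x].var() > 0 and gm[y].var() > 0:
        between = float(np.corrcoef(gm[x], gm[y])[0, 1] ** 2)
    counts = d.groupby(patient)[x].transform("size")
    cen = d[counts >= 2].copy()
    within = np.nan
    if len(cen) >= 3 and cen[patient].nunique() >= 1:
        cx = cen[x] - cen.groupby(patient)[x].transform("mean")
        cy = cen[y] - cen.groupby(patient)[y].transform("mean")
        if cx.var() > 0 and cy.var() > 0:
            within = float(np.corrcoef(cx, cy)[0, 1] ** 2)
    return CorrelationReport(between_r2=between, within_r2=within,
                             n_patients=int(d[patient].nunique()),
                             n_obs=int(len(d)))


# ---------------------------------------------------------------------------
# repeated cross-validation


@dataclass
class CrossValReport:
    """Per-repetition k1/k2, AUROCs and agreement statistics."""

    per_rep: pd.DataFrame
    n_reps: int
    seed: int | None
    n_undefined: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        num = self.per_rep.select_dtypes(float)
        return pd.DataFrame({
            "median": num.median(),
            "q25": num.quantile(0.25),
            "q75": num.quantile(0.75),
            "n_defined": num.notna().sum(),
        })


def cross_validate(summaries, truth: pd.DataFrame | None = None,
                   reps: int = 100, split: float = 0.5, n_occ: int = 3,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS,
                   seed: int | None = 0) -> CrossValReport:
    """Repeated patient-level split-half cross-validation.

    Each repetition randomly divides patients into derivation and
    validation halves (odd counts rounded toward derivation; the sets are
    disjoint by construction).  k1/k2 are derived on the derivation half;
    on each valid validation recording, ``n_occ`` randomly selected ΔPocc
    values feed the prediction equations; agreement (repeated-measures
    Bland-Altman) and discrimination (AUROC per threshold) are computed
    per repetition.

    The exceedance reference is the measured recording means, or — when a
    ground-truth table with columns ``patient, day, true_mean_pmus,
    true_mean_delta_pl`` is supplied — the simulator's true values.
    Repetitions whose validation half contains a single class are marked
    undefined for that threshold and excluded from summaries (with
    counts).
    """
    df = _as_frame(summaries)
    if df["patient"].nunique() < 4:
        raise ValueError("need at least 4 patients for split-half "
                         "cross-validation")
    if truth is not None:
        df = df.merge(
            truth[["patient", "day", "true_mean_pmus", "true_mean_delta_pl"]],
            on=["patient", "day"], how="left")
    patients = np.array(sorted(df["patient"].unique()))
    master = np.random.default_rng(seed)
    streams = master.spawn(reps)
    rows = []
    n_undef: dict[str, int] = {}
    for r in range(reps):
        rng = streams[r]
        perm = rng.permutation(patients)
        n_der = int(np.ceil(split * patients.size))
        der_set, val_set = set(perm[:n_der]), set(perm[n_der:])
        assert not (der_set & val_set), "derivation/validation sets overlap"
        der = df[df["patient"].isin(der_set)]
        val = df[df["patient"].isin(val_set) & df["valid"]]
        row: dict = {"rep": r}
        try:
            est = derive_conversion_factors(der)
        except Exception as exc:
            logger.warning("repetition %d: derivation failed (%s)", r, exc)
            rows.append(row)
            continue
        row["k1"] = est.factors.k1
        row["k2"] = est.factors.k2
        preds_pmus, preds_pl, meas_pmus, meas_pl, pids = [], [], [], [], []
        for _, rec in val.iterrows():
            vals = rec["pocc_values"]
            if len(vals) < n_occ or not all(v < 0 for v in vals):
                continue
            used = select_occlusions(vals, n=n_occ, rng=rng)
            preds_pmus.append(predict_pmus(used, est.factors))
            preds_pl.append(predict_delta_pl(rec["mean_delta_paw"], used,
                                             est.factors))
            if truth is not None:
                meas_pmus.append(rec["true_mean_pmus"])
                meas_pl.append(rec["true_mean_delta_pl"])
            else:
                meas_pmus.append(rec["mean_pmus"])
                meas_pl.append(rec["mean_delta_pl_dyn"])
            pids.append(rec["patient"])
        row["n_val"] = len(preds_pmus)
        if len(preds_pmus) >= 3:
            for name, preds, meas, thrs in (
                    ("pmus", preds_pmus, meas_pmus, thresholds.pmus),
                    ("dpl", preds_pl, meas_pl, thresholds.delta_pl)):
                for t in thrs:
                    key = f"auroc_{name}_gt{t:g}"
                    lab = np.asarray(meas) > t
                    if lab.all() or not lab.any():
                        row[key] = np.nan
                        n_undef[key] = n_undef.get(key, 0) + 1
                        continue
                    row[key] = float(roc_auc_score(lab, preds))
                try:
                    ba = bland_altman_repeated(preds, meas, pids)
                    row[f"bias_{name}"] = ba.bias_mean
                    row[f"la_pct_within_{name}"] = ba.la_pct_within
                    row[f"sd_bias_btw_{name}"] = ba.sd_bias_between
                except ValueError:
                    pass
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    return CrossValReport(per_rep=per_rep, n_reps=reps, seed=seed,
                          n_undefined=n_undef)
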
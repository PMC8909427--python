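"""Prognostic-model stability under segmentation uncertainty.

The pipeline mirrors a standard radiomics survival study: fit a Cox
proportional-hazards model on a training cohort (four radiomic covariates,
log-scaled, standardized, |z| > 3 outliers removed), stratify the test
cohort at the median training risk score, and measure stratification with a
two-sample log-rank test.

Stability is probed by Monte Carlo: each simulation independently samples,
per patient, one mask realization's feature vector (uniformly, with
replacement) in both cohorts and re-runs the whole pipeline.  The fraction
of simulations with log-rank p < alpha summarises robustness.  An
"ensemble" model — the fitted model whose coefficients are closest (least
squares) to the element-wise coefficient medians — is then scored on many
test realizations, scores averaged per patient, and per-patient agreement
delta computed over every realization's classification.

"Risk score" throughout is the Cox linear predictor (log relative hazard);
median-splitting it is identical to median-splitting the hazard ratio by
monotonicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from segstress.errors import FitError, ValidationError
from segstress.uncertainty_stats import AgreementRecord, FeatureRealizations, agreement_delta
from segstress.volumes_io import SurvivalRecord

logger = logging.getLogger(__name__)

#: significance level for counting a simulation as "significant"
ALPHA = 0.05
#: standardized-score cutoff for outlier exclusion
OUTLIER_Z = 3.0


def survival_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """patient_id-indexed frame with time_days and event columns."""
    return pd.DataFrame(
        {
            "time_days": [r.time_days for r in records],
            "event": [int(r.event) for r in records],
        },
        index=pd.Index([r.patient_id for r in records], name="patient_id"),
    )


@dataclass
class PreprocessParams:
    """Per-feature log-shift and training mean/SD."""

    shift: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class CoxModelFit:
    """Fitted coefficients, the training-median risk threshold, and the
    training preprocessing parameters needed to score new patients."""

    coefficients: pd.Series
    training_median_score: float
    preprocessing: PreprocessParams

    def scores(self, raw_features: pd.DataFrame) -> pd.Series:
        """Cox linear predictor for raw (untransformed) feature rows."""
        z, _ = _apply_preprocessing(raw_features, self.preprocessing)
        return z[self.coefficients.index] @ self.coefficients


@dataclass
class SimulationResult:
    records: pd.DataFrame
    fraction_significant: float
    n_failures: int
    ensemble_model: CoxModelFit | None = None
    ensembled_statistic: float | None = None
    ensembled_p_value: float | None = None
    agreements: list[AgreementRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing


def fit_preprocessing(train: pd.DataFrame) -> PreprocessParams:
    """Learn per-feature log-shift and standardization from training rows."""
    if len(train) < 2:
        raise ValidationError("need >= 2 training patients")
    shift, mean, sd = {}, {}, {}
    for col in train.columns:
        x = train[col].to_numpy(dtype=float)
        s = 1.0 - x.min() if x.min() <= 0 else 0.0
        logged = np.log(x + s)
        mu, sigma = logged.mean(), logged.std(ddof=1)
        if sigma == 0:
            raise FitError(f"degenerate feature {col!r}: zero training SD after log")
        shift[col], mean[col], sd[col] = float(s), float(mu), float(sigma)
    return PreprocessParams(shift=shift, mean=mean, sd=sd)


def _apply_preprocessing(
    df: pd.DataFrame, params: PreprocessParams
) -> tuple[pd.DataFrame, pd.Series]:
    """Transform raw feature rows; returns (z-scores, excluded flags).

    A patient is flagged excluded when any feature has |z| > 3 or when the
    training log-shift leaves a non-positive value (out of the training
    support).
    """
    z = pd.DataFrame(index=df.index, dtype=float)
    excluded = pd.Series(False, index=df.index)
    for col in df.columns:
        shifted = df[col].astype(float) + params.shift[col]
        bad = shifted <= 0
        excluded |= bad
        logged = np.log(shifted.where(~bad, 1.0))
        z[col] = (logged - params.mean[col]) / params.sd[col]
        excluded |= z[col].abs() > OUTLIER_Z
    return z, excluded


def preprocess(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, PreprocessParams]:
    """Log-scale, standardize on training statistics, flag |z| > 3 outliers.

    Returns transformed train/test tables and per-cohort exclusion flags;
    flagged patients are dropped from that realization's fit or scoring,
    their values are never clipped.
    """
    params = fit_preprocessing(train)
    z_train, excl_train = _apply_preprocessing(train, params)
    z_test, excl_test = _apply_preprocessing(test, params)
    return z_train, z_test, excl_train, excl_test, params


# ---------------------------------------------------------------------------
# Cox fit, stratification, log-rank


def fit_and_threshold(
    train_features: pd.DataFrame, train_survival: pd.DataFrame
) -> CoxModelFit:
    """Cox PH fit on raw training features plus the median-risk threshold.

    Preprocessing (log, standardize, outlier exclusion) happens inside so
    the returned model can score raw feature tables directly.
    """
    params = fit_preprocessing(train_features)
    z, excluded = _apply_preprocessing(train_features, params)
    kept = z[~excluded]
    surv = train_survival.loc[kept.index]
    if surv["event"].sum() == 0:
        raise FitError("no events in training data")
    df = pd.concat([kept, surv], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_days", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"Cox fit did not converge: {exc}") from exc
    coef = cph.params_[train_features.columns]
    scores = kept @ coef
    return CoxModelFit(
        coefficients=coef,
        training_median_score=float(scores.median()),
        preprocessing=params,
    )


def logrank_statistic(
    time_a, event_a, time_b, event_b
) -> tuple[float, float]:
    """Two-sample log-rank (statistic, p-value)."""
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def stratify_and_test(
    model: CoxModelFit, test_features: pd.DataFrame, test_survival: pd.DataFrame
) -> tuple[float, float, pd.Series]:
    """Median-stratify the test cohort with a fitted model and log-rank the
    two risk groups.

    Patients flagged by preprocessing are dropped from the test.  An empty
    stratum yields (nan, nan, labels) — a flagged degenerate result.
    """
    z, excluded = _apply_preprocessing(test_features, model.preprocessing)
    kept = z[~excluded]
    scores = kept[model.coefficients.index] @ model.coefficients
    labels = scores > model.training_median_score  # True = high risk
    surv = test_survival.loc[kept.index]
    if labels.all() or (~labels).all():
        logger.warning("degenerate stratification: one empty risk stratum")
        return float("nan"), float("nan"), labels
    hi, lo = surv[labels], surv[~labels]
    stat, p = logrank_statistic(
        hi["time_days"], hi["event"], lo["time_days"], lo["event"]
    )
    return stat, p, labels


# ---------------------------------------------------------------------------
# Monte Carlo simulation


def sample_realization(fr: FeatureRealizations, rng: np.random.Generator) -> pd.DataFrame:
    """One feature table: per patient, one realization index drawn uniformly
    (the same index for all of that patient's features — one mask, one
    feature vector)."""
    idx = rng.integers(0, fr.n_realizations, size=fr.n_patients)
    return pd.DataFrame(
        {f: arr[np.arange(fr.n_patients), idx] for f, arr in fr.values.items()},
        index=pd.Index(fr.patient_ids, name="patient_id"),
    )


def _iter_rng(seed: int, i: int) -> np.random.Generator:
    # per-iteration streams: stable when n_sim changes
    return np.random.default_rng(np.random.SeedSequence((seed, i)))


def baseline_pipeline(
    train_features: pd.DataFrame,
    train_survival: pd.DataFrame,
    test_features: pd.DataFrame,
    test_survival: pd.DataFrame,
) -> tuple[CoxModelFit, float, float]:
    """Fit + stratify + log-rank on one pair of feature tables (e.g. the
    original masks).  Returns (model, statistic, p)."""
    model = fit_and_threshold(train_features, train_survival)
    stat, p, _ = stratify_and_test(model, test_features, test_survival)
    return model, stat, p


def run_simulation(
    train_fr: FeatureRealizations,
    train_survival: list[SurvivalRecord] | pd.DataFrame,
    test_fr: FeatureRealizations,
    test_survival: list[SurvivalRecord] | pd.DataFrame,
    features: list[str] | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
    ensemble: bool = True,
) -> SimulationResult:
    """Monte Carlo pipeline-stability simulation.

    Each of ``n_sim`` iterations samples one realization per patient in both
    cohorts, preprocesses, fits the Cox model, median-stratifies the test
    set and records the log-rank statistic, p-value and coefficients.
    Individual iteration failures are recorded; more than 10% failures is an
    error.  When ``ensemble`` is set, the coefficient-median-closest model is
    selected, scored on ``n_sim`` fresh test realizations with per-patient
    score averaging, and per-patient agreement deltas are computed over all
    realizations.
    """
    if not isinstance(train_survival, pd.DataFrame):
        train_survival = survival_frame(train_survival)
    if not isinstance(test_survival, pd.DataFrame):
        test_survival = survival_frame(test_survival)
    if features is not None:
        train_fr = train_fr.subset(features)
        test_fr = test_fr.subset(features)

    rows = []
    models: list[CoxModelFit] = []
    n_failures = 0
    for i in range(n_sim):
        rng = _iter_rng(seed, i)
        train_tab = sample_realization(train_fr, rng)
        test_tab = sample_realization(test_fr, rng)
        try:
            model = fit_and_threshold(train_tab, train_survival)
            stat, p = stratify_and_test(model, test_tab, test_survival)[:2]
        except (FitError, ValidationError) as exc:
            logger.warning("simulation %d failed: %s", i, exc)
            n_failures += 1
            rows.append({"iteration": i, "statistic": np.nan, "p_value": np.nan, "failed": True})
            continue
        row = {"iteration": i, "statistic": stat, "p_value": p, "failed": False}
        for f, c in model.coefficients.items():
            row[f"coef_{f}"] = c
        rows.append(row)
        models.append(model)
    if n_failures > 0.1 * n_sim:
        raise FitError(f"{n_failures}/{n_sim} simulations failed")
    records = pd.DataFrame(rows)
    valid_p = records.loc[~records["failed"], "p_value"].dropna()
    fraction_significant = float((valid_p < alpha).mean()) if len(valid_p) else 0.0

    result = SimulationResult(
        records=records,
        fraction_significant=fraction_significant,
        n_failures=n_failures,
    )
    if ensemble and models:
        result.ensemble_model = select_ensemble(models)
        scores, labels = ensembled_scores(
            result.ensemble_model, test_fr, n_sim=n_sim, seed=seed + 1
        )
        surv = test_survival.loc[labels.index]
        if labels.any() and (~labels).any():
            hi, lo = surv[labels], surv[~labels]
            result.ensembled_statistic, result.ensembled_p_value = logrank_statistic(
                hi["time_days"], hi["event"], lo["time_days"], lo["event"]
            )
        result.agreements = [
            patient_agreement(result.ensemble_model, test_fr, pid)
            for pid in test_fr.patient_ids
        ]
    return result


def select_ensemble(models: list[CoxModelFit]) -> CoxModelFit:
    """The model whose coefficient vector is least-squares closest to the
    element-wise median of all models' coefficients; ties take the first."""
    if not models:
        raise ValidationError("select_ensemble needs at least one model")
    coef_mat = np.vstack([m.coefficients.to_numpy() for m in models])
    med = np.median(coef_mat, axis=0)
    sq = ((coef_mat - med) ** 2).sum(axis=1)
    return models[int(np.argmin(sq))]


def ensembled_scores(
    model: CoxModelFit,
    test_fr: FeatureRealizations,
    n_sim: int,
    seed: int,
) -> tuple[pd.Series, pd.Series]:
    """Score ``n_sim`` sampled test realizations with a fixed model, average
    the linear predictor per patient, and label at the model's training
    median.  Returns (mean scores, high-risk labels)."""
    totals = np.zeros(test_fr.n_patients)
    for i in range(n_sim):
        rng = _iter_rng(seed, i)
        tab = sample_realization(test_fr, rng)
        totals += model.scores(tab).to_numpy()
    mean_scores = pd.Series(
        totals / n_sim, index=pd.Index(test_fr.patient_ids, name="patient_id")
    )
    return mean_scores, mean_scores > model.training_median_score


def patient_agreement(
    model: CoxModelFit, fr: FeatureRealizations, patient_id: str
) -> AgreementRecord:
    """Classify every mask realization of one patient with a fixed model and
    summarise with the agreement delta."""
    p = fr.patient_ids.index(patient_id)
    tab = pd.DataFrame({f: arr[p, :] for f, arr in fr.values.items()})
    scores = model.scores(tab)
    labels = (scores > model.training_median_score).tolist()
    rec = agreement_delta(labels, patient_id=patient_id)
    return rec
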
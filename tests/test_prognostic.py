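import numpy as np
import pandas as pd
import pytest

from oracles import bf_logrank_statistic

from segstress.errors import FitError, ValidationError
from segstress.prognostic import (
    CoxModelFit,
    baseline_pipeline,
    ensembled_scores,
    fit_and_threshold,
    fit_preprocessing,
    logrank_statistic,
    patient_agreement,
    preprocess,
    run_simulation,
    sample_realization,
    select_ensemble,
    stratify_and_test,
    survival_frame,
)
from segstress.synthetic import make_contrast_cohort, make_survival
from segstress.uncertainty_stats import FeatureRealizations


def _frame(values, index=None):
    return pd.DataFrame({"f": values}, index=index or [f"p{i}" for i in range(len(values))])


# ---------------------------------------------------------------------------
# preprocessing


def test_constant_feature_is_degenerate():
    with pytest.raises(FitError):
        fit_preprocessing(_frame([3.0, 3.0, 3.0]))


def test_value_at_training_mean_retained_outlier_flagged():
    rng = np.random.default_rng(0)
    base = np.exp(rng.normal(0, 0.5, size=60))  # positive, log-normal
    train = _frame(base)
    params = fit_preprocessing(train)
    # plant a test value exactly at the training geometric mean -> z == 0
    at_mean = float(np.exp(params.mean["f"]) - params.shift["f"])
    outlier = float(np.exp(params.mean["f"] + 4 * params.sd["f"]) - params.shift["f"])
    test = _frame([at_mean, outlier], index=["ok", "out"])
    z_train, z_test, excl_train, excl_test, _ = preprocess(train, test)
    assert z_test.loc["ok", "f"] == pytest.approx(0.0, abs=1e-12)
    assert not excl_test["ok"]
    assert excl_test["out"]


def test_nonpositive_shift_applies_to_train_min():
    train = _frame([-2.0, 0.0, 3.0, 5.0])
    params = fit_preprocessing(train)
    assert params.shift["f"] == 3.0  # 1 - min


# ---------------------------------------------------------------------------
# Cox fit and log-rank


@pytest.fixture(scope="module")
def simple_cohort():
    rng = np.random.default_rng(42)
    n = 200
    x = np.exp(rng.normal(0, 0.4, size=n))  # positive covariate
    z = (np.log(x) - np.log(x).mean()) / np.log(x).std(ddof=1)
    time = rng.exponential(500 * np.exp(-z))
    event = rng.random(n) > 0.2
    features = pd.DataFrame({"f": x}, index=[f"p{i}" for i in range(n)])
    surv = pd.DataFrame(
        {"time_days": time, "event": event.astype(int)}, index=features.index
    )
    return features, surv


def test_cox_fit_matches_statsmodels_reference(simple_cohort):
    from statsmodels.duration.hazard_regression import PHReg

    features, surv = simple_cohort
    model = fit_and_threshold(features, surv)
    params = fit_preprocessing(features)
    z = np.log(features["f"] + params.shift["f"])
    z = (z - params.mean["f"]) / params.sd["f"]
    kept = z[np.abs(z) <= 3.0]
    ref = PHReg(
        surv.loc[kept.index, "time_days"],
        kept.to_numpy()[:, None],
        status=surv.loc[kept.index, "event"],
        ties="efron",
    ).fit()
    assert model.coefficients["f"] == pytest.approx(float(ref.params[0]), abs=1e-4)


def test_null_covariate_coefficient_near_zero():
    rng = np.random.default_rng(1)
    n = 200
    features = _frame(np.exp(rng.normal(size=n)))
    surv = pd.DataFrame(
        {"time_days": rng.exponential(300, size=n), "event": np.ones(n, dtype=int)},
        index=features.index,
    )
    model = fit_and_threshold(features, surv)
    assert abs(model.coefficients["f"]) < 0.25


def test_cox_recovers_planted_log_hazard():
    rng = np.random.default_rng(3)
    n = 500
    z = rng.normal(size=n)
    time = rng.exponential(500 * np.exp(-z))  # beta = 1 on standardized scale
    features = _frame(np.exp(z))  # log-scaling in preprocess recovers z
    surv = pd.DataFrame(
        {"time_days": time, "event": np.ones(n, dtype=int)}, index=features.index
    )
    model = fit_and_threshold(features, surv)
    assert model.coefficients["f"] == pytest.approx(1.0, abs=0.2)


def test_logrank_matches_hand_computed_table():
    # textbook fixture: group1 {3+, 5, 7}, group2 {1, 4, 8+}
    t1, e1 = [3, 5, 7], [0, 1, 1]
    t2, e2 = [1, 4, 8], [1, 1, 0]
    stat, p = logrank_statistic(t1, e1, t2, e2)
    assert stat == pytest.approx(bf_logrank_statistic(t1, e1, t2, e2), abs=1e-9)
    assert 0 < p < 1


def test_logrank_identical_groups_null():
    t = [100, 200, 300, 400]
    e = [1, 1, 0, 1]
    stat, p = logrank_statistic(t, e, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_separated_groups_significant():
    rng = np.random.default_rng(7)
    for seed in range(5):
        r = np.random.default_rng(seed)
        t1 = r.exponential(100, 100)
        t2 = r.exponential(300, 100)  # hazard ratio 3
        _, p = logrank_statistic(t1, np.ones(100), t2, np.ones(100))
        assert p < 0.05


def test_stratify_degenerate_single_stratum_flagged(simple_cohort):
    features, surv = simple_cohort
    model = fit_and_threshold(features, surv)
    lopsided = CoxModelFit(
        coefficients=model.coefficients,
        training_median_score=1e9,  # nobody exceeds this
        preprocessing=model.preprocessing,
    )
    stat, p, labels = stratify_and_test(lopsided, features, surv)
    assert np.isnan(stat) and np.isnan(p)
    assert not labels.any()


# ---------------------------------------------------------------------------
# realization sampling


def _toy_fr(n_patients=10, n_real=301, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureRealizations(
        patient_ids=[f"p{i}" for i in range(n_patients)],
        values={"f": rng.normal(size=(n_patients, n_real)) + 10.0},
    )


def test_sample_realization_deterministic_and_uniform():
    fr = _toy_fr()
    t1 = sample_realization(fr, np.random.default_rng(5))
    t2 = sample_realization(fr, np.random.default_rng(5))
    pd.testing.assert_frame_equal(t1, t2)
    single = FeatureRealizations(patient_ids=["a"], values={"f": np.array([[3.0]])})
    assert sample_realization(single, np.random.default_rng(0)).iloc[0, 0] == 3.0
    # frequencies roughly uniform over realization indices
    from scipy import stats

    fr10 = _toy_fr(n_patients=10, n_real=10)
    rng = np.random.default_rng(9)
    counts = np.zeros(10)
    for _ in range(2000):
        tab = sample_realization(fr10, rng)
        # recover chosen index per patient from the values
        for p in range(10):
            idx = int(np.argmin(np.abs(fr10.values["f"][p] - tab.iloc[p, 0])))
            counts[idx] += 1
    assert stats.chisquare(counts).pvalue > 1e-3


# ---------------------------------------------------------------------------
# full simulation


@pytest.fixture(scope="module")
def small_cohort():
    return make_contrast_cohort(n_train=80, n_test=60, n_realizations=21, seed=4)


def test_single_simulation_with_originals_reproduces_baseline(small_cohort):
    co = small_cohort
    trs, tes = survival_frame(co.train_survival), survival_frame(co.test_survival)
    originals_train = FeatureRealizations(
        patient_ids=co.train_fr.patient_ids,
        values={f: co.train_fr.values[f][:, :1] for f in co.low_features},
    )
    originals_test = FeatureRealizations(
        patient_ids=co.test_fr.patient_ids,
        values={f: co.test_fr.values[f][:, :1] for f in co.low_features},
    )
    res = run_simulation(
        originals_train, trs, originals_test, tes,
        features=co.low_features, n_sim=1, seed=0, ensemble=False,
    )
    model, stat, p = baseline_pipeline(
        co.train_fr.subset(co.low_features).originals(), trs,
        co.test_fr.subset(co.low_features).originals(), tes,
    )
    rec = res.records.iloc[0]
    assert rec["statistic"] == stat and rec["p_value"] == p  # bit-for-bit
    for f in co.low_features:
        assert rec[f"coef_{f}"] == model.coefficients[f]


def test_zero_intra_patient_noise_collapses_p_values(small_cohort):
    co = small_cohort
    trs, tes = survival_frame(co.train_survival), survival_frame(co.test_survival)
    dup_train = FeatureRealizations(
        patient_ids=co.train_fr.patient_ids,
        values={
            f: np.repeat(co.train_fr.values[f][:, :1], 5, axis=1) for f in co.low_features
        },
    )
    dup_test = FeatureRealizations(
        patient_ids=co.test_fr.patient_ids,
        values={
            f: np.repeat(co.test_fr.values[f][:, :1], 5, axis=1) for f in co.low_features
        },
    )
    res = run_simulation(
        dup_train, trs, dup_test, tes, features=co.low_features,
        n_sim=6, seed=1, ensemble=False,
    )
    assert res.records["p_value"].nunique() == 1


def test_simulation_failure_budget(small_cohort, monkeypatch):
    co = small_cohort
    trs, tes = survival_frame(co.train_survival), survival_frame(co.test_survival)
    import segstress.prognostic as prog

    def boom(*a, **k):
        raise FitError("forced")

    monkeypatch.setattr(prog, "fit_and_threshold", boom)
    with pytest.raises(FitError):
        prog.run_simulation(
            co.train_fr, trs, co.test_fr, tes,
            features=co.low_features, n_sim=5, seed=0, ensemble=False,
        )


# ---------------------------------------------------------------------------
# ensemble


def _model(coefs) -> CoxModelFit:
    from segstress.prognostic import PreprocessParams

    names = [f"f{i}" for i in range(len(coefs))]
    return CoxModelFit(
        coefficients=pd.Series(coefs, index=names),
        training_median_score=0.0,
        preprocessing=PreprocessParams(
            shift={n: 0.0 for n in names},
            mean={n: 0.0 for n in names},
            sd={n: 1.0 for n in names},
        ),
    )


def test_select_ensemble_median_least_squares():
    models = [_model([0.9]), _model([1.0]), _model([5.0])]
    assert select_ensemble(models) is models[1]
    assert select_ensemble([models[0]]) is models[0]
    tied = [_model([1.0]), _model([1.0])]
    assert select_ensemble(tied) is tied[0]
    with pytest.raises(ValidationError):
        select_ensemble([])


def test_ensembled_scores_reduce_variance_and_degenerate_case():
    rng = np.random.default_rng(12)
    n_p, n_r = 40, 51
    base = np.exp(rng.normal(0, 1, size=(n_p, 1)))
    noisy = base * np.exp(rng.normal(0, 0.5, size=(n_p, n_r)))
    noisy[:, 0] = base[:, 0]
    fr = FeatureRealizations(patient_ids=[f"p{i}" for i in range(n_p)], values={"f0": noisy})
    model = _model([1.0])
    mean_scores, labels = ensembled_scores(model, fr, n_sim=100, seed=3)
    orig_scores = model.scores(pd.DataFrame({"f0": base[:, 0]}, index=fr.patient_ids))
    single = model.scores(sample_realization(fr, np.random.default_rng(0)))
    assert np.var(mean_scores - orig_scores) < np.var(single - orig_scores)
    # zero intra-patient noise: averaged score equals the single-realization score
    flat = FeatureRealizations(
        patient_ids=fr.patient_ids, values={"f0": np.repeat(base, 3, axis=1)}
    )
    mean_flat, _ = ensembled_scores(model, flat, n_sim=10, seed=0)
    np.testing.assert_allclose(mean_flat.to_numpy(), orig_scores.to_numpy())
    # determinism
    again, _ = ensembled_scores(model, fr, n_sim=100, seed=3)
    pd.testing.assert_series_equal(mean_scores, again)


def test_patient_agreement_extremes():
    model = _model([1.0])
    # scores are z-scores of log(value); threshold 0 <-> value 1.0
    far = FeatureRealizations(
        patient_ids=["far"], values={"f0": np.full((1, 301), 100.0)}
    )
    assert patient_agreement(model, far, "far").delta == 1.0
    straddle_vals = np.concatenate([np.full(150, np.exp(1.0)), np.full(151, np.exp(-1.0))])
    straddle = FeatureRealizations(
        patient_ids=["s"], values={"f0": straddle_vals[None, :]}
    )
    rec = patient_agreement(model, straddle, "s")
    assert rec.delta == pytest.approx(1 / 301)
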
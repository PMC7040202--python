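import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from ctradiomics.errors import FittingError, ValidationError
from ctradiomics.survival import (
    SignatureModel,
    clinical_and_combined_models,
    compare_baseline,
    fit_signature,
    grho_logrank,
    harrell_cindex,
    hazard_ratio_table,
    km_estimate,
    published_signature,
    stratify,
    td_auc,
)


def exp_cohort(n, seed, beta_lp=1.0, censor=(30.0, 1095.0)):
    """Exponential PFS driven by a standard-normal linear predictor."""
    rng = np.random.default_rng(seed)
    lp = rng.normal(size=n)
    lam = np.log(2) / 248.0
    t = rng.exponential(1.0 / (lam * np.exp(beta_lp * lp)))
    c = rng.uniform(*censor, size=n)
    return lp, np.minimum(t, c), (t <= c).astype(int)


# ---------------------------------------------------------------------------
# published signature


def test_published_signature_printed_coefficients():
    assert published_signature(1, 0) == pytest.approx(0.312)
    assert published_signature(0, 1) == pytest.approx(0.602)
    assert published_signature(0, 0) == 0.0
    assert published_signature(2.0, -1.0) == pytest.approx(2 * 0.312 - 0.602)


# ---------------------------------------------------------------------------
# signature fitting and stratification


def test_fit_signature_recovers_unit_coefficient():
    lp, t, e = exp_cohort(800, seed=1)
    feats = pd.DataFrame({"score": lp})
    model = fit_signature(feats, t, e)
    est = model.coefs[0]
    se = model.summary.loc["score", "se(coef)"]
    assert abs(est - 1.0) < 2 * se


def test_fit_signature_rejects_constant_feature():
    _, t, e = exp_cohort(50, seed=2)
    feats = pd.DataFrame({"flat": np.ones(50)})
    with pytest.raises(FittingError):
        fit_signature(feats, t, e)


def test_fit_signature_order_invariance():
    lp, t, e = exp_cohort(120, seed=3)
    feats = pd.DataFrame({"a": lp, "b": lp**2 * 0.1})
    model = fit_signature(feats, t, e)
    perm = np.random.default_rng(0).permutation(120)
    model_p = fit_signature(feats.iloc[perm].reset_index(drop=True), t[perm], e[perm])
    np.testing.assert_allclose(model.coefs, model_p.coefs, rtol=1e-6)


def test_stratify_median_split_and_tie_rule():
    model = SignatureModel(feature_names=["s"], coefs=np.array([1.0]), cutoff=0.5)
    scores = np.array([0.2, 0.5, 0.7, 0.9])
    labels = stratify(model, scores)
    assert list(labels) == ["low", "low", "high", "high"]  # tie goes low
    assert list(stratify(model, np.array([-1.0, 0.0]))) == ["low", "low"]


def test_validation_uses_training_cutoff():
    lp, t, e = exp_cohort(100, seed=4)
    model = fit_signature(pd.DataFrame({"s": lp}), t, e)
    val_scores = model.score(pd.DataFrame({"s": lp + 10.0}))  # sentinel shift
    assert set(stratify(model, val_scores)) == {"high"}  # cutoff unchanged


# ---------------------------------------------------------------------------
# KM


def test_km_hand_product_limit():
    km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    s_at = dict(zip(km["time"], km["survival"]))
    assert s_at[2.0] == pytest.approx(0.5)
    assert km["median"] == pytest.approx(2.0)


def test_km_all_censored():
    km = km_estimate([5.0, 10.0, 20.0], [0, 0, 0])
    assert np.all(np.asarray(km["survival"]) == 1.0)
    assert not km["median_defined"]


def test_km_median_large_exponential_sample():
    rng = np.random.default_rng(5)
    t = rng.exponential(248.0 / np.log(2), size=4000)
    km = km_estimate(t, np.ones_like(t, dtype=int))
    assert abs(km["median"] - 248.0) / 248.0 < 0.10


# ---------------------------------------------------------------------------
# G-rho log-rank


def test_grho_rho_zero_matches_independent_logrank_oracle():
    rng = np.random.default_rng(6)
    t = rng.exponential(200.0, size=20)
    e = (rng.random(20) < 0.8).astype(int)
    g = np.array(["a"] * 10 + ["b"] * 10)
    chi, p = grho_logrank(t, e, g, rho=0.0)
    ref = logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
    assert chi == pytest.approx(ref.test_statistic, abs=1e-8)
    assert p == pytest.approx(ref.p_value, abs=1e-8)


def test_grho_identical_groups_gives_zero_statistic():
    t = np.array([3.0, 5.0, 8.0, 13.0] * 2)
    e = np.array([1, 0, 1, 1] * 2)
    g = np.array(["a"] * 4 + ["b"] * 4)  # duplicated survival experience
    chi, p = grho_logrank(t, e, g, rho=1.0)
    assert chi == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_grho_requires_two_groups():
    with pytest.raises(ValidationError):
        grho_logrank([1.0, 2.0], [1, 1], ["a", "a"])


def test_grho_matches_r_survdiff_fixture():
    """Fixed 12-patient fixture checked against survival::survdiff
    (rho = 1): chi-square 0.4105307617, and rho = 0: 0.5181760300."""
    t = np.array([10, 50, 80, 120, 160, 200, 30, 70, 140, 210, 260, 300], float)
    e = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
    g = np.array(["a"] * 6 + ["b"] * 6)
    chi1, _ = grho_logrank(t, e, g, rho=1.0)
    chi0, _ = grho_logrank(t, e, g, rho=0.0)
    assert chi1 == pytest.approx(0.4105307617, abs=1e-6)
    assert chi0 == pytest.approx(0.5181760300, abs=1e-6)


# ---------------------------------------------------------------------------
# C-index


def test_cindex_hand_enumerated_fixture():
    # times 1..4, all events; scores concordant except the (3, 4) pair
    est, _, _ = harrell_cindex([4.0, 3.0, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ci=False)
    assert est == pytest.approx(5.0 / 6.0)


def test_cindex_perfect_ranking():
    t = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
    est, _, _ = harrell_cindex(-t, t, np.ones(5, dtype=int), ci=False)
    assert est == 1.0


def test_cindex_monotone_transform_invariance():
    lp, t, e = exp_cohort(150, seed=7)
    a, _, _ = harrell_cindex(lp, t, e, ci=False)
    b, _, _ = harrell_cindex(np.exp(3.0 * lp) + 5.0, t, e, ci=False)
    assert a == pytest.approx(b)


def test_cindex_bootstrap_ci_brackets_estimate():
    lp, t, e = exp_cohort(120, seed=8)
    est, lo, hi = harrell_cindex(lp, t, e, n_boot=200, seed=0)
    assert lo <= est <= hi
    assert 0.5 < est < 1.0


# ---------------------------------------------------------------------------
# time-dependent AUC


def test_td_auc_perfect_score():
    t = np.array([30.0, 60.0, 90.0, 400.0, 500.0, 600.0])
    e = np.ones(6, dtype=int)
    scores = -t  # higher risk = earlier event
    assert td_auc(scores, t, e, horizon=183.0) == pytest.approx(1.0)


def test_td_auc_error_without_cases():
    t = np.array([400.0, 500.0])
    with pytest.raises(ValidationError, match="183"):
        td_auc([1.0, 2.0], t, [1, 1], horizon=183.0)


# ---------------------------------------------------------------------------
# HR table


def test_hr_recovery_for_true_linear_predictor():
    lp, t, e = exp_cohort(800, seed=9)
    table = hazard_ratio_table(pd.DataFrame({"lp": lp}), t, e)
    row = table.loc["lp"]
    assert row["ci_low"] < np.e < row["ci_high"]
    assert row["lrt_p"] < 1e-6


def test_hr_binary_factor_identical_survival_covers_one():
    t = np.array([3.0, 5.0, 8.0, 13.0, 21.0] * 2)
    e = np.array([1, 1, 0, 1, 1] * 2)
    fac = pd.DataFrame({"grp": [0.0] * 5 + [1.0] * 5})
    row = hazard_ratio_table(fac, t, e).loc["grp"]
    assert row["ci_low"] <= 1.0 <= row["ci_high"]


def test_hr_null_factor_pvalues_are_uniform():
    rng = np.random.default_rng(10)
    pvals = []
    for rep in range(150):
        lp, t, e = exp_cohort(60, seed=2000 + rep, beta_lp=0.0)
        noise = rng.normal(size=60)
        pvals.append(
            hazard_ratio_table(pd.DataFrame({"x": noise}), t, e).loc["x", "lrt_p"]
        )
    frac = np.mean(np.asarray(pvals) < 0.05)
    band = 1.96 * np.sqrt(0.05 * 0.95 / 150)
    assert 0.05 - band <= frac <= 0.05 + band


# ---------------------------------------------------------------------------
# clinical vs combined models


def clinical_frame(n, t, e, rng, age_effect=False):
    age = rng.normal(55, 10, size=n)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age_years": age,
            "smoking": rng.choice(["smoker", "nonsmoker"], size=n),
            "pfs_days": t,
            "event": e,
            "cohort_label": "c",
        }
    )
    return df


def test_texture_only_survival_keeps_combined_close_to_signature():
    rng = np.random.default_rng(11)
    lp, t, e = exp_cohort(300, seed=12)
    tr, va = np.arange(150), np.arange(150, 300)
    ctr = clinical_frame(150, t[tr], e[tr], rng)
    cva = clinical_frame(150, t[va], e[va], rng)
    out = clinical_and_combined_models(ctr, lp[tr], cva, lp[va])
    assert (
        out["combined_model"]["cindex_validation"]
        <= out["signature_cindex_validation"] + 0.05
    )


def test_age_only_survival_favors_clinical_model():
    rng = np.random.default_rng(13)
    n = 300
    age = rng.normal(55, 10, size=n)
    lam = np.log(2) / 248.0
    lp = 1.2 * (age - age.mean()) / age.std()
    t_ev = rng.exponential(1.0 / (lam * np.exp(lp)))
    c = rng.uniform(30, 1095, size=n)
    t, e = np.minimum(t_ev, c), (t_ev <= c).astype(int)
    noise_sig = rng.normal(size=n)  # signature unrelated to survival
    tr, va = np.arange(150), np.arange(150, 300)
    ctr = clinical_frame(150, t[tr], e[tr], rng)
    ctr["age_years"] = age[tr]
    cva = clinical_frame(150, t[va], e[va], rng)
    cva["age_years"] = age[va]
    out = clinical_and_combined_models(ctr, noise_sig[tr], cva, noise_sig[va])
    assert out["clinical_model"] is not None
    assert (
        out["clinical_model"]["cindex_validation"]
        > out["signature_cindex_validation"]
    )


# ---------------------------------------------------------------------------
# baseline comparison


def test_identical_proportions_give_p_one():
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(8)],
            "sex": ["male", "female"] * 4,
            "age_years": [50.0, 60.0] * 4,
            "smoking": ["smoker", "nonsmoker"] * 4,
            "pfs_days": [100.0] * 8,
            "event": [1] * 8,
            "cohort_label": ["a"] * 4 + ["b"] * 4,
        }
    )
    out = compare_baseline(df, characteristics=["sex", "smoking"])
    assert out.loc["sex", "chi2"] == pytest.approx(0.0)
    assert out.loc["sex", "p"] == pytest.approx(1.0)


def test_chi_square_matches_hand_oracle_on_printed_sex_counts():
    # 2x2 table: training 16 male / 16 female, validation 17 male / 14 female
    rows = []
    for cohort, males, females in (("train", 16, 16), ("val", 17, 14)):
        rows += [{"cohort_label": cohort, "sex": "male"}] * males
        rows += [{"cohort_label": cohort, "sex": "female"}] * females
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"p{i}" for i in range(len(df))]
    df["age_years"], df["smoking"] = 50.0, "nonsmoker"
    df["pfs_days"], df["event"] = 100.0, 1
    out = compare_baseline(df, characteristics=["sex"])
    # direct Pearson chi-square formula on the 2x2 counts
    obs = np.array([[16, 16], [17, 14]], float)
    row_tot = obs.sum(1, keepdims=True)
    col_tot = obs.sum(0, keepdims=True)
    exp = row_tot @ col_tot / obs.sum()
    chi_oracle = ((obs - exp) ** 2 / exp).sum()
    assert out.loc["sex", "chi2"] == pytest.approx(chi_oracle, rel=1e-12)


def test_baseline_chi_square_calibration():
    rng = np.random.default_rng(14)
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        sex = rng.choice(["male", "female"], size=60)
        lab = np.array(["a"] * 30 + ["b"] * 30)
        df = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(60)],
                "sex": sex,
                "age_years": 50.0,
                "smoking": "nonsmoker",
                "pfs_days": 100.0,
                "event": 1,
                "cohort_label": lab,
            }
        )
        hits += compare_baseline(df, characteristics=["sex"]).loc["sex", "p"] < 0.05
    band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(hits / n_rep - 0.05) <= band + 0.01  # chi-square is discrete at n=60
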
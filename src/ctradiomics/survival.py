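"""Radiomic-signature construction and survival evaluation.

The signature is the linear predictor of an unpenalized multivariate Cox
model over the selected features; patients are dichotomized at the
training-median score (ties to the low group), higher score meaning higher
hazard.  Evaluation covers Kaplan-Meier stratification with the
Harrington-Fleming G-rho weighted log-rank test (rho = 1, the Peto-Peto
weighting), Harrell's C-index with a percentile-bootstrap CI, IPCW
time-dependent AUC at a fixed horizon (default 183 days = 6 months), and
per-factor hazard-ratio tables with likelihood-ratio p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .errors import FittingError, ValidationError

DEFAULT_HORIZON_DAYS = 183.0  # "6 months"
PUBLISHED_COEF_MIN_CLUSTERSHADE = 0.312
PUBLISHED_COEF_SRHGLE = 0.602


# ---------------------------------------------------------------------------
# signature


@dataclass
class SignatureModel:
    """Cox coefficients plus the training-median dichotomization cutoff."""

    feature_names: list[str]
    coefs: np.ndarray
    cutoff: float
    summary: pd.DataFrame | None = field(default=None, repr=False)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor beta . x (higher = higher hazard)."""
        return features[self.feature_names].to_numpy(dtype=float) @ self.coefs

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "coefs": self.coefs.tolist(),
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            feature_names=list(d["feature_names"]),
            coefs=np.asarray(d["coefs"], dtype=float),
            cutoff=float(d["cutoff"]),
        )


def _cox_fit(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[covariates + ["pfs_days", "event"]],
            duration_col="pfs_days",
            event_col="event",
        )
    except ConvergenceError as exc:
        raise FittingError(f"Cox fit did not converge: {exc}") from exc
    return cph


def fit_signature(
    features: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> SignatureModel:
    """Multivariate unpenalized Cox fit on the selected features."""
    if features.shape[1] == 0:
        raise FittingError("no features to fit a signature on")
    const = [c for c in features.columns if features[c].nunique() <= 1]
    if const:
        raise FittingError(f"constant features cannot enter the signature: {const}")
    if np.asarray(event).sum() == 0:
        raise FittingError("cannot fit a signature with no observed events")
    df = features.copy()
    df["pfs_days"] = np.asarray(time, dtype=float)
    df["event"] = np.asarray(event, dtype=int)
    cph = _cox_fit(df, list(features.columns))
    coefs = cph.params_[list(features.columns)].to_numpy()
    model = SignatureModel(
        feature_names=list(features.columns),
        coefs=coefs,
        cutoff=0.0,
        summary=cph.summary,
    )
    model.cutoff = float(np.median(model.score(features)))
    return model


def published_signature(min_times_clustershade, srhgle):
    """The published fixed scoring rule.

    score = 0.312 x (first-order minimum x cluster shade) + 0.602 x SRHGLE,
    with both inputs on the normalized training scale.
    """
    return (
        PUBLISHED_COEF_MIN_CLUSTERSHADE * np.asarray(min_times_clustershade, dtype=float)
        + PUBLISHED_COEF_SRHGLE * np.asarray(srhgle, dtype=float)
    )


def stratify(model: SignatureModel, scores: np.ndarray) -> np.ndarray:
    """Dichotomize at the training-median cutoff; ties go to 'low'."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > model.cutoff, "high", "low")


# ---------------------------------------------------------------------------
# estimators and tests


def km_estimate(time, event) -> dict:
    """Product-limit survival curve with at-risk counts and median."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValidationError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(time >= t).sum() for t in grid])
    median = kmf.median_survival_time_
    defined = np.isfinite(median)
    return {
        "time": grid,
        "survival": surv,
        "at_risk": at_risk,
        "median": float(median) if defined else None,
        "median_defined": bool(defined),
    }


def grho_logrank(time, event, group, rho: float = 1.0) -> tuple[float, float]:
    """Harrington-Fleming G-rho weighted two-sample log-rank test.

    Weights are S(t-)^rho with S the left-continuous pooled Kaplan-Meier
    estimate; rho = 0 is the standard log-rank, rho = 1 the Peto-Peto test.
    Returns (chi-square statistic, p-value on 1 df).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(labels)}")
    g1 = group == labels[0]

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    event_times = np.unique(time[event == 1])
    u = 0.0
    var = 0.0
    s_left = 1.0  # pooled KM just before the current event time
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        w = s_left**rho
        e1 = d * n1 / n
        u += w * (d1 - e1)
        if n > 1:
            var += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        s_left *= 1.0 - d / n
    if var == 0:
        return 0.0, 1.0
    chi = u**2 / var
    return float(chi), float(stats.chi2.sf(chi, 1))


def harrell_cindex(
    scores,
    time,
    event,
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = True,
) -> tuple[float, float, float]:
    """Harrell's concordance of a risk score (higher = earlier event).

    Returns (estimate, ci_low, ci_high); the CI is a seeded percentile
    bootstrap over patients.  With ``ci=False`` the bounds are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event, dtype=int).astype(bool)
    if ev.sum() == 0:
        raise ValidationError("no comparable pairs: no observed events")
    est = float(concordance_index_censored(ev, time, scores)[0])
    if not ci:
        return est, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    n = len(scores)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if ev[idx].sum() == 0:
            continue
        try:
            reps.append(concordance_index_censored(ev[idx], time[idx], scores[idx])[0])
        except Exception:
            continue
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return est, float(lo), float(hi)


def td_auc(scores, time, event, horizon: float = DEFAULT_HORIZON_DAYS) -> float:
    """IPCW cumulative/dynamic AUC at ``horizon``.

    Cases = event by the horizon; controls = event-free past it; censoring
    distribution estimated by Kaplan-Meier on the same records.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event, dtype=int).astype(bool)
    cases = ev & (time <= horizon)
    controls = time > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValidationError(
            f"time-dependent AUC undefined at horizon {horizon}: "
            f"{int(cases.sum())} cases, {int(controls.sum())} controls"
        )
    y = Surv.from_arrays(event=ev, time=time)
    auc, _ = cumulative_dynamic_auc(y, y, scores, [horizon])
    return float(auc[0])


def hazard_ratio_table(factors: pd.DataFrame, time, event) -> pd.DataFrame:
    """Univariate Cox per factor: HR, 95% CI and likelihood-ratio p.

    Continuous factors give HR per unit; binary factors must be 0/1 coded.
    Non-convergent factors are flagged (NaN row) without aborting the table.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    for col in factors.columns:
        df = pd.DataFrame(
            {col: factors[col].to_numpy(dtype=float), "pfs_days": time, "event": event}
        )
        try:
            cph = _cox_fit(df, [col])
            s = cph.summary.loc[col]
            lrt = cph.log_likelihood_ratio_test()
            rows.append(
                {
                    "factor": col,
                    "hr": float(s["exp(coef)"]),
                    "ci_low": float(s["exp(coef) lower 95%"]),
                    "ci_high": float(s["exp(coef) upper 95%"]),
                    "lrt_p": float(lrt.p_value),
                    "converged": True,
                }
            )
        except (FittingError, Exception):
            rows.append(
                {
                    "factor": col,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "lrt_p": np.nan,
                    "converged": False,
                }
            )
    return pd.DataFrame(rows).set_index("factor")


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of the clinical covariates for Cox models."""
    return pd.DataFrame(
        {
            "age_years": clinical["age_years"].to_numpy(dtype=float),
            "sex_male": (clinical["sex"] == "male").astype(float).to_numpy(),
            "smoker": (clinical["smoking"] == "smoker").astype(float).to_numpy(),
        },
        index=clinical.index,
    )


def clinical_and_combined_models(
    clinical_train: pd.DataFrame,
    scores_train: np.ndarray,
    clinical_val: pd.DataFrame,
    scores_val: np.ndarray,
    screen_p: float = 0.05,
) -> dict:
    """Clinical model (training-significant covariates) and combined model.

    Covariates pass a univariate Cox screen at ``screen_p`` on the training
    cohort; the combined model adds the signature score.  Returns the fitted
    coefficient tables and train/validation C-indices of both models.
    """
    enc_tr = encode_clinical(clinical_train)
    enc_va = encode_clinical(clinical_val)
    t_tr = clinical_train["pfs_days"].to_numpy(dtype=float)
    e_tr = clinical_train["event"].to_numpy(dtype=int)
    t_va = clinical_val["pfs_days"].to_numpy(dtype=float)
    e_va = clinical_val["event"].to_numpy(dtype=int)

    screen = hazard_ratio_table(enc_tr, t_tr, e_tr)
    selected = [c for c in enc_tr.columns if screen.loc[c, "lrt_p"] < screen_p]

    out: dict = {"screen": screen, "clinical_covariates": selected}

    def _eval(covs: pd.DataFrame, covs_val: pd.DataFrame, names: list[str]):
        df = covs[names].copy()
        df["pfs_days"], df["event"] = t_tr, e_tr
        cph = _cox_fit(df, names)
        beta = cph.params_[names].to_numpy()
        sc_tr = covs[names].to_numpy(dtype=float) @ beta
        sc_va = covs_val[names].to_numpy(dtype=float) @ beta
        return {
            "coefs": dict(zip(names, beta.tolist())),
            "cindex_train": harrell_cindex(sc_tr, t_tr, e_tr, ci=False)[0],
            "cindex_validation": harrell_cindex(sc_va, t_va, e_va, ci=False)[0],
        }

    if selected:
        out["clinical_model"] = _eval(enc_tr, enc_va, selected)
    else:
        out["clinical_model"] = None  # degenerate: nothing passed the screen

    comb_tr = enc_tr.copy()
    comb_tr["signature"] = np.asarray(scores_train, dtype=float)
    comb_va = enc_va.copy()
    comb_va["signature"] = np.asarray(scores_val, dtype=float)
    out["combined_model"] = _eval(comb_tr, comb_va, selected + ["signature"])
    out["signature_cindex_train"] = harrell_cindex(scores_train, t_tr, e_tr, ci=False)[0]
    out["signature_cindex_validation"] = harrell_cindex(scores_val, t_va, e_va, ci=False)[0]
    return out


def compare_baseline(clinical: pd.DataFrame, characteristics=None) -> pd.DataFrame:
    """Chi-square comparison of baseline characteristics between cohorts.

    Continuity correction is not applied (plain Pearson chi-square on the
    2 x k contingency table); age is dichotomized at the pooled median.
    Characteristics with an all-zero expected cell are flagged.
    """
    labels = clinical["cohort_label"].unique()
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 cohorts, got {list(labels)}")
    df = clinical.copy()
    df["age_group"] = np.where(
        df["age_years"] > df["age_years"].median(), "older", "younger"
    )
    characteristics = characteristics or ["sex", "age_group", "smoking"]
    rows = []
    for ch in characteristics:
        tab = pd.crosstab(df["cohort_label"], df[ch])
        if tab.shape[1] < 2:
            rows.append({"characteristic": ch, "chi2": 0.0, "p": 1.0, "flagged": True})
            continue
        chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append(
            {
                "characteristic": ch,
                "chi2": float(chi2),
                "p": float(p),
                "flagged": bool((expected == 0).any()),
            }
        )
    return pd.DataFrame(rows).set_index("characteristic")


def evaluate_signature(
    model: SignatureModel,
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    horizon: float = DEFAULT_HORIZON_DAYS,
    n_boot: int = 2000,
    seed: int = 0,
    rho: float = 1.0,
) -> dict:
    """Full per-cohort evaluation report for a fitted signature."""
    scores = model.score(features)
    time = clinical["pfs_days"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    groups = stratify(model, scores)
    cindex, ci_lo, ci_hi = harrell_cindex(scores, time, event, n_boot=n_boot, seed=seed)
    chi, p = grho_logrank(time, event, groups, rho=rho)
    report = {
        "n": int(len(clinical)),
        "n_events": int(event.sum()),
        "cindex": cindex,
        "cindex_ci": [ci_lo, ci_hi],
        "logrank_chi2": chi,
        "logrank_p": p,
        "auc_horizon_days": horizon,
        "km": {},
        "median_pfs": {},
    }
    try:
        report["auc"] = td_auc(scores, time, event, horizon=horizon)
    except ValidationError as exc:
        report["auc"] = None
        report["auc_note"] = str(exc)
    for lab in ("high", "low"):
        sel = groups == lab
        if sel.sum() == 0:
            continue
        km = km_estimate(time[sel], event[sel])
        report["km"][lab] = {
            "time": km["time"].tolist(),
            "survival": km["survival"].tolist(),
            "at_risk": km["at_risk"].tolist(),
        }
        report["median_pfs"][lab] = km["median"]
    return report
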
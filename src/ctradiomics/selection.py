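"""Feature discovery: normalization, Pearson redundancy pruning,
cross-validated LASSO-Cox, events-per-variable check and split-stability.

The discovery chain mirrors a standard radiomics protocol: features are
z-scored with training-cohort statistics only, redundant features (|r| >
0.8) are pruned deterministically, and an L1-penalized Cox model selects a
sparse set along a log-spaced penalty path, with the penalty chosen to
minimise the 10-fold cross-validated partial-likelihood deviance
(Verweij-van Houwelingen).  Folds and cohort splits are stratified by event
status and fully seeded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .errors import FittingError, ValidationError

logger = logging.getLogger(__name__)

PEARSON_THRESHOLD = 0.8


@dataclass
class NormalizationState:
    """Training-cohort feature means/SDs (sample SD, ddof=1)."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (table[cols] - self.mean) / self.sd


def zscore_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[list[pd.DataFrame], NormalizationState]:
    """Z-score features with training statistics; transform other cohorts
    with the same state (no leakage).  Zero-variance training columns are
    dropped with a logged warning."""
    if train.empty:
        raise ValidationError("training feature table is empty")
    mean = train.mean()
    sd = train.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("dropped %d zero-variance features: %s", len(dropped), dropped[:5])
    keep = sd.index.difference(dropped, sort=False)
    state = NormalizationState(mean=mean[keep], sd=sd[keep], dropped=dropped)
    return [state.apply(t) for t in (train, *others)], state


def pearson_filter(
    table: pd.DataFrame, threshold: float = PEARSON_THRESHOLD
) -> list[str]:
    """Prune features until no surviving pair has |r| > threshold.

    Deterministic removal order: iteratively drop the feature with the most
    |r| > threshold partners; ties broken by larger mean |r| against the
    current survivors, then by later registry (column) order.
    """
    if table.shape[1] < 2:
        return list(table.columns)
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    constant = [c for c, s in zip(cols, sd) if s == 0 or not np.isfinite(s)]
    keep_idx = [i for i, c in enumerate(cols) if c not in constant]
    if len(keep_idx) < 2:
        return [cols[i] for i in keep_idx]

    corr = np.corrcoef(x[:, keep_idx], rowvar=False)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr, 0.0)
    names = [cols[i] for i in keep_idx]
    order = {c: i for i, c in enumerate(cols)}

    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        over = sub > threshold
        degree = over.sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        alive_idx = np.flatnonzero(alive)
        mean_r = sub.mean(axis=1)
        # worst offender: max degree, then max mean |r|, then latest registry order
        key = list(
            zip(degree, mean_r, [order[names[i]] for i in alive_idx])
        )
        drop_local = max(range(len(key)), key=lambda i: key[i])
        alive[alive_idx[drop_local]] = False
    return [names[i] for i in np.flatnonzero(alive)]


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) — used for CV deviance


def cox_partial_loglik(
    x: np.ndarray, beta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of ``beta`` on (x, time, event)."""
    eta = x @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o = eta[order]
    t_o = time[order]
    e_o = event[order].astype(bool)
    log_cumsum = np.logaddexp.accumulate(eta_o)
    # ties: the risk set at t includes everyone with time >= t
    # map each position to the last position with the same time
    last_same = np.arange(len(t_o))
    for i in range(len(t_o) - 2, -1, -1):
        if t_o[i] == t_o[i + 1]:
            last_same[i] = last_same[i + 1]
    ll = float(np.sum(eta_o[e_o] - log_cumsum[last_same[e_o]]))
    return ll


@dataclass
class SelectionResult:
    """Output of the CV LASSO-Cox stage."""

    surviving: list[str]  # features that entered the LASSO (post-Pearson)
    alphas: np.ndarray  # penalty grid, decreasing
    coef_path: np.ndarray  # (n_features, n_alphas)
    chosen_alpha: float
    nonzero: dict[str, float]  # feature -> coefficient at chosen alpha
    cv_mean: np.ndarray  # mean CV deviance per alpha
    cv_sd: np.ndarray  # fold dispersion per alpha
    seed: int = 0

    def entry_order(self) -> list[str]:
        """Features ordered by the penalty at which they first enter the path."""
        first = {}
        for i, name in enumerate(self.surviving):
            nz = np.flatnonzero(self.coef_path[i] != 0)
            first[name] = nz[0] if len(nz) else np.inf
        return sorted(self.surviving, key=lambda c: (first[c], self.surviving.index(c)))

    def to_dict(self) -> dict:
        return {
            "surviving": self.surviving,
            "entry_order": self.entry_order(),
            "alphas": self.alphas.tolist(),
            "chosen_alpha": self.chosen_alpha,
            "nonzero": self.nonzero,
            "cv_mean": self.cv_mean.tolist(),
            "cv_sd": self.cv_sd.tolist(),
            "seed": self.seed,
        }


def lasso_cox_cv(
    table: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    alphas: np.ndarray | None = None,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> SelectionResult:
    """L1-penalized Cox over a log-spaced penalty grid with seeded,
    event-stratified K-fold choice of the penalty.

    The chosen penalty minimises the mean Verweij-van Houwelingen deviance
    ``-2 * (ll_all(beta_k) - ll_train_k(beta_k))`` across folds.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise FittingError("cannot fit a Cox model with no observed events")
    x = table.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def _fit(xs, ys, alpha_grid):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=None if alpha_grid is None else list(alpha_grid),
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xs, ys)
        return model

    full = _fit(x, y, alphas)
    grid = np.asarray(full.alphas_, dtype=float)
    coef_path = np.asarray(full.coef_)  # (n_features, n_alphas)

    # event-stratified folds when both classes are large enough, plain
    # shuffled folds otherwise (stratification is impossible when the rarer
    # class has fewer members than folds)
    folds_eff = max(2, min(folds, len(event) // 2))
    min_class = min(int(event.sum()), int((event == 0).sum()))
    if min_class >= folds_eff:
        splitter = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
        fold_iter = splitter.split(x, event)
    else:
        splitter = KFold(n_splits=folds_eff, shuffle=True, random_state=seed)
        fold_iter = splitter.split(x)
    dev = np.full((folds_eff, len(grid)), np.nan)
    for k, (tr, _te) in enumerate(fold_iter):
        fold_model = _fit(x[tr], y[tr], grid)
        fold_coefs = np.asarray(fold_model.coef_)
        fold_alphas = np.asarray(fold_model.alphas_, dtype=float)
        for j, a in enumerate(grid):
            jj = int(np.argmin(np.abs(fold_alphas - a)))
            b = fold_coefs[:, jj]
            ll_all = cox_partial_loglik(x, b, time, event)
            ll_tr = cox_partial_loglik(x[tr], b, time[tr], event[tr])
            dev[k, j] = -2.0 * (ll_all - ll_tr)
    cv_mean = np.nanmean(dev, axis=0)
    cv_sd = np.nanstd(dev, axis=0, ddof=1)
    best = int(np.nanargmin(cv_mean))
    chosen = float(grid[best])
    coefs = coef_path[:, best]
    nonzero = {
        c: float(b) for c, b in zip(table.columns, coefs) if b != 0.0
    }
    return SelectionResult(
        surviving=list(table.columns),
        alphas=grid,
        coef_path=coef_path,
        chosen_alpha=chosen,
        nonzero=nonzero,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        seed=seed,
    )


def epv_check(n_selected: int, n_events: int) -> tuple[bool, str]:
    """Events-per-variable rule: warn when selected features >= events/10.

    Returns ``(ok, message)``; the pipeline logs the warning but proceeds.
    """
    if n_selected < 0 or n_events < 0:
        raise ValidationError("counts must be non-negative")
    if n_events == 0 or n_selected >= n_events / 10.0:
        msg = (
            f"epv_check warn n_selected={n_selected} n_events={n_events} "
            f"limit={n_events / 10.0:.1f}"
        )
        logger.warning(msg)
        return False, msg
    return True, f"epv_check pass n_selected={n_selected} n_events={n_events}"


def select_features(
    table: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    pearson_threshold: float = PEARSON_THRESHOLD,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Pearson pruning followed by CV LASSO-Cox (the paper-order chain)."""
    surviving = pearson_filter(table, threshold=pearson_threshold)
    result = lasso_cox_cv(table[surviving], time, event, folds=folds, seed=seed)
    epv_check(len(result.nonzero), int(np.asarray(event).sum()))
    return result


def stability_analysis(
    table: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_splits: int = 10,
    seed: int = 0,
    pearson_threshold: float = PEARSON_THRESHOLD,
    folds: int = 10,
) -> pd.Series:
    """Selection frequency of every feature over repeated random 1:1
    event-stratified cohort splits, running the full discovery chain on the
    training half of each split."""
    if len(table) < 4:
        raise ValidationError("stability analysis needs at least 4 patients")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    counts = pd.Series(0, index=table.columns, dtype=int)
    for s in range(n_splits):
        idx_tr, _ = train_test_split(
            np.arange(len(table)),
            test_size=0.5,
            stratify=event,
            random_state=seed + s,
        )
        sub = table.iloc[idx_tr]
        (sub_n,), _ = zscore_fit_apply(sub)
        res = select_features(
            sub_n,
            time[idx_tr],
            event[idx_tr],
            pearson_threshold=pearson_threshold,
            folds=folds,
            seed=seed + s,
        )
        for name in res.nonzero:
            counts[name] += 1
    return counts / n_splits
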
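"""Penalized Cox risk models, linear risk scores, and median-split
Kaplan-Meier / log-rank analysis.

The risk score of a sample is the plain linear combination
``sum_i coefficient_i * expression_i`` of the model's selected features; the
training-set median of that score is the cutoff separating high- from
low-risk groups (ties at the median go to the low group).

The L1-penalized Cox fit minimizes -(2/n) Breslow partial log-likelihood
+ lambda * ||beta||_1 along a log-spaced lambda path (glmnet-style coordinate
descent via scikit-survival's Coxnet), with lambda chosen by K-fold
cross-validated partial-likelihood deviance (minimum rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


@dataclass
class RiskModel:
    features: list[str]
    coefficients: dict[str, float]
    lam: float
    median_cutoff: float
    cv_deviance: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class KMResult:
    curves: dict  # group label -> DataFrame(timeline, survival, at_risk)
    group_sizes: dict
    logrank_chi2: float | None
    logrank_p: float | None


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Breslow partial log-likelihood (ties share the full risk set)."""
    eta = X @ beta
    order = np.argsort(time)
    t, e, lp = time[order], event[order], eta[order]
    ll = 0.0
    # iterate distinct event times; risk set = all with time >= t_k
    for tk in np.unique(t[e == 1]):
        at = t >= tk
        d = (t == tk) & (e == 1)
        ll += lp[d].sum() - d.sum() * np.log(np.exp(lp[at]).sum())
    return float(ll)


def _as_surv(time, event):
    return Surv.from_arrays(event=np.asarray(event, bool), time=np.asarray(time, float))


def lasso_cox_fit(
    X: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 50,
) -> RiskModel:
    """L1-penalized Cox fit with cross-validated lambda.

    ``X`` is samples x features.  Features are standardized inside the solver;
    coefficients are reported on the original scale.  Raises on all-censored
    data.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() == 0:
        raise ValueError("all samples censored: partial likelihood undefined")

    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    sd[sd == 0] = 1.0
    Z = (X.to_numpy(float) - mu) / sd
    y = _as_surv(time, event)

    if lambda_grid is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_lambdas,
                                      alpha_min_ratio=0.01)
        path.fit(Z, y)
        lambda_grid = np.asarray(path.alphas_)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    if len(lambda_grid) > 1:
        lam = _cv_choose_lambda(Z, time, event, lambda_grid, cv_folds, seed)
        cvdev = lam[1]
        lam = lam[0]
    else:
        lam, cvdev = float(lambda_grid[0]), None

    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], fit_baseline_model=False)
    model.fit(Z, y)
    beta_std = model.coef_[:, 0]
    beta = beta_std / sd

    feats = [f for f, b in zip(X.columns, beta) if b != 0.0]
    coefs = {f: float(b) for f, b in zip(X.columns, beta) if b != 0.0}
    scores = X[feats].to_numpy(float) @ np.array([coefs[f] for f in feats]) \
        if feats else np.zeros(len(X))
    return RiskModel(feats, coefs, float(lam), float(np.median(scores)), cvdev)


def _cv_choose_lambda(Z, time, event, lambda_grid, cv_folds, seed):
    """Verweij & van Houwelingen cross-validated partial-likelihood deviance."""
    rng = np.random.default_rng(seed)
    n = len(time)
    # fold assignment balanced over events so every fold sees events
    idx_e = rng.permutation(np.where(event == 1)[0])
    idx_c = rng.permutation(np.where(event == 0)[0])
    fold = np.empty(n, int)
    fold[idx_e] = np.arange(len(idx_e)) % cv_folds
    fold[idx_c] = np.arange(len(idx_c)) % cv_folds

    y = _as_surv(time, event)
    dev = np.zeros((cv_folds, len(lambda_grid)))
    for f in range(cv_folds):
        tr = fold != f
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(lambda_grid))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z[tr], y[tr])
        fitted = np.asarray(model.alphas_)
        for j, lam in enumerate(lambda_grid):
            jj = int(np.argmin(np.abs(fitted - lam)))
            beta = model.coef_[:, jj]
            ll_all = breslow_loglik(Z, time, event, beta)
            ll_tr = breslow_loglik(Z[tr], time[tr], event[tr], beta)
            dev[f, j] = -2.0 * (ll_all - ll_tr)
    mean_dev = dev.mean(axis=0)
    table = pd.DataFrame({"lambda": lambda_grid, "mean_deviance": mean_dev})
    return float(lambda_grid[int(np.argmin(mean_dev))]), table


def risk_score(model: RiskModel, X: pd.DataFrame) -> pd.Series:
    """Per-sample linear risk score, exactly sum_i coef_i * expression_i."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise KeyError(f"missing model features in expression data: {missing}")
    if not model.features:
        return pd.Series(np.zeros(len(X)), index=X.index)
    beta = np.array([model.coefficients[f] for f in model.features])
    return pd.Series(X[model.features].to_numpy(float) @ beta, index=X.index)


def median_split(scores: pd.Series, cutoff: float | None = None) -> pd.Series:
    """'high' where score > cutoff (default: median of ``scores``), else 'low'."""
    if cutoff is None:
        cutoff = float(np.median(scores))
    if np.ptp(scores.to_numpy(float)) == 0:
        raise ValueError("all risk scores equal: median split is degenerate")
    return pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)


def km_logrank(groups: pd.Series, time: pd.Series, event: pd.Series) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    With no events anywhere the curves are flat at 1 and the log-rank
    statistic is reported as missing.
    """
    time = pd.Series(np.asarray(time, float), index=groups.index)
    event = pd.Series(np.asarray(event, int), index=groups.index)
    curves, sizes = {}, {}
    for lab in sorted(groups.unique()):
        sel = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tbl = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "timeline": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(
                    kmf.survival_function_.index).to_numpy(),
            }
        )
        sizes[lab] = int(sel.sum())
    if event.sum() == 0 or groups.nunique() < 2:
        return KMResult(curves, sizes, None, None)
    labs = sorted(groups.unique())
    a, b = (groups == labs[0]), (groups == labs[1])
    res = logrank_test(time[a], time[b], event[a], event[b])
    return KMResult(curves, sizes, float(res.test_statistic), float(res.p_value))


def km_logrank_by_median(scores: pd.Series, time: pd.Series,
                         event: pd.Series, cutoff: float | None = None) -> KMResult:
    if len(scores) < 4:
        raise ValueError("need at least 4 samples")
    return km_logrank(median_split(scores, cutoff), time, event)
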
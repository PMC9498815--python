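"""Multivariate Cox model over risk groups and clinical covariates, nomogram
construction, and discrimination/calibration of the resulting prognosis.

The nomogram maps each covariate linearly to a 0-100 point scale: the
covariate with the largest |beta| x range spans the full scale, and total
points map monotonically to predicted survival S(t | x) = S0(t)^exp(lp(x) -
lp(mean)) at the requested horizons (default 1/3/5 years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv


@dataclass
class CoxModel:
    covariates: list[str]
    summary: pd.DataFrame  # coef, se, HR, CI bounds, p per covariate
    baseline_survival: pd.DataFrame = field(repr=False)
    means: pd.Series = field(repr=False)
    mins: pd.Series = field(repr=False)
    maxs: pd.Series = field(repr=False)
    max_time: float = 0.0
    fitter: CoxPHFitter = field(default=None, repr=False)

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        return X[self.covariates].astype(float) @ self.coefs

    def predict_survival(self, X: pd.DataFrame, time: float) -> pd.Series:
        """S(t | x) from the Breslow baseline; refuses extrapolation."""
        if time > self.max_time:
            raise ValueError(f"time {time} beyond observed follow-up {self.max_time}")
        s0 = self._baseline_at(time)
        rel = self.linear_predictor(X) - float(self.means @ self.coefs)
        return pd.Series(s0 ** np.exp(rel), index=X.index)

    def _baseline_at(self, time: float) -> float:
        bs = self.baseline_survival.iloc[:, 0]
        prior = bs[bs.index <= time]
        return float(prior.iloc[-1]) if len(prior) else 1.0


def check_collinearity(X: pd.DataFrame) -> list[str]:
    """Columns involved in exact linear dependence (rank deficiency)."""
    Z = X.astype(float).to_numpy()
    Z = Z - Z.mean(axis=0)
    if np.linalg.matrix_rank(Z) == Z.shape[1]:
        return []
    offenders = set()
    cor = np.corrcoef(X.astype(float).to_numpy(), rowvar=False)
    for i in range(len(X.columns)):
        for j in range(i + 1, len(X.columns)):
            if np.isclose(abs(cor[i, j]), 1.0):
                offenders.update([X.columns[i], X.columns[j]])
    if not offenders:
        offenders = set(X.columns)
    return sorted(offenders)


def multivariate_cox(X: pd.DataFrame, time: pd.Series, event: pd.Series,
                     max_iter: int = 100) -> CoxModel:
    """Multivariate Cox PH fit (Breslow ties) with HR, 95% CI and Wald p.

    Degenerate (collinear or constant) covariates raise with the offending
    columns named.
    """
    const = [c for c in X.columns if X[c].astype(float).std() == 0]
    if const:
        raise ValueError(f"constant covariates: {const}")
    bad = check_collinearity(X)
    if bad:
        raise ValueError(f"collinear covariates: {bad}")

    df = X.astype(float).copy()
    df["_time"], df["_event"] = np.asarray(time, float), np.asarray(event, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_ci_lower": s["exp(coef) lower 95%"],
            "hr_ci_upper": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    return CoxModel(
        covariates=list(X.columns),
        summary=summary,
        baseline_survival=cph.baseline_survival_,
        means=df[X.columns].mean(),
        mins=df[X.columns].min(),
        maxs=df[X.columns].max(),
        max_time=float(np.max(time)),
        fitter=cph,
    )


@dataclass
class Nomogram:
    times: tuple
    point_scales: pd.DataFrame  # per covariate: beta, ref, points_per_unit, max points
    scale_denominator: float
    lp_ref: float
    lp_mean: float
    total_points_table: pd.DataFrame  # total points -> S(t) per horizon

    def points(self, covariate: str, value: float) -> float:
        row = self.point_scales.loc[covariate]
        return 100.0 * row["beta"] * (value - row["ref"]) / self.scale_denominator

    def total_points(self, X: pd.DataFrame) -> pd.Series:
        return sum(
            self.points(c, X[c].astype(float)) for c in self.point_scales.index
        )

    def survival_at(self, total_points, time: float, model: CoxModel) -> np.ndarray:
        lp = self.lp_ref + np.asarray(total_points) * self.scale_denominator / 100.0
        s0 = model._baseline_at(time)
        return s0 ** np.exp(lp - self.lp_mean)


def build_nomogram(model: CoxModel, times=(1.0, 3.0, 5.0),
                   n_grid: int = 101) -> Nomogram:
    """Point scales and the total-points -> survival lookup for a Cox model.

    points_i(x) = 100 * beta_i * (x - ref_i) / max_j(|beta_j| * range_j),
    with ref_i the covariate value minimizing beta_i * x, so each covariate
    contributes 0..(its share of 100) points.
    """
    for t in times:
        if t > model.max_time:
            raise ValueError(f"horizon {t} beyond observed follow-up")
    beta = model.coefs
    rng = model.maxs - model.mins
    denom = float((beta.abs() * rng).max())
    if denom == 0:
        raise ValueError("all covariates have zero beta x range")
    ref = pd.Series(
        np.where(beta >= 0, model.mins, model.maxs), index=beta.index
    )
    scales = pd.DataFrame(
        {
            "beta": beta,
            "ref": ref,
            "max_points": 100.0 * beta.abs() * rng / denom,
        }
    )
    lp_ref = float(beta @ ref)
    lp_mean = float(beta @ model.means)

    max_tp = float(scales["max_points"].sum())
    grid = np.linspace(0.0, max_tp, n_grid)
    nomo = Nomogram(tuple(times), scales, denom, lp_ref, lp_mean, pd.DataFrame())
    tbl = {"total_points": grid}
    for t in times:
        tbl[f"surv_{t:g}y"] = nomo.survival_at(grid, t, model)
    nomo.total_points_table = pd.DataFrame(tbl)
    return nomo


def model_discrimination(scores: pd.Series, time: pd.Series, event: pd.Series,
                         horizon: float = 3.0,
                         train: tuple | None = None) -> dict:
    """Harrell's C plus IPCW cumulative/dynamic AUC at a horizon.

    ``scores`` are risk scores (higher = worse).  ``train`` optionally gives
    (time, event) used to estimate the censoring distribution for the IPCW
    weights; by default the evaluation data serve both roles.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    est = np.asarray(scores, float)
    try:
        c_index = float(concordance_index_censored(event, time, est)[0])
    except Exception as exc:  # no comparable pairs
        warnings.warn(f"C-index undefined: {exc}")
        c_index = float("nan")
    if train is None:
        y_train = Surv.from_arrays(event=event, time=time)
    else:
        y_train = Surv.from_arrays(event=np.asarray(train[1], bool),
                                   time=np.asarray(train[0], float))
    y_test = Surv.from_arrays(event=event, time=time)
    try:
        auc, _ = cumulative_dynamic_auc(y_train, y_test, est, [horizon])
        auc = float(auc[0])
    except Exception as exc:
        warnings.warn(f"AUC undefined at horizon {horizon}: {exc}")
        auc = float("nan")
    return {"c_index": c_index, "auc": auc}


def harrells_c(scores, time, event) -> float:
    return model_discrimination(pd.Series(scores), pd.Series(time),
                                pd.Series(event))["c_index"]


def calibration_table(predicted_surv: pd.Series, time: pd.Series,
                      event: pd.Series, at_time: float,
                      n_bins: int = 10) -> pd.DataFrame:
    """Observed (KM) vs mean predicted survival at ``at_time`` per prediction bin.

    Bins are deciles of predicted survival; empty/degenerate bins merge with
    their neighbor via quantile deduplication.
    """
    pred = np.asarray(predicted_surv, float)
    edges = np.unique(np.quantile(pred, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        bins = np.zeros(len(pred), int)
    else:
        bins = np.clip(np.searchsorted(edges, pred, side="right") - 1,
                       0, edges.size - 2)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        obs = float(kmf.predict(at_time))
        ci = kmf.confidence_interval_survival_function_
        prior = ci[ci.index <= at_time]
        lo, hi = (float(prior.iloc[-1, 0]), float(prior.iloc[-1, 1])) \
            if len(prior) else (np.nan, np.nan)
        rows.append(
            {
                "bin": int(b),
                "n": int(sel.sum()),
                "mean_predicted": float(pred[sel].mean()),
                "observed_km": obs,
                "observed_lo": lo,
                "observed_hi": hi,
            }
        )
    return pd.DataFrame(rows)
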
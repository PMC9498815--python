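"""Immune-cell screening against survival and gene-risk groups, and the
immune risk model.

A cell type is carried into the immune LASSO Cox model only if it passes
both screens: (1) its median-abundance split separates overall survival
(log-rank p < alpha) and (2) its abundance differs between the high- and
low-gene-risk groups (Wilcoxon rank-sum p < alpha).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .survival import RiskModel, km_logrank_by_median, lasso_cox_fit

EXACT_WILCOXON_BELOW = 10  # per-group n under which the exact test is used


def screen_os_associated(
    immune: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per cell type: median-abundance split + log-rank test vs overall survival.

    ``immune`` is samples x cell types.  Returns a table with the log-rank
    statistic, p, and a ``selected`` flag (p < alpha).  Constant cells are
    skipped with a warning.
    """
    if len(immune) < 4:
        raise ValueError("need at least 4 samples")
    rows = []
    for cell in immune.columns:
        ab = immune[cell]
        if np.ptp(ab.to_numpy(float)) == 0:
            warnings.warn(f"{cell}: constant abundance, skipped")
            continue
        res = km_logrank_by_median(ab, time, event)
        rows.append(
            {
                "cell": cell,
                "logrank_chi2": res.logrank_chi2,
                "p_value": res.logrank_p,
                "selected": res.logrank_p is not None and res.logrank_p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def screen_riskgroup_de(
    immune: pd.DataFrame,
    risk_groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of each cell between high/low risk groups."""
    hi = immune.loc[risk_groups == "high"]
    lo = immune.loc[risk_groups == "low"]
    if hi.empty or lo.empty:
        raise ValueError("both risk groups must be non-empty")
    low_conf = min(len(hi), len(lo)) < EXACT_WILCOXON_BELOW
    rows = []
    for cell in immune.columns:
        a, b = hi[cell].to_numpy(float), lo[cell].to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"{cell}: constant abundance, skipped")
            continue
        method = "exact" if low_conf else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        rows.append(
            {
                "cell": cell,
                "p_value": float(p),
                "selected": p < alpha,
                "low_confidence": low_conf,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def intersect_and_fit(
    os_screen: pd.DataFrame,
    de_screen: pd.DataFrame,
    immune: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    seed: int = 0,
    **lasso_kwargs,
) -> tuple[RiskModel, list[str]]:
    """LASSO Cox on the cells passing both screens.

    Returns (model, intersection).  An empty intersection raises with both
    screening tables attached for inspection.
    """
    os_cells = set(os_screen.index[os_screen["selected"]])
    de_cells = set(de_screen.index[de_screen["selected"]])
    both = sorted(os_cells & de_cells)
    if not both:
        err = ValueError("no immune cell passed both screens")
        err.os_screen = os_screen
        err.de_screen = de_screen
        raise err
    model = lasso_cox_fit(immune[both], time, event, seed=seed, **lasso_kwargs)
    return model, both
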
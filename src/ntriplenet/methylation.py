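"""Methylation analysis of ntRNAs: DNMT expression by ntRNA level, per-probe
Pearson correlation with ntRNA PSI, and probe-survival association.

"Key" methylation sites are probes that are both negatively correlated with
their ntRNA's PSI (FDR < 0.05, r < 0) and associated with survival by a
median-beta log-rank split (FDR < 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .survival import km_logrank_by_median


def dnmt_group_test(dnmt_expr: pd.DataFrame, ntrna_psi: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum of each DNA methyltransferase between high- and
    low-PSI groups of each ntRNA (split at the median PSI).

    ``dnmt_expr`` is DNMT genes x samples; ``ntrna_psi`` is ntRNA events x
    samples.  Requires >= 4 shared samples; constant-PSI ntRNAs are skipped.
    """
    shared = dnmt_expr.columns.intersection(ntrna_psi.columns)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    rows = []
    for nt in ntrna_psi.index:
        psi = ntrna_psi.loc[nt, shared].astype(float)
        if np.ptp(psi.to_numpy()) == 0:
            continue
        high = psi > psi.median()
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        for g in dnmt_expr.index:
            a = dnmt_expr.loc[g, shared[high]].to_numpy(float)
            b = dnmt_expr.loc[g, shared[~high]].to_numpy(float)
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append(
                {
                    "ntrna": nt,
                    "dnmt": g,
                    "p_value": float(p),
                    "direction": "high_psi_higher" if a.mean() > b.mean()
                    else "low_psi_higher",
                }
            )
    return pd.DataFrame(rows)


def probe_correlations(beta: pd.DataFrame, ntrna_psi: pd.DataFrame,
                       probe_map: dict[str, str]) -> pd.DataFrame:
    """Pearson r (and BH-FDR) between each probe and the ntRNA it annotates to.

    ``probe_map`` maps probe id -> ntRNA event id; pairs with fewer than 4
    complete observations after pairwise deletion are skipped.
    """
    rows = []
    for probe in beta.index:
        nt = probe_map.get(probe)
        if nt is None or nt not in ntrna_psi.index:
            continue
        shared = beta.columns.intersection(ntrna_psi.columns)
        b = beta.loc[probe, shared].astype(float)
        p = ntrna_psi.loc[nt, shared].astype(float)
        ok = b.notna() & p.notna()
        if ok.sum() < 4:
            continue
        r, pv = stats.pearsonr(b[ok], p[ok])
        rows.append({"probe": probe, "ntrna": nt, "pearson_r": float(r),
                     "p_value": float(pv), "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def probe_survival(beta: pd.DataFrame, time: pd.Series,
                   event: pd.Series) -> pd.DataFrame:
    """Median-beta split log-rank test per probe, BH-FDR across probes."""
    shared = beta.columns.intersection(time.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 samples with survival data")
    rows = []
    for probe in beta.index:
        b = beta.loc[probe, shared].astype(float)
        if np.ptp(b.to_numpy()) == 0:
            continue
        res = km_logrank_by_median(b, time[shared], event[shared])
        rows.append({"probe": probe, "logrank_chi2": res.logrank_chi2,
                     "p_value": res.logrank_p})
    out = pd.DataFrame(rows)
    if not out.empty:
        valid = out["p_value"].notna()
        out["fdr"] = np.nan
        if valid.any():
            out.loc[valid, "fdr"] = bh_fdr(out.loc[valid, "p_value"].to_numpy())
    return out


def key_methylation_sites(cor_table: pd.DataFrame, surv_table: pd.DataFrame,
                          fdr_max: float = 0.05) -> list[str]:
    """Probes negatively correlated with their ntRNA and survival-associated."""
    if cor_table.empty or surv_table.empty:
        return []
    neg = set(cor_table.loc[(cor_table["fdr"] < fdr_max)
                            & (cor_table["pearson_r"] < 0), "probe"])
    surv = set(surv_table.loc[surv_table["fdr"] < fdr_max, "probe"])
    return sorted(neg & surv)
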
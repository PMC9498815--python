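"""Differential expression between tumor and normal samples.

Per-feature Wilcoxon rank-sum tests with Benjamini–Hochberg FDR, log2
fold changes on group means with a pseudocount, a low-expression filter,
and the two selection rules used downstream:

* fixed thresholds (FDR < 0.05, |log2FC| > 1) for miRNAs / lncRNAs, and
* the percentile rule for "gene-independent" ntRNAs: the ntRNA's splicing
  event must be strongly differential (FDR at or below the 10th percentile of
  the ntRNA table, |log2FC| > 1) while its host gene's overall expression is
  not (gene FDR at or above the gene-table median).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 1.0
PSI_PSEUDOCOUNT = 0.01


def filter_low_expressed(
    matrix: pd.DataFrame, zero_fraction_threshold: float = 0.6
) -> pd.DataFrame:
    """Drop features whose expression is zero in strictly more than
    ``zero_fraction_threshold`` of samples.

    Rows are features, columns samples.  A feature zero in exactly the
    threshold fraction is kept.
    """
    if matrix.empty:
        return matrix
    zero_frac = (matrix == 0).sum(axis=1) / matrix.shape[1]
    return matrix.loc[zero_frac <= zero_fraction_threshold]


def de_stats(
    matrix: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal statistics.

    ``groups`` maps sample id -> "tumor"/"normal".  Returns a DataFrame
    indexed by feature with columns mean_tumor, mean_normal, log2fc, p_value,
    fdr.  log2fc = log2((mean_tumor + eps) / (mean_normal + eps)); the test is
    the two-sided Wilcoxon rank-sum (Mann-Whitney, normal approximation with
    tie correction).
    """
    groups = groups.reindex(matrix.columns)
    tumor = matrix.loc[:, groups == "tumor"].to_numpy(float)
    normal = matrix.loc[:, groups == "normal"].to_numpy(float)
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("both tumor and normal groups must be non-empty")

    mean_t = tumor.mean(axis=1)
    mean_n = normal.mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_n + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows give p=1 below
        res = stats.mannwhitneyu(tumor, normal, axis=1, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, float)
    constant = np.ptp(np.hstack([tumor, normal]), axis=1) == 0
    p[constant] = 1.0
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
        },
        index=matrix.index,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def select_de_features(
    de: pd.DataFrame, fdr_max: float = 0.05, abs_log2fc_min: float = 1.0
) -> list[str]:
    """Features with fdr < fdr_max and |log2fc| > abs_log2fc_min (both strict)."""
    if de.empty:
        return []
    keep = (de["fdr"] < fdr_max) & (de["log2fc"].abs() > abs_log2fc_min)
    return list(de.index[keep])


def select_independent_ntrnas(
    ntrna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    tag_map: dict[str, str],
    ntrna_fdr_percentile: float = 10.0,
    gene_fdr_percentile: float = 50.0,
    abs_log2fc_min: float = 1.0,
) -> list[str]:
    """ntRNAs differential at the event level while their gene is not.

    Selected iff (a) event fdr <= the ``ntrna_fdr_percentile``-th percentile
    of the ntRNA table's fdr values and |log2fc| > ``abs_log2fc_min``, and
    (b) host-gene fdr >= the ``gene_fdr_percentile``-th percentile of the gene
    table's fdr values.  Percentiles use linear interpolation over the full
    respective tables.  ntRNAs whose gene is missing from ``gene_de`` are
    skipped with a warning.
    """
    if ntrna_de.empty:
        return []
    ntrna_cut = np.percentile(ntrna_de["fdr"].to_numpy(), ntrna_fdr_percentile)
    gene_cut = np.percentile(gene_de["fdr"].to_numpy(), gene_fdr_percentile)

    selected = []
    for nt in ntrna_de.index:
        gene = tag_map.get(nt)
        if gene is None or gene not in gene_de.index:
            warnings.warn(f"ntRNA {nt}: no mapped gene in the gene table; skipped")
            continue
        row = ntrna_de.loc[nt]
        if (
            row["fdr"] <= ntrna_cut
            and abs(row["log2fc"]) > abs_log2fc_min
            and gene_de.loc[gene, "fdr"] >= gene_cut
        ):
            selected.append(nt)
    return selected
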
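"""Weighted coexpression modules (WGCNA-style) and module-trait correlation.

Adjacency is unsigned soft-thresholded Pearson correlation, a_ij = |cor|^beta,
with beta chosen by the approximate scale-free topology criterion.  Modules
come from average-linkage clustering of 1 - TOM with a static height cut, a
minimum size rule (small clusters fall into "grey"), and iterative merging of
modules whose eigengenes correlate at or above a threshold.  The module
eigengene is the first principal component of the standardized member
expression, oriented so it correlates positively with mean member expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# WGCNA-style module labels, assigned in decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


@dataclass
class CoexpressionModule:
    label: str
    members: list[str]
    eigengene: pd.Series
    power_used: int


def _adjacency(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal.  Rows are features."""
    cor = np.corrcoef(expr.to_numpy(float))
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def drop_constant_features(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"removed {int(bad.sum())} constant features")
    return expr.loc[~bad]


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-occupancy bins.

    With equal-occupancy bins the per-bin frequency is constant, so p(k) is
    estimated as the bin density (frequency / bin width).  Positive when the
    distribution decays (negative slope), as the scale-free criterion demands.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    # equal-occupancy bin edges; duplicates collapse for degenerate inputs
    qs = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if edges.size < 4:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    mean_k, dens = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if sel.any() and width > 0:
            mean_k.append(k[sel].mean())
            dens.append(sel.mean() / width)
    if len(mean_k) < 3:
        return 0.0
    x, y = np.log10(mean_k), np.log10(dens)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    slope, _, r, _, _ = stats.linregress(x, y)
    return -np.sign(slope) * r**2


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: range = range(1, 21),
    r2_target: float = 0.85,
    fallback_power: int | None = None,
) -> int:
    """Smallest power whose connectivity distribution meets the scale-free
    R^2 target.

    When no power qualifies, returns ``fallback_power`` if given (small
    feature sets rarely satisfy the criterion; 6 is the community convention
    for unsigned networks at large sample sizes), otherwise the power
    maximizing R^2 — with a warning either way.
    """
    expr = drop_constant_features(expr)
    cor = np.abs(np.corrcoef(expr.to_numpy(float)))
    np.fill_diagonal(cor, 0.0)
    best_beta, best_r2 = None, -np.inf
    for beta in candidate_powers:
        k = (cor**beta).sum(axis=1)
        r2 = scale_free_fit(k)
        if r2 >= r2_target:
            return beta
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    if fallback_power is not None:
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; "
            f"using conventional power {fallback_power}"
        )
        return fallback_power
    warnings.warn(
        f"no power reached scale-free R^2 {r2_target}; using beta={best_beta} "
        f"(R^2={best_r2:.2f})"
    )
    return best_beta


def tom_similarity(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Topological overlap matrix of the soft-thresholded adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    a = _adjacency(expr, beta)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def module_eigengene(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component across samples of standardized member rows,
    oriented to correlate positively with mean member expression."""
    x = expr.loc[members].to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    ref = z.mean(axis=0)
    if ref.std() > 0 and np.corrcoef(eig, ref)[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_size: int = 10,
    merge_threshold: float = 0.85,
    cut_quantile: float | None = None,
    power_used: int = 0,
) -> list[CoexpressionModule]:
    """Average-linkage modules on 1 - TOM with min-size and eigengene merging.

    The tree is cut at a static height: by default the midpoint of the
    largest gap in sorted merge heights (which separates tight clusters from
    the late joins of unclustered features); pass ``cut_quantile`` to cut at
    that quantile of merge heights instead.  Clusters below ``min_size``
    become "grey"; modules whose eigengenes correlate >= ``merge_threshold``
    merge iteratively (closest pair first).  Labels are assigned by
    decreasing size; "grey" collects the unassigned.
    """
    features = list(tom.index)
    if len(features) < min_size:
        return [
            CoexpressionModule("grey", features, module_eigengene(expr, features),
                               power_used)
        ]
    dis = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dis, 0.0)
    z = linkage(squareform(dis, checks=False), method="average")
    heights = np.sort(z[:, 2])
    if cut_quantile is not None:
        cut = float(np.quantile(heights, cut_quantile))
    elif len(heights) > 1:
        gaps = np.diff(heights)
        g = int(np.argmax(gaps))
        cut = float((heights[g] + heights[g + 1]) / 2.0)
    else:
        cut = float(heights[-1])
    labels = fcluster(z, t=cut, criterion="distance")

    groups: dict[int, list[str]] = {}
    for f, lab in zip(features, labels):
        groups.setdefault(int(lab), []).append(f)
    proper = [m for m in groups.values() if len(m) >= min_size]
    grey = [f for m in groups.values() if len(m) < min_size for f in m]

    # iterative eigengene merging
    proper = [sorted(m) for m in proper]
    while len(proper) > 1:
        eigs = np.array([module_eigengene(expr, m).to_numpy() for m in proper])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] < merge_threshold:
            break
        merged = sorted(proper[i] + proper[j])
        proper = [m for t, m in enumerate(proper) if t not in (i, j)] + [merged]

    proper.sort(key=lambda m: (-len(m), m[0]))
    out = [
        CoexpressionModule(MODULE_COLORS[t % len(MODULE_COLORS)], m,
                           module_eigengene(expr, m), power_used)
        for t, m in enumerate(proper)
    ]
    if grey:
        out.append(
            CoexpressionModule("grey", sorted(grey), module_eigengene(expr, grey),
                               power_used)
        )
    return out


def module_trait_correlation(
    modules: list[CoexpressionModule],
    traits: pd.DataFrame,
    primary_trait: str = "os_status",
) -> tuple[pd.DataFrame, str | None]:
    """Pearson correlation of each module eigengene with each numeric trait.

    Returns the module x trait table and the key (non-grey) module label:
    the one maximizing |cor| with ``primary_trait``.  Constant traits yield
    missing correlations.
    """
    rows = []
    for mod in modules:
        eig = mod.eigengene.reindex(traits.index)
        for trait in traits.columns:
            tv = traits[trait].astype(float)
            if tv.std() == 0 or eig.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(eig, tv)
            rows.append({"module": mod.label, "trait": trait, "cor": r, "p_value": p})
    table = pd.DataFrame(rows)
    sub = table[(table["trait"] == primary_trait) & (table["module"] != "grey")]
    sub = sub.dropna(subset=["cor"])
    key = None
    if not sub.empty:
        key = sub.loc[sub["cor"].abs().idxmax(), "module"]
    return table, key
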
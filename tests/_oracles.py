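"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from first principles (explicit loops,
exhaustive enumeration, direct formula application), staying independent of
the package's implementation path.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s):
    return "".join(_COMP[b] for b in reversed(s))


def seed_sites_bruteforce(mirna: str, target: str):
    """All seed sites by direct per-type window comparison; returns a set of
    (site_type, 1-based position) after strongest-type collapse per core
    locus.  8mer/7mer-m8 positions start at the m8-complementary base."""
    mir = mirna.upper().replace("U", "T")
    tgt = target.upper().replace("U", "T")
    out = set()
    for p in range(len(tgt)):  # p: 0-based candidate 6mer-core start
        if tgt[p : p + 6] != _rc(mir[1:7]):
            continue
        m8 = p >= 1 and tgt[p - 1 : p + 6] == _rc(mir[1:8])
        a1 = tgt[p + 6 : p + 7] == "A"
        if m8 and a1:
            out.add(("8mer", p))        # 1-based (p-1)+1
        elif m8:
            out.add(("7mer-m8", p))
        elif a1:
            out.add(("7mer-A1", p + 1))
        else:
            out.add(("6mer", p + 1))
    return out


def all_pairs_shortest_paths(edges, nodes):
    """Floyd-Warshall distances."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for u, v in edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d, idx


def betweenness_bruteforce(edges, nodes):
    """Count shortest paths through each node by path enumeration."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    d, idx = all_pairs_shortest_paths(edges, nodes)

    def count_paths(s, t):
        # number of shortest s-t paths through each node, via DAG counting
        ds = d[idx[s]]
        sigma = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        for v in sorted(nodes, key=lambda x: ds[idx[x]]):
            if np.isinf(ds[idx[v]]) or v == s:
                continue
            sigma[v] = sum(sigma[u] for u in adj[v]
                           if ds[idx[u]] == ds[idx[v]] - 1)
        # paths through w: sigma_s(w) * sigma_w(t) if on a shortest path
        return sigma

    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if np.isinf(d[idx[s], idx[t]]):
            continue
        sig_s = count_paths(s, t)
        sig_t = count_paths(t, s)
        total = sig_s[t]
        for w in nodes:
            if w in (s, t):
                continue
            if d[idx[s], idx[w]] + d[idx[w], idx[t]] == d[idx[s], idx[t]]:
                bc[w] += sig_s[w] * sig_t[w] / total
    return bc


def closeness_harmonic_bruteforce(edges, nodes):
    d, idx = all_pairs_shortest_paths(edges, nodes)
    return {
        v: sum(1.0 / d[idx[v], idx[u]] for u in nodes
               if u != v and np.isfinite(d[idx[v], idx[u]]))
        for v in nodes
    }


def radiality_bruteforce(edges, nodes):
    d, idx = all_pairs_shortest_paths(edges, nodes)
    out = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and np.isfinite(d[idx[v], idx[u]])]
        if not reach:
            out[v] = 0.0
            continue
        comp = set(reach) | {v}
        diam = max(
            d[idx[a], idx[b]] for a in comp for b in comp
            if np.isfinite(d[idx[a], idx[b]])
        )
        out[v] = sum(diam + 1 - d[idx[v], idx[u]] for u in reach) / (len(comp) - 1)
    return out


def epc_exact(edges, nodes, keep_prob=0.5):
    """Exact expected reachable-set size by enumerating all edge subsets."""
    edges = list(edges)
    m = len(edges)
    out = {v: 0.0 for v in nodes}
    for mask in range(2 ** m):
        kept = [e for i, e in enumerate(edges) if mask >> i & 1]
        w = keep_prob ** bin(mask).count("1") * (1 - keep_prob) ** (
            m - bin(mask).count("1"))
        d, idx = all_pairs_shortest_paths(kept, nodes)
        for v in nodes:
            out[v] += w * sum(
                1 for u in nodes if u != v and np.isfinite(d[idx[v], idx[u]]))
    return out


def tom_bruteforce(adjacency: np.ndarray) -> np.ndarray:
    """Direct double-loop topological overlap on a zero-diagonal adjacency."""
    n = adjacency.shape[0]
    k = adjacency.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(adjacency[i, u] * adjacency[u, j] for u in range(n))
            tom[i, j] = (shared + adjacency[i, j]) / (
                min(k[i], k[j]) + 1 - adjacency[i, j])
    return tom


def harrells_c_bruteforce(scores, time, event):
    """All-pairs concordance count (prediction ties = 0.5)."""
    n = len(scores)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the earlier observed event
            if event[i] != 1 or time[i] >= time[j]:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def logrank_bruteforce(time_a, event_a, time_b, event_b):
    """Two-group log-rank chi-square by explicit tabulation of event times."""
    times = sorted(set(list(time_a) + list(time_b)))
    O = E = V = 0.0
    for t in times:
        na = sum(1 for x in time_a if x >= t)
        nb = sum(1 for x in time_b if x >= t)
        da = sum(1 for x, e in zip(time_a, event_a) if x == t and e)
        db = sum(1 for x, e in zip(time_b, event_b) if x == t and e)
        d, n = da + db, na + nb
        if d == 0 or n < 2:
            continue
        O += da
        E += d * na / n
        V += d * (n - d) * na * nb / (n ** 2 * (n - 1))
    return (O - E) ** 2 / V if V > 0 else 0.0


def independent_ntrna_selection_bruteforce(ntrna_fdr, ntrna_lfc, gene_fdr,
                                           tag_map, pct_nt=10.0, pct_gene=50.0,
                                           lfc_min=1.0):
    """Literal restatement of the two percentile rules."""
    nt_cut = np.percentile(list(ntrna_fdr.values()), pct_nt)
    g_cut = np.percentile(list(gene_fdr.values()), pct_gene)
    out = []
    for nt in ntrna_fdr:
        g = tag_map.get(nt)
        if g is None or g not in gene_fdr:
            continue
        if (ntrna_fdr[nt] <= nt_cut and abs(ntrna_lfc[nt]) > lfc_min
                and gene_fdr[g] >= g_cut):
            out.append(nt)
    return sorted(out)
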
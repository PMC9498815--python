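"""miRNA seed-site prediction and triple-network assembly.

Target sites are canonical seed matches: with the target written 5'→3', a
site is the reverse complement of miRNA seed positions 2–7 (6mer) or 2–8
(m8 extension), optionally followed by an A opposite miRNA position 1:

    8mer     revcomp(miR[2..8]) + A
    7mer-m8  revcomp(miR[2..8])
    7mer-A1  revcomp(miR[2..7]) + A
    6mer     revcomp(miR[2..7])

Overlapping site calls at one seed locus collapse to the strongest type
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  The network has two layers,
ntRNA–miRNA and miRNA–lncRNA, joined on the miRNAs of the first layer —
the ceRNA coupling under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

SITE_STRENGTH = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _norm(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(_norm(seq)))


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    site_type: str
    position: int  # 1-based start of the matched subsequence in the target


@dataclass(frozen=True)
class InteractionPair:
    mirna_id: str
    target_id: str
    layer: str  # "ntrna_mirna" | "mirna_lncrna"
    sites: tuple[SeedSite, ...] = ()


def find_seed_sites(
    mirna_sequence: str,
    target_sequence: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one target sequence.

    Both sequences are 5'→3'; the miRNA may use U or T.  The reported
    ``position`` is the 1-based start of the full matched subsequence
    (including the m8-complementary base for 8mer/7mer-m8 sites).
    """
    mir = _norm(mirna_sequence)
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    tgt = _norm(target_sequence)

    core6 = reverse_complement(mir[1:7])   # complements seed 2-7
    m8c = _COMPLEMENT[mir[7]]              # base complementary to position 8

    sites = []
    for p in range(len(tgt) - 5):          # p = 0-based start of the 6mer core
        if tgt[p : p + 6] != core6:
            continue
        has_m8 = p >= 1 and tgt[p - 1] == m8c
        has_a1 = p + 6 < len(tgt) and tgt[p + 6] == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", p - 1
        elif has_m8:
            stype, start = "7mer-m8", p - 1
        elif has_a1:
            stype, start = "7mer-A1", p
        else:
            stype, start = "6mer", p
        sites.append(SeedSite(mirna_id, target_id, stype, start + 1))
    return sites


def build_layer_pairs(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str | None],
    layer: str,
) -> list[InteractionPair]:
    """Pairs (miRNA, target) supported by at least one seed site."""
    import warnings

    pairs = []
    for mid in sorted(mirna_seqs):
        for tid in sorted(target_seqs):
            seq = target_seqs[tid]
            if not seq:
                warnings.warn(f"{tid}: missing sequence, skipped")
                continue
            sites = find_seed_sites(mirna_seqs[mid], seq, mid, tid)
            if sites:
                pairs.append(InteractionPair(mid, tid, layer, tuple(sites)))
    return pairs


@dataclass
class TripleNetwork:
    """The ntRNA–miRNA–lncRNA graph: two bipartite layers joined on miRNAs."""

    graph: nx.Graph
    ntrnas: set[str] = field(default_factory=set)
    mirnas: set[str] = field(default_factory=set)
    lncrnas: set[str] = field(default_factory=set)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def assemble_triple_network(
    ntrna_mirna_pairs: Iterable[InteractionPair],
    mirna_lncrna_pairs: Iterable[InteractionPair],
) -> TripleNetwork:
    """Union of both layers, restricted to miRNAs of the ntRNA–miRNA layer.

    Node sets derive from surviving edges, so the miRNA set equals the
    miRNAs that appear in edges; there are no ntRNA–lncRNA edges by
    construction.  Order-independent and idempotent.
    """
    layer1 = list(ntrna_mirna_pairs)
    shared = {p.mirna_id for p in layer1}
    layer2 = [p for p in mirna_lncrna_pairs if p.mirna_id in shared]

    g = nx.Graph()
    ntrnas, mirnas, lncrnas = set(), set(), set()
    for p in layer1:
        g.add_edge(p.mirna_id, p.target_id, layer="ntrna_mirna")
        mirnas.add(p.mirna_id)
        ntrnas.add(p.target_id)
    for p in layer2:
        g.add_edge(p.mirna_id, p.target_id, layer="mirna_lncrna")
        mirnas.add(p.mirna_id)
        lncrnas.add(p.target_id)
    return TripleNetwork(g, ntrnas, mirnas, lncrnas)


def edge_list_frame(net: TripleNetwork):
    import pandas as pd

    rows = [
        {"source": u, "target": v, "layer": d["layer"]}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "layer"])
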
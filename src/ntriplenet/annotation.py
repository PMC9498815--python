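"""Transcript classification into ntRNA / normal, ntRNA-unique splice tags,
and matching of tags to alternative-splicing events.

An ntRNA (nonsense-mediated-decay-targeted RNA) is called from annotation
alone, by the first matching rule in a fixed order:

1. ``nr_prefix``          — RefSeq accession starting with ``NR_``.
2. ``not_protein_coding`` — Ensembl transcript whose biotype is not
                            protein_coding.
3. ``no_ccds``            — Ensembl protein_coding transcript without a CCDS.
4. ``short_75pct``        — Ensembl protein_coding transcript with a CCDS but
                            spliced length strictly less than 75% of the
                            longest RefSeq NM isoform of the same gene.

RefSeq ``NM_`` transcripts are the "normal" (protein-producing) reference set
against which unique splice features are defined.  All genomic coordinates are
1-based closed intervals (GTF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

Interval = tuple[int, int]

SPLICE_TYPES = ("AP", "AT", "AD", "AA", "ES", "RI", "ME")

RULE_ORDER = ("nr_prefix", "not_protein_coding", "no_ccds", "short_75pct")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exons on a genome.

    ``exons`` are 1-based closed intervals, non-overlapping, stored sorted by
    start coordinate regardless of strand; ``length`` is the spliced (exonic)
    length.
    """

    transcript_id: str
    gene_id: str
    source: str  # "refseq" | "ensembl"
    biotype: str
    ccds_id: str | None
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self):
        exs = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s1, e1)} / {(s2, e2)}"
                )
        object.__setattr__(self, "exons", exs)
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class NtRNAClassification:
    transcript_id: str
    gene_id: str
    is_ntrna: bool
    rule_fired: str  # one of RULE_ORDER or "none"
    note: str = ""


@dataclass(frozen=True)
class NtRNATag:
    """A splice feature present in an ntRNA but in no NM isoform of its gene."""

    gene_id: str
    ntrna_id: str
    kind: str  # unique_exon | unique_junction | retained_intron | alt_boundary
    intervals: tuple[Interval, ...]
    at_5prime: bool = False  # feature sits at the transcript's 5' terminal exon
    at_3prime: bool = False


@dataclass
class ASEvent:
    """A named alternative-splicing event with a per-sample PSI vector.

    ``event_id`` has the form GENE_NUM_TYPE, e.g. ``KLC2_16990_AP``.
    """

    event_id: str
    gene: str
    number: int
    splice_type: str
    interval: Interval
    psi: pd.Series | None = field(default=None, repr=False)

    @classmethod
    def parse_id(cls, event_id: str) -> tuple[str, int, str]:
        gene, num, stype = event_id.rsplit("_", 2)
        if stype not in SPLICE_TYPES:
            raise ValueError(f"unknown splice type in event id {event_id!r}")
        return gene, int(num), stype

    @classmethod
    def from_id(cls, event_id: str, interval: Interval, psi=None) -> "ASEvent":
        gene, num, stype = cls.parse_id(event_id)
        return cls(event_id, gene, num, stype, tuple(interval), psi)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_transcripts(
    transcripts: Iterable[TranscriptModel],
) -> list[NtRNAClassification]:
    """Classify each transcript as ntRNA or normal.

    Pure function of (accession prefix, biotype, CCDS presence, length ratio);
    input order never changes the result.  Ensembl protein_coding transcripts
    of genes with no NM isoform cannot be tested against the 75% length rule
    and are flagged ``unclassifiable-by-rule-3``.
    """
    transcripts = list(transcripts)
    longest_nm: dict[str, int] = {}
    for t in transcripts:
        if t.source == "refseq" and t.transcript_id.startswith("NM_"):
            longest_nm[t.gene_id] = max(longest_nm.get(t.gene_id, 0), t.length)

    out = []
    for t in transcripts:
        rule, note = "none", ""
        if t.source == "refseq":
            if t.transcript_id.startswith("NR_"):
                rule = "nr_prefix"
        elif t.source == "ensembl":
            if t.biotype != "protein_coding":
                rule = "not_protein_coding"
            elif t.ccds_id is None:
                rule = "no_ccds"
            else:
                nm_len = longest_nm.get(t.gene_id)
                if nm_len is None:
                    note = "unclassifiable-by-rule-3"
                elif t.length < 0.75 * nm_len:  # strict inequality
                    rule = "short_75pct"
        out.append(
            NtRNAClassification(t.transcript_id, t.gene_id, rule != "none", rule, note)
        )
    return out


# ---------------------------------------------------------------------------
# unique splice tags
# ---------------------------------------------------------------------------

def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def extract_unique_tags(
    gene_transcripts: Sequence[TranscriptModel],
    classifications: Sequence[NtRNAClassification] | None = None,
) -> list[NtRNATag]:
    """Splice features unique to each ntRNA of a gene relative to its NMs.

    Emits four kinds of tag per ntRNA:

    * ``unique_exon``    — exon not overlapping any NM exon;
    * ``alt_boundary``   — exon overlapping an NM exon but with no NM exon
                           sharing both boundaries;
    * ``unique_junction``— intron (splice junction) absent from every NM;
    * ``retained_intron``— NM intron fully contained inside an ntRNA exon.

    Genes without an NM baseline yield an empty list with a warning.
    Output is deterministically ordered by (ntrna_id, kind, coordinates).
    """
    if classifications is None:
        classifications = classify_transcripts(gene_transcripts)
    cls_by_id = {c.transcript_id: c for c in classifications}

    nms = [
        t for t in gene_transcripts
        if t.source == "refseq" and t.transcript_id.startswith("NM_")
    ]
    ntrnas = [t for t in gene_transcripts if cls_by_id[t.transcript_id].is_ntrna]
    if not ntrnas:
        return []
    if not nms:
        warnings.warn(
            f"gene {gene_transcripts[0].gene_id}: no NM transcript, "
            "no baseline for unique-tag extraction"
        )
        return []

    nm_exons = {e for t in nms for e in t.exons}
    nm_introns = {i for t in nms for i in t.introns}

    tags: list[NtRNATag] = []
    for t in ntrnas:
        first, last = t.exons[0], t.exons[-1]
        # genomic first exon is 5' on + strand, 3' on - strand
        def _ends(exon: Interval) -> tuple[bool, bool]:
            is_first_genomic = exon == first
            is_last_genomic = exon == last
            if t.strand == "+":
                return is_first_genomic, is_last_genomic
            return is_last_genomic, is_first_genomic

        for exon in t.exons:
            if exon in nm_exons:
                continue
            p5, p3 = _ends(exon)
            if any(_overlaps(exon, ne) for ne in nm_exons):
                tags.append(
                    NtRNATag(t.gene_id, t.transcript_id, "alt_boundary", (exon,), p5, p3)
                )
            else:
                tags.append(
                    NtRNATag(t.gene_id, t.transcript_id, "unique_exon", (exon,), p5, p3)
                )
        for intron in t.introns:
            if intron not in nm_introns:
                tags.append(
                    NtRNATag(t.gene_id, t.transcript_id, "unique_junction", (intron,))
                )
        for intron in nm_introns:
            for exon in t.exons:
                if exon[0] <= intron[0] and intron[1] <= exon[1]:
                    tags.append(
                        NtRNATag(t.gene_id, t.transcript_id, "retained_intron", (intron,))
                    )
                    break
    tags.sort(key=lambda g: (g.ntrna_id, g.kind, g.intervals))
    return tags


# tag kind -> compatible SpliceSeq event types; terminal-exon tags additionally
# match alternate promoter/terminator events
_BASE_COMPAT = {
    "retained_intron": {"RI"},
    "unique_exon": {"ES", "ME"},
    "alt_boundary": {"AD", "AA"},
    "unique_junction": {"ES", "ME", "AD", "AA"},
}


def compatible_types(tag: NtRNATag) -> set[str]:
    types = set(_BASE_COMPAT[tag.kind])
    if tag.kind in ("unique_exon", "alt_boundary"):
        if tag.at_5prime:
            types.add("AP")
        if tag.at_3prime:
            types.add("AT")
    return types


def match_tags_to_ase(
    tags: Sequence[NtRNATag],
    ase_catalog: Sequence[ASEvent],
    gene_symbols: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Map each ntRNA to the splicing events realising one of its unique tags.

    A tag matches an event when the gene symbols agree, the event's splice
    type is compatible with the tag kind, and the intervals overlap.  All
    matches are kept (ambiguity is visible as >1 event per ntRNA); the PSI
    vector of a matched event thereafter quantifies the ntRNA.
    """
    gene_symbols = gene_symbols or {}
    by_gene: dict[str, list[ASEvent]] = {}
    for ev in ase_catalog:
        by_gene.setdefault(ev.gene, []).append(ev)

    mapping: dict[str, list[str]] = {}
    for tag in sorted(tags, key=lambda g: (g.ntrna_id, g.kind, g.intervals)):
        symbol = gene_symbols.get(tag.gene_id, tag.gene_id)
        ok_types = compatible_types(tag)
        for ev in by_gene.get(symbol, ()):
            if ev.splice_type not in ok_types:
                continue
            if any(_overlaps(iv, ev.interval) for iv in tag.intervals):
                lst = mapping.setdefault(tag.ntrna_id, [])
                if ev.event_id not in lst:
                    lst.append(ev.event_id)
    return mapping


# ---------------------------------------------------------------------------
# GTF / TSV round trip
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    lines = []
    for t in transcripts:
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'transcript_biotype "{t.biotype}";'
        )
        if t.ccds_id:
            attrs += f' ccds_id "{t.ccds_id}";'
        src = "RefSeq" if t.source == "refseq" else "Ensembl"
        span = (t.exons[0][0], t.exons[-1][1])
        lines.append(
            f"chr1\t{src}\ttranscript\t{span[0]}\t{span[1]}\t.\t{t.strand}\t.\t{attrs}"
        )
        for s, e in t.exons:
            lines.append(f"chr1\t{src}\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_attrs(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features only)."""
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = _parse_attrs(f[8])
            tid = attrs["transcript_id"]
            rec = rows.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "source": "refseq" if f[1] == "RefSeq" else "ensembl",
                    "biotype": attrs.get("transcript_biotype", ""),
                    "ccds_id": attrs.get("ccds_id"),
                    "strand": f[6],
                    "exons": [],
                },
            )
            rec["exons"].append((int(f[3]), int(f[4])))
    return [
        TranscriptModel(
            tid, r["gene_id"], r["source"], r["biotype"], r["ccds_id"], r["strand"],
            tuple(sorted(r["exons"])),
        )
        for tid, r in rows.items()
    ]


def classification_frame(classifications: Sequence[NtRNAClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "gene_id": c.gene_id,
                "is_ntrna": c.is_ntrna,
                "rule_fired": c.rule_fired,
                "note": c.note,
            }
            for c in classifications
        ]
    )


def tag_frame(tags: Sequence[NtRNATag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "ntrna_id": t.ntrna_id,
                "kind": t.kind,
                "intervals": ";".join(f"{s}-{e}" for s, e in t.intervals),
                "at_5prime": t.at_5prime,
                "at_3prime": t.at_3prime,
            }
            for t in tags
        ]
    )
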
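"""Transcript classification rules, unique splice tags, and event matching."""

import numpy as np
import pytest

from ntriplenet.annotation import (
    ASEvent,
    TranscriptModel,
    classify_transcripts,
    compatible_types,
    extract_unique_tags,
    match_tags_to_ase,
)


def tx(tid, gene="G1", source="refseq", biotype="protein_coding", ccds="C1",
       strand="+", exons=((1, 100), (201, 300))):
    return TranscriptModel(tid, gene, source, biotype, ccds, strand, tuple(exons))


def classify_one(transcripts, tid):
    return {c.transcript_id: c for c in classify_transcripts(transcripts)}[tid]


class TestClassification:
    NM2000 = tx("NM_1", exons=((1, 1000), (1201, 2200)))  # spliced length 2000

    @pytest.mark.parametrize(
        "t, is_ntrna, rule",
        [
            (tx("NR_000001"), True, "nr_prefix"),
            (tx("NM_000001"), False, "none"),
            (tx("ENST1", source="ensembl", biotype="lincRNA"), True,
             "not_protein_coding"),
            (tx("ENST2", source="ensembl", ccds=None), True, "no_ccds"),
        ],
    )
    def test_single_rules(self, t, is_ntrna, rule):
        c = classify_one([t, self.NM2000], t.transcript_id)
        assert (c.is_ntrna, c.rule_fired) == (is_ntrna, rule)

    @pytest.mark.parametrize(
        "length, expected",
        [(1499, True), (1500, False)],  # strictly less than 75% of 2000
    )
    def test_length_rule_boundary(self, length, expected):
        short = tx("ENST3", source="ensembl", exons=((1, length),))
        c = classify_one([short, self.NM2000], "ENST3")
        assert c.is_ntrna is expected
        assert c.rule_fired == ("short_75pct" if expected else "none")

    def test_gene_without_nm_flagged_unclassifiable(self):
        lonely = tx("ENST4", source="ensembl", gene="G9")
        c = classify_one([lonely, self.NM2000], "ENST4")
        assert not c.is_ntrna and c.note == "unclassifiable-by-rule-3"

    def test_order_invariance(self):
        ts = [self.NM2000, tx("NR_1"), tx("ENST5", source="ensembl", ccds=None),
              tx("ENST6", source="ensembl", exons=((1, 500),))]
        fwd = {c.transcript_id: c.rule_fired for c in classify_transcripts(ts)}
        rev = {c.transcript_id: c.rule_fired for c in classify_transcripts(ts[::-1])}
        assert fwd == rev


class TestUniqueTags:
    def test_identical_structure_gives_no_tags(self):
        nm = tx("NM_1", exons=((1, 100), (201, 300)))
        nt = tx("NR_1", exons=((1, 100), (201, 300)))
        assert extract_unique_tags([nm, nt]) == []

    def test_retained_intron(self):
        nm = tx("NM_1", exons=((1, 100), (201, 300)))
        nt = tx("NR_1", exons=((1, 300),))
        tags = extract_unique_tags([nm, nt])
        ri = [t for t in tags if t.kind == "retained_intron"]
        assert len(ri) == 1 and ri[0].intervals == ((101, 200),)

    def test_novel_first_exon_is_ap_compatible(self):
        nm = tx("NM_1", exons=((60, 100), (201, 300)))
        nt = tx("NR_1", exons=((1, 50), (201, 300)))
        tags = extract_unique_tags([nm, nt])
        ue = [t for t in tags if t.kind == "unique_exon"]
        assert len(ue) == 1 and ue[0].intervals == ((1, 50),)
        assert ue[0].at_5prime and "AP" in compatible_types(ue[0])

    def test_gene_without_nm_warns_and_returns_empty(self):
        nt = tx("NR_1", gene="G2")
        with pytest.warns(UserWarning, match="no NM"):
            assert extract_unique_tags([nt]) == []

    def test_bruteforce_exon_junction_oracle(self):
        """On random small genes the emitted unique exons/junctions equal a
        direct set difference, and no tag interval occurs in any NM."""
        rng = np.random.default_rng(0)
        for trial in range(30):
            n_tx = rng.integers(2, 5)
            txs = []
            for t in range(n_tx):
                n_ex = int(rng.integers(1, 7))
                # random exon grid on a lattice of 40-unit slots
                slots = sorted(rng.choice(12, size=n_ex, replace=False))
                exons = tuple((1 + 40 * s, 1 + 40 * s + int(rng.integers(10, 39)))
                              for s in slots)
                tid = f"NM_{t}" if t < max(1, n_tx - 2) else f"NR_{t}"
                txs.append(tx(tid, exons=exons, source="refseq",
                              biotype="protein_coding",
                              ccds=None if tid.startswith("NR") else "C1"))
            tags = extract_unique_tags(txs)
            nms = [t for t in txs if t.transcript_id.startswith("NM_")]
            nm_exons = {e for t in nms for e in t.exons}
            nm_introns = {i for t in nms for i in t.introns}
            for nt in (t for t in txs if t.transcript_id.startswith("NR_")):
                got_ex = {g.intervals[0] for g in tags
                          if g.ntrna_id == nt.transcript_id
                          and g.kind in ("unique_exon", "alt_boundary")}
                assert got_ex == {e for e in nt.exons if e not in nm_exons}
                got_j = {g.intervals[0] for g in tags
                         if g.ntrna_id == nt.transcript_id
                         and g.kind == "unique_junction"}
                assert got_j == {i for i in nt.introns if i not in nm_introns}
            for g in tags:
                if g.kind in ("unique_exon", "alt_boundary"):
                    assert g.intervals[0] not in nm_exons
                elif g.kind == "unique_junction":
                    assert g.intervals[0] not in nm_introns


class TestASEMatching:
    def test_event_id_parses_into_components(self):
        assert ASEvent.parse_id("KLC2_16990_AP") == ("KLC2", 16990, "AP")
        with pytest.raises(ValueError):
            ASEvent.parse_id("KLC2_16990_XX")

    def test_exact_retained_intron_match(self):
        nm = tx("NM_1", exons=((1, 100), (201, 300)))
        nt = tx("NR_1", exons=((1, 300),))
        tags = extract_unique_tags([nm, nt])
        ev = ASEvent.from_id("G1_1_RI", (101, 200))
        assert match_tags_to_ase(tags, [ev]) == {"NR_1": ["G1_1_RI"]}

    def test_wrong_gene_gives_empty_mapping(self):
        nm = tx("NM_1", exons=((1, 100), (201, 300)))
        nt = tx("NR_1", exons=((1, 300),))
        tags = extract_unique_tags([nm, nt])
        ev = ASEvent.from_id("OTHER_1_RI", (101, 200))
        assert match_tags_to_ase(tags, [ev]) == {}

    def test_planted_correspondences_fully_recovered(self, dataset):
        """Every planted ntRNA-event correspondence in the synthetic cohort is
        recovered, with no spurious assignments."""
        ts = dataset.annotation.transcripts
        by_gene = {}
        for t in ts:
            by_gene.setdefault(t.gene_id, []).append(t)
        tags = []
        for g in sorted(by_gene):
            tags.extend(extract_unique_tags(by_gene[g]))
        mapping = match_tags_to_ase(tags, dataset.annotation.events)
        assert mapping == {tid: [ev] for tid, ev in
                           dataset.truth.event_map.items()}
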
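"""Contracts of the synthetic cohort generator: determinism, planted-truth
completeness, and calibration of planted effects."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ntriplenet.annotation import classify_transcripts
from ntriplenet.cerna import find_seed_sites
from ntriplenet.synthetic import (
    SyntheticConfig,
    generate_annotation,
    generate_clinical_survival,
    generate_dataset,
    generate_expression_and_psi,
    write_dataset,
)


def empirical_log2fc(matrix, feature):
    t = matrix.loc[feature, [c for c in matrix.columns if c.endswith("_01")]]
    n = matrix.loc[feature, [c for c in matrix.columns if c.endswith("_11")]]
    return np.log2((t.mean() + 1) / (n.mean() + 1))


class TestDeterminismAndFormats:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(seed=7, n_tumor=30, n_normal=10, n_genes=12)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(cfg), a)
        write_dataset(generate_dataset(cfg), b)
        files = sorted(p.name for p in a.glob("*"))
        assert files
        match, mismatch, errors = filecmp.cmpfiles(a, b, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_sample_ids_carry_type_suffixes(self, dataset):
        cols = dataset.expression.psi.columns
        assert all(c.endswith("_01") or c.endswith("_11") for c in cols)
        assert sum(c.endswith("_01") for c in cols) == dataset.config.n_tumor

    def test_value_ranges(self, dataset):
        psi = dataset.expression.psi.to_numpy()
        assert psi.min() >= 0 and psi.max() <= 1
        beta = dataset.beta.to_numpy()
        assert beta.min() >= 0 and beta.max() <= 1
        assert (dataset.immune.to_numpy() >= 0).all()

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(n_genes=0)
        with pytest.raises(ValueError):
            generate_clinical_survival(
                pd.DataFrame([[1.0, 2.0]], index=["f"]), {"f": 1.0},
                censoring_rate=1.0)
        with pytest.raises(KeyError):
            generate_clinical_survival(
                pd.DataFrame([[1.0, 2.0]], index=["f"]), {"ghost": 1.0})


class TestAnnotationContracts:
    def test_forced_nr_construction(self):
        ann = generate_annotation(n_genes=1, isoforms_per_gene=2, seed=7,
                                  ntrna_fraction=1.0, fraction_short=0.0)
        assert len(ann.ntrna_rules) == 1
        (tid,) = ann.ntrna_rules
        assert tid.startswith("NR_") and ann.ntrna_rules[tid] == "nr_prefix"

    def test_fraction_short_one_makes_every_ntrna_short(self):
        ann = generate_annotation(n_genes=8, seed=3, ntrna_fraction=1.0,
                                  fraction_short=1.0)
        by_gene = {}
        for t in ann.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gene, ts in by_gene.items():
            nm_len = max(t.length for t in ts
                         if t.transcript_id.startswith("NM_"))
            for t in ts:
                if t.transcript_id in ann.ntrna_rules:
                    assert t.length < 0.75 * nm_len

    def test_planted_rules_agree_with_classifier(self, dataset):
        cls = {c.transcript_id: c
               for c in classify_transcripts(dataset.annotation.transcripts)}
        for tid, rule in dataset.truth.ntrna_rules.items():
            assert cls[tid].is_ntrna and cls[tid].rule_fired == rule

    def test_planted_seed_sites_literally_present(self, dataset):
        ann = dataset.annotation
        for mid, target, stype, pos in dataset.truth.planted_seed_sites:
            seq = ann.ntrna_scan_seqs.get(target) or ann.lncrna_seqs[target]
            sites = find_seed_sites(ann.mirna_seqs[mid], seq, mid, target)
            assert (stype, pos) in {(s.site_type, s.position) for s in sites}


class TestPlantedEffects:
    def test_planted_and_null_log2fc_calibrated(self, dataset):
        truth = dataset.truth
        mirna = dataset.expression.mirna
        for feat, lfc in truth.planted_de["mirna"].items():
            assert empirical_log2fc(mirna, feat) == pytest.approx(lfc, abs=0.3)
        null = [f for f in mirna.index if f not in truth.planted_de["mirna"]]
        null_lfc = np.array([empirical_log2fc(mirna, f) for f in null])
        # nulls are unbiased; individual values scatter with the n=50
        # normal-group sampling noise but stay well below the planted effect
        assert abs(null_lfc.mean()) < 0.1
        assert np.abs(null_lfc).max() < 0.6

    def test_psi_de_planted_while_gene_stays_null(self, dataset):
        truth = dataset.truth
        psi, mrna = dataset.expression.psi, dataset.expression.mrna
        ev = truth.hub_event
        gene = ev.rsplit("_", 2)[0]
        t_cols = [c for c in psi.columns if c.endswith("_01")]
        n_cols = [c for c in psi.columns if c.endswith("_11")]
        assert psi.loc[ev, t_cols].mean() > 2 * psi.loc[ev, n_cols].mean()
        assert abs(empirical_log2fc(mrna, gene)) < 0.3

    def test_zero_variance_config_gives_equal_group_means(self):
        cfg = SyntheticConfig(n_genes=6, n_tumor=5, n_normal=5,
                              psi_logit_sd=0.0, expr_log_sd=0.0,
                              nb_dispersion=0.0, module_loading_expr=0.0,
                              module_loading_psi=0.0,
                              n_independent_ntrnas=2, n_network_mirnas=2,
                              n_network_lncrnas=2, n_lowexpr_features=0)
        ann = generate_annotation(cfg.n_genes, seed=0,
                                  ntrna_fraction=cfg.ntrna_fraction)
        expr = generate_expression_and_psi(ann, 5, 5, cfg, seed=0)
        m = expr.mrna
        null_genes = [g for g in m.index
                      if g not in expr.truth.planted_de["gene"]]
        assert null_genes
        t_cols = [c for c in m.columns if c.endswith("_01")]
        n_cols = [c for c in m.columns if c.endswith("_11")]
        assert np.allclose(m.loc[null_genes, t_cols].mean(axis=1),
                           m.loc[null_genes, n_cols].mean(axis=1))


class TestSurvivalGenerator:
    def feature_row(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame([rng.normal(size=n)], index=["f"],
                            columns=[f"s{i}" for i in range(n)])

    def test_zero_censoring_gives_all_events(self):
        feats = self.feature_row(100)
        clin = generate_clinical_survival(feats, {"f": 0.5},
                                          censoring_rate=0.0, seed=1)
        assert (clin["os_status"] == 1).all()

    def test_positive_coefficient_shortens_survival_of_high_expressers(self):
        feats = self.feature_row(4000, seed=2)
        clin = generate_clinical_survival(feats, {"f": 1.0},
                                          censoring_rate=0.0, seed=2)
        x = feats.loc["f"]
        hi = clin.loc[x > x.median(), "os_time"].median()
        lo = clin.loc[x <= x.median(), "os_time"].median()
        assert hi < lo

    def test_null_coefficients_give_uniform_logrank_p(self):
        """With no planted effect, median-split log-rank p-values over
        replicates behave like a uniform draw."""
        from ntriplenet.survival import km_logrank_by_median
        ps = []
        for rep in range(100):
            feats = self.feature_row(40, seed=200 + rep)
            clin = generate_clinical_survival(feats, {"f": 0.0},
                                              censoring_rate=0.2,
                                              seed=300 + rep)
            res = km_logrank_by_median(feats.loc["f"], clin["os_time"],
                                       clin["os_status"])
            ps.append(res.logrank_p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_clinical_categories_match_expected_levels(self, dataset):
        clin = dataset.clinical
        assert set(clin["grade"]) <= {"G1&G2", "G3&G4"}
        assert set(clin["t_stage"]) <= {"T1&T2", "T3&T4"}
        assert set(clin["m_stage"]) <= {"M0", "M1", "MX"}
        assert set(clin["n_stage"]) <= {"N0", "N1", "NX"}
        assert clin["age"].between(26, 90).all()


class TestTruthCompleteness:
    def test_every_planted_identifier_resolves(self, dataset):
        truth = dataset.truth
        expr = dataset.expression
        for f in truth.planted_de["mirna"]:
            assert f in expr.mirna.index
        for f in truth.planted_de["lncrna"]:
            assert f in expr.lncrna.index
        for ev in truth.independent_ntrnas:
            assert ev in expr.psi.index
        for f in truth.planted_prognostic:
            assert f in expr.psi.index or f in expr.mirna.index \
                or f in expr.lncrna.index
        for cell in truth.planted_immune:
            assert cell in dataset.immune.columns
        for probe in truth.planted_methyl:
            assert probe in dataset.beta.index

    def test_round_trip_preserves_matrices(self, dataset, data_dir):
        psi = pd.read_csv(Path(data_dir) / "ase_psi.tsv", sep="\t", index_col=0)
        psi = psi.drop(columns=["gene", "splice_type", "start", "end"])
        assert np.allclose(psi.to_numpy(),
                           dataset.expression.psi.to_numpy(), atol=1e-6)
        assert list(psi.columns) == list(dataset.expression.psi.columns)
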
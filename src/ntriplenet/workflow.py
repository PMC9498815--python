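"""End-to-end orchestration: classification, tag/event matching, differential
selection, network assembly, modules, hubs, risk models, prognosis and
methylation, under one config and one seed.

Sample groups come from TCGA-style barcode suffixes ("_01" tumor, "_11"
normal).  Patients are split 4:1 into training and test sets once, before any
model fitting; all models are fit on the training set only and evaluated on
both.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import centrality as cent_mod
from . import cerna, coexpression, differential, immune as imm_mod, methylation
from . import prognosis as prog_mod
from . import survival as surv_mod
from .synthetic import read_fasta


def parse_groups(sample_ids) -> pd.Series:
    """Tumor/normal labels from barcode suffixes ('_01' / '_11')."""
    def lab(s):
        if s.endswith("_01"):
            return "tumor"
        if s.endswith("_11"):
            return "normal"
        raise ValueError(f"sample id {s!r} has no recognized type suffix")
    return pd.Series({s: lab(s) for s in sample_ids})


def split_samples(sample_ids, train_fraction: float = 0.8,
                  stratify_by: pd.Series | None = None,
                  seed: int = 0) -> tuple[list, list]:
    """Random train/test split; |train| = round(n * train_fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction must be in (0, 1)")
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    n_train = round(len(ids) * train_fraction)
    if stratify_by is None:
        perm = rng.permutation(len(ids))
        train_idx = set(perm[:n_train])
        train = [s for i, s in enumerate(ids) if i in train_idx]
        test = [s for i, s in enumerate(ids) if i not in train_idx]
        return train, test
    strat = stratify_by.reindex(ids)
    train = []
    for _, grp in strat.groupby(strat, sort=True):
        members = list(grp.index)
        k = round(len(members) * train_fraction)
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:k])
    train_set = set(train)
    # round per-stratum counts can drift by one; repair to the global target
    rest = [s for s in ids if s not in train_set]
    while len(train) > n_train:
        rest.append(train.pop())
    while len(train) < n_train and rest:
        train.append(rest.pop())
    train_set = set(train)
    return [s for s in ids if s in train_set], [s for s in ids if s not in train_set]


def total_retained(per_class_counts: dict) -> int:
    """Total features kept after the low-expression filter, across classes."""
    return int(sum(per_class_counts.values()))


def summarize_categories(values: pd.Series) -> pd.DataFrame:
    """Counts and percentages (one decimal) per category, as in a cohort table."""
    counts = values.value_counts()
    return pd.DataFrame(
        {"n": counts, "percent": (100.0 * counts / counts.sum()).round(1)}
    )


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    seed: int = 0
    split_ratio: float = 0.8
    zero_fraction_threshold: float = 0.6
    ntrna_fdr_percentile: float = 10.0
    gene_fdr_percentile: float = 50.0
    de_fdr_max: float = 0.05
    de_abs_log2fc_min: float = 1.0
    wgcna_min_module_size: int = 10
    wgcna_merge_threshold: float = 0.85
    wgcna_r2_target: float = 0.85
    hub_top_k: int = 15
    lasso_cv_folds: int = 5
    horizons: tuple = (1.0, 3.0, 5.0)
    auc_horizon: float = 3.0
    stratify_split: bool = False


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_inputs(data_dir) -> dict:
    d = Path(data_dir)
    ase = pd.read_csv(d / "ase_psi.tsv", sep="\t", index_col=0)
    meta_cols = ["gene", "splice_type", "start", "end"]
    inputs = {
        "transcripts": ann_mod.read_gtf(d / "annotation.gtf"),
        "ntrna_regions": read_fasta(d / "ntrna_regions.fa"),
        "mirna_seqs": read_fasta(d / "mirnas.fa"),
        "lncrna_seqs": read_fasta(d / "lncrnas.fa"),
        "mrna": pd.read_csv(d / "expr_mrna.tsv", sep="\t", index_col=0),
        "mirna": pd.read_csv(d / "expr_mirna.tsv", sep="\t", index_col=0),
        "lncrna": pd.read_csv(d / "expr_lncrna.tsv", sep="\t", index_col=0),
        "event_meta": ase[meta_cols],
        "psi": ase.drop(columns=meta_cols),
        "clinical": pd.read_csv(d / "clinical.tsv", sep="\t", index_col=0),
        "immune": pd.read_csv(d / "immune.tsv", sep="\t", index_col=0),
        "beta": pd.read_csv(d / "methylation_beta.tsv", sep="\t", index_col=0),
        "probe_map": pd.read_csv(d / "probe_map.tsv", sep="\t", index_col=0)[
            "event_id"].to_dict(),
        "dnmt": pd.read_csv(d / "dnmt_expr.tsv", sep="\t", index_col=0),
        "_hashes": {p.name: _hash_file(p) for p in sorted(d.glob("*"))
                    if p.is_file()},
    }
    return inputs


def run_full_pipeline(config: PipelineConfig, upto: str | None = None) -> dict:
    """Execute all stages (or stop after ``upto``); returns and writes a
    structured run report.

    A stage failure is recorded with its error and all downstream stages are
    skipped; the report always serializes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config.data_dir)
    report: dict = {
        "config": asdict(config),
        "input_hashes": inputs["_hashes"],
        "stages": {},
        "counts": {},
    }
    state: dict = {"inputs": inputs}
    stages = [
        ("classify_and_match", _stage_classify),
        ("differential_selection", _stage_differential),
        ("triple_network", _stage_network),
        ("coexpression_modules", _stage_modules),
        ("hub_selection", _stage_hubs),
        ("gene_risk_model", _stage_gene_risk),
        ("immune_risk_model", _stage_immune),
        ("prognostic_model", _stage_prognosis),
        ("methylation", _stage_methylation),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            fn(state, config, report, out)
            report["stages"][name] = {"status": "ok"}
        except Exception as exc:  # structured failure path
            report["stages"][name] = {"status": "error", "error": str(exc),
                                      "error_type": type(exc).__name__}
            failed = True
        if name == upto:
            break
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    raise TypeError(f"not serializable: {type(x)}")


# --- stages ----------------------------------------------------------------

def _stage_classify(state, cfg, report, out):
    inputs = state["inputs"]
    transcripts = inputs["transcripts"]
    classifications = ann_mod.classify_transcripts(transcripts)
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    cls_by_gene = {c.transcript_id: c for c in classifications}
    tags = []
    for gene, ts in sorted(by_gene.items()):
        tags.extend(ann_mod.extract_unique_tags(
            ts, [cls_by_gene[t.transcript_id] for t in ts]))
    events = [
        ann_mod.ASEvent.from_id(eid, (int(row["start"]), int(row["end"])))
        for eid, row in inputs["event_meta"].iterrows()
    ]
    mapping = ann_mod.match_tags_to_ase(tags, events)
    state.update(classifications=classifications, tags=tags, event_map=mapping)
    ann_mod.classification_frame(classifications).to_csv(
        out / "classification.tsv", sep="\t", index=False)
    ann_mod.tag_frame(tags).to_csv(out / "ntrna_tags.tsv", sep="\t", index=False)
    report["counts"]["ntrna_transcripts"] = sum(c.is_ntrna for c in classifications)
    report["counts"]["unique_tags"] = len(tags)
    report["counts"]["matched_ntrnas"] = len(mapping)


def _stage_differential(state, cfg, report, out):
    inputs = state["inputs"]
    fl = lambda m: differential.filter_low_expressed(m, cfg.zero_fraction_threshold)
    mrna, mirna, lncrna = fl(inputs["mrna"]), fl(inputs["mirna"]), fl(inputs["lncrna"])
    groups = parse_groups(inputs["psi"].columns)
    de = {
        "gene": differential.de_stats(mrna, groups),
        "mirna": differential.de_stats(mirna, groups),
        "lncrna": differential.de_stats(lncrna, groups),
    }
    matched_events = sorted({e for evs in state["event_map"].values() for e in evs})
    psi_matched = inputs["psi"].loc[matched_events]
    de["ntrna"] = differential.de_stats(
        psi_matched, groups, pseudocount=differential.PSI_PSEUDOCOUNT)

    tid_to_gene = {t.transcript_id: t.gene_id for t in inputs["transcripts"]}
    event_to_gene = {}
    for tid, evs in state["event_map"].items():
        for ev in evs:
            event_to_gene[ev] = tid_to_gene[tid]
    selected_ntrnas = differential.select_independent_ntrnas(
        de["ntrna"], de["gene"], event_to_gene,
        cfg.ntrna_fdr_percentile, cfg.gene_fdr_percentile, cfg.de_abs_log2fc_min)
    de_mirnas = differential.select_de_features(
        de["mirna"], cfg.de_fdr_max, cfg.de_abs_log2fc_min)
    de_lncrnas = differential.select_de_features(
        de["lncrna"], cfg.de_fdr_max, cfg.de_abs_log2fc_min)
    state.update(de=de, groups=groups, selected_ntrnas=selected_ntrnas,
                 de_mirnas=de_mirnas, de_lncrnas=de_lncrnas,
                 event_to_gene=event_to_gene)
    for k, tbl in de.items():
        tbl.to_csv(out / f"de_{k}.tsv", sep="\t", float_format="%.6g")
    report["counts"].update(
        retained_features={"gene": len(mrna), "mirna": len(mirna),
                           "lncrna": len(lncrna)},
        retained_total=total_retained(
            {"gene": len(mrna), "mirna": len(mirna), "lncrna": len(lncrna)}),
        independent_ntrnas=len(selected_ntrnas),
        de_mirnas=len(de_mirnas),
        de_lncrnas=len(de_lncrnas),
    )
    report["selected_ntrnas"] = selected_ntrnas


def _stage_network(state, cfg, report, out):
    inputs = state["inputs"]
    if not state["selected_ntrnas"] or not state["de_mirnas"]:
        raise ValueError("empty differential selection: no features to build "
                         "the triple network from")
    event_to_tid = {}
    for tid, evs in state["event_map"].items():
        for ev in evs:
            event_to_tid.setdefault(ev, tid)
    mirna_seqs = {m: inputs["mirna_seqs"][m] for m in state["de_mirnas"]}
    ntrna_seqs = {ev: inputs["ntrna_regions"].get(event_to_tid[ev])
                  for ev in state["selected_ntrnas"]}
    lnc_seqs = {l: inputs["lncrna_seqs"].get(l) for l in state["de_lncrnas"]}
    layer1 = cerna.build_layer_pairs(mirna_seqs, ntrna_seqs, "ntrna_mirna")
    layer2 = cerna.build_layer_pairs(mirna_seqs, lnc_seqs, "mirna_lncrna")
    net = cerna.assemble_triple_network(layer1, layer2)
    state.update(network=net, layer1=layer1, layer2=layer2)
    cerna.edge_list_frame(net).to_csv(out / "triple_network_edges.tsv",
                                      sep="\t", index=False)
    report["counts"].update(
        ntrna_mirna_pairs=len(layer1), mirna_lncrna_pairs=len(layer2),
        network_edges=net.n_edges,
        network_nodes={"ntrna": len(net.ntrnas), "mirna": len(net.mirnas),
                       "lncrna": len(net.lncrnas)},
    )


def _stage_modules(state, cfg, report, out):
    inputs = state["inputs"]
    tumor = [s for s in inputs["psi"].columns if state["groups"][s] == "tumor"]
    feats = pd.concat(
        [
            inputs["psi"].loc[state["selected_ntrnas"], tumor],
            np.log2(inputs["mirna"].loc[state["de_mirnas"], tumor] + 1),
            np.log2(inputs["lncrna"].loc[state["de_lncrnas"], tumor] + 1),
        ]
    )
    feats = coexpression.drop_constant_features(feats)
    beta = coexpression.pick_soft_threshold(feats, r2_target=cfg.wgcna_r2_target,
                                            fallback_power=6)
    tom = coexpression.tom_similarity(feats, beta)
    modules = coexpression.detect_modules(
        tom, feats, cfg.wgcna_min_module_size, cfg.wgcna_merge_threshold,
        power_used=beta)
    clin = inputs["clinical"].loc[tumor]
    traits = pd.DataFrame(
        {
            "os_status": clin["os_status"].astype(float),
            "os_time": clin["os_time"].astype(float),
            "stage": (clin["t_stage"] == "T3&T4").astype(float),
        }
    )
    trait_tbl, key = coexpression.module_trait_correlation(modules, traits)
    state.update(modules=modules, key_module=key, wgcna_features=feats,
                 tumor_samples=tumor)
    trait_tbl.to_csv(out / "module_trait_cor.tsv", sep="\t", index=False,
                     float_format="%.6g")
    pd.DataFrame(
        [{"feature": f, "module": m.label} for m in modules for f in m.members]
    ).to_csv(out / "module_membership.tsv", sep="\t", index=False)
    report["counts"]["modules"] = sum(m.label != "grey" for m in modules)
    report["soft_threshold_power"] = beta
    report["key_module"] = key


def _stage_hubs(state, cfg, report, out):
    if state["key_module"] is None:
        raise ValueError("no key module identified")
    members = set(next(m.members for m in state["modules"]
                       if m.label == state["key_module"]))
    sub = state["network"].graph.subgraph(
        members & set(state["network"].graph.nodes))
    if sub.number_of_nodes() == 0:
        raise ValueError("key module shares no nodes with the triple network")
    table = cent_mod.compute_centralities(sub, seed=cfg.seed)
    hubs = cent_mod.select_hub_nodes(table, cfg.hub_top_k)
    state.update(centrality=table, hubs=hubs)
    table.to_csv(out / "centrality.tsv", sep="\t", float_format="%.6g")
    report["hub_nodes"] = sorted(hubs)
    report["counts"]["hub_nodes"] = len(hubs)
    report["counts"]["key_module_network_nodes"] = sub.number_of_nodes()


def _stage_gene_risk(state, cfg, report, out):
    inputs = state["inputs"]
    tumor = state["tumor_samples"]
    clin = inputs["clinical"].loc[tumor]
    train, test = split_samples(tumor, cfg.split_ratio,
                                clin["os_status"] if cfg.stratify_split else None,
                                cfg.seed)
    X = state["wgcna_features"].loc[sorted(state["hubs"])].T  # samples x features
    model = surv_mod.lasso_cox_fit(
        X.loc[train], clin.loc[train, "os_time"], clin.loc[train, "os_status"],
        cv_folds=cfg.lasso_cv_folds, seed=cfg.seed)
    scores = surv_mod.risk_score(model, X)
    risk_groups = surv_mod.median_split(scores, model.median_cutoff)
    km_train = surv_mod.km_logrank(risk_groups[train], clin.loc[train, "os_time"],
                                   clin.loc[train, "os_status"])
    km_test = surv_mod.km_logrank(risk_groups[test], clin.loc[test, "os_time"],
                                  clin.loc[test, "os_status"])
    state.update(train=train, test=test, gene_model=model, gene_scores=scores,
                 gene_risk_groups=risk_groups, clin=clin)
    report["gene_model"] = {"features": model.features,
                            "coefficients": model.coefficients,
                            "lambda": model.lam,
                            "median_cutoff": model.median_cutoff}
    report["counts"]["train_samples"] = len(train)
    report["counts"]["test_samples"] = len(test)
    report["gene_km"] = {"train_logrank_p": km_train.logrank_p,
                         "test_logrank_p": km_test.logrank_p}


def _stage_immune(state, cfg, report, out):
    inputs = state["inputs"]
    train = state["train"]
    clin = state["clin"]
    immune = inputs["immune"].loc[train]
    os_screen = imm_mod.screen_os_associated(
        immune, clin.loc[train, "os_time"], clin.loc[train, "os_status"])
    de_screen = imm_mod.screen_riskgroup_de(
        immune, state["gene_risk_groups"][train])
    model, both = imm_mod.intersect_and_fit(
        os_screen, de_screen, immune,
        clin.loc[train, "os_time"], clin.loc[train, "os_status"], seed=cfg.seed,
        cv_folds=cfg.lasso_cv_folds)
    scores = surv_mod.risk_score(model, inputs["immune"].loc[state["tumor_samples"]])
    groups = surv_mod.median_split(scores, model.median_cutoff)
    state.update(immune_model=model, immune_scores=scores,
                 immune_risk_groups=groups, immune_screens=(os_screen, de_screen))
    report["immune_model"] = {"screened_both": both,
                              "features": model.features,
                              "coefficients": model.coefficients}
    report["counts"]["os_associated_cells"] = int(os_screen["selected"].sum())
    report["counts"]["riskgroup_de_cells"] = int(de_screen["selected"].sum())
    report["counts"]["cells_both"] = len(both)


def _stage_prognosis(state, cfg, report, out):
    clin = state["clin"]
    train, test = state["train"], state["test"]
    design = pd.DataFrame(
        {
            "risk_gene_high": (state["gene_risk_groups"] == "high").astype(float),
            "risk_immune_high": (state["immune_risk_groups"] == "high").astype(float),
            "grade_high": (clin["grade"] == "G3&G4").astype(float),
            "age": clin["age"].astype(float),
            "t34": (clin["t_stage"] == "T3&T4").astype(float),
            "m1": (clin["m_stage"] == "M1").astype(float),
            "n1": (clin["n_stage"] == "N1").astype(float),
        }
    )
    model = prog_mod.multivariate_cox(
        design.loc[train], clin.loc[train, "os_time"], clin.loc[train, "os_status"])
    horizons = [t for t in cfg.horizons if t <= model.max_time]
    nomo = prog_mod.build_nomogram(model, times=tuple(horizons))
    lp = model.linear_predictor(design)
    disc = {}
    for name, ids in (("train", train), ("test", test)):
        disc[name] = prog_mod.model_discrimination(
            lp[ids], clin.loc[ids, "os_time"], clin.loc[ids, "os_status"],
            horizon=cfg.auc_horizon,
            train=(clin.loc[train, "os_time"], clin.loc[train, "os_status"]))
    cal_t = min(cfg.auc_horizon, model.max_time)
    cal = prog_mod.calibration_table(
        model.predict_survival(design.loc[train], cal_t),
        clin.loc[train, "os_time"], clin.loc[train, "os_status"], cal_t)
    state.update(cox_model=model, nomogram=nomo)
    model.summary.to_csv(out / "multivariate_cox.tsv", sep="\t",
                         float_format="%.6g")
    nomo.total_points_table.to_csv(out / "nomogram_points.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    cal.to_csv(out / "calibration.tsv", sep="\t", index=False,
               float_format="%.6g")
    report["multivariate_cox"] = {
        c: {"hr": float(model.summary.loc[c, "hr"]),
            "p": float(model.summary.loc[c, "p_value"])}
        for c in model.covariates
    }
    report["discrimination"] = disc


def _stage_methylation(state, cfg, report, out):
    inputs = state["inputs"]
    psi = inputs["psi"].loc[state["selected_ntrnas"]]
    dnmt_tbl = methylation.dnmt_group_test(inputs["dnmt"], psi)
    cor_tbl = methylation.probe_correlations(inputs["beta"], inputs["psi"],
                                             inputs["probe_map"])
    clin_all = inputs["clinical"]
    surv_tbl = methylation.probe_survival(
        inputs["beta"], clin_all["os_time"], clin_all["os_status"])
    keys = methylation.key_methylation_sites(cor_tbl, surv_tbl)
    for name, tbl in (("dnmt_tests", dnmt_tbl), ("probe_correlations", cor_tbl),
                      ("probe_survival", surv_tbl)):
        tbl.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    report["key_methylation_sites"] = keys
    report["counts"]["key_methylation_sites"] = len(keys)
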
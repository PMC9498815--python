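"""Synthetic multi-omic dataset generator with machine-readable planted truth.

Emulates the inputs the pipeline consumes — two-source transcript annotation,
miRNA/lncRNA/target sequences, tumor+normal expression matrices, a
SpliceSeq-style PSI table, clinical survival, immune-cell abundances and a
methylation beta matrix — at desk scale, planting:

* ntRNA isoforms satisfying exactly one classification rule each, with a
  unique splice feature realized as a named splicing event;
* differential expression (mean log2 fold changes) for chosen features, with
  "independent" ntRNAs whose event PSI is differential while their host
  gene's overall expression is not;
* literal miRNA seed sites (8mers) in target sequences, with all other seed
  cores scrubbed so the planted pair set is exactly recoverable;
* two correlated feature blocks (latent factors) for module detection, one of
  which drives survival;
* proportional-hazards survival with known coefficients, plus four immune
  cells carrying prognostic signal;
* methylation probes negatively correlated with hub ntRNA PSI.

Counts use a log-normal signal on negative-binomial noise; PSI is
logistic-normal.  Identical seed and config give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import ASEvent, TranscriptModel, write_gtf

IMMUNE_CELLS = [
    "Bcell", "CD4_T", "CD8_T", "DC", "Monocyte", "Macrophage", "NK", "Neutrophil",
    "Tc", "Tex", "Tcm", "Tem", "Tfh", "Tgd", "Th1", "Th2", "Th17", "Tr1",
    "iTreg", "nTreg", "MAIT", "NKT", "Gamma_delta", "CD4_naive",
]

_VARIANT_FOR_RULE = {
    "nr_prefix": "retained_intron",
    "not_protein_coding": "alt_promoter",
    "no_ccds": "alt_donor",
    "short_75pct": "double_skip",
}
_EVENT_TYPE_FOR_VARIANT = {
    "retained_intron": "RI",
    "alt_promoter": "AP",
    "alt_donor": "AD",
    "double_skip": "ES",
}


@dataclass
class SyntheticConfig:
    """Default study conditions for the synthetic cohort."""

    n_genes: int = 40
    isoforms_per_gene: int = 2
    ntrna_fraction: float = 0.75
    fraction_short: float = 0.25
    n_tumor: int = 250
    n_normal: int = 50
    n_mirnas: int = 30
    n_lncrnas: int = 60
    n_de_mirnas: int = 10
    n_de_lncrnas: int = 25
    n_independent_ntrnas: int = 8
    n_network_mirnas: int = 5
    n_network_lncrnas: int = 22
    de_log2fc: float = 2.0
    hub_psi_log2fc: float = 2.5
    other_psi_log2fc: float = 1.6    # non-hub independent ntRNAs
    gene_de_log2fc: float = 1.5      # the truly-DE background gene population
    base_psi: float = 0.12
    psi_logit_sd: float = 0.4
    expr_log_sd: float = 0.4
    nb_dispersion: float = 0.05
    module_loading_expr: float = 1.0
    module_loading_psi: float = 0.6
    prognostic_coefs: dict = field(default_factory=lambda: {
        "__hub_event__": 0.8, "__hub_mirna__": 0.6, "__hub_lncrna__": 0.5,
    })
    immune_coefs: dict = field(default_factory=lambda: {
        "Tex": 0.5, "iTreg": 0.4, "Th1": 0.3, "Tcm": -0.5,
    })
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.12    # events per year at linear predictor 0
    followup_cap_years: float = 12.0
    methyl_target_r: float = -0.6
    n_null_probes: int = 6
    n_lowexpr_features: int = 5
    seed: int = 0


@dataclass
class SyntheticTruth:
    planted_de: dict            # class -> {feature: log2fc}
    planted_seed_sites: list    # (mirna, target, site_type, 1-based position)
    planted_modules: dict       # feature -> module label
    planted_prognostic: dict    # feature -> log-hazard coefficient (z scale)
    planted_immune: dict        # cell -> coefficient
    planted_methyl: dict        # probe -> [event_id, target r]
    event_map: dict             # ntRNA transcript -> event id
    independent_ntrnas: list    # event ids planted gene-independent DE
    hub_event: str
    ntrna_rules: dict           # transcript -> planted classification rule
    low_expressed: list
    rng_seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _scrub(seq: str, cores: set[str], rng) -> str:
    """Mutate bases until no forbidden 6-mer core remains."""
    s = list(seq)
    for _ in range(200):
        hit = None
        text = "".join(s)
        for p in range(len(s) - 5):
            if text[p : p + 6] in cores:
                hit = p
                break
        if hit is None:
            return text
        s[hit + int(rng.integers(0, 6))] = "ACGT"[int(rng.integers(0, 4))]
    raise RuntimeError("could not scrub sequence of seed cores")


def _plant_sites(seq: str, sites: list[str], all_cores: set[str],
                 own_cores: set[str], rng) -> tuple[str, list[int]]:
    """Overwrite ``seq`` with the given site subsequences at fixed,
    non-overlapping slots, then scrub any accidental core of a non-planted
    miRNA (never touching a planted region).  Returns (sequence, 1-based
    positions)."""
    slot = max(12, (len(seq) - 10) // max(len(sites), 1))
    if slot < 12:
        raise ValueError("target sequence too short for the requested sites")
    s = list(seq)
    positions, protected = [], set()
    for t, site in enumerate(sites):
        pos = 4 + t * slot
        s[pos : pos + len(site)] = site
        positions.append(pos + 1)
        protected.update(range(pos, pos + len(site)))
    forbidden = all_cores - own_cores
    for _ in range(200):
        text = "".join(s)
        hit = None
        for p in range(len(s) - 5):
            if text[p : p + 6] in forbidden:
                hit = p
                break
        if hit is None:
            return text, positions
        editable = [q for q in range(hit, hit + 6) if q not in protected]
        if not editable:
            raise RuntimeError("forbidden core inside a planted site")
        q = editable[int(rng.integers(0, len(editable)))]
        s[q] = "ACGT"[int(rng.integers(0, 4))]
    raise RuntimeError("could not scrub accidental seed cores")


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    transcripts: list
    ntrna_rules: dict          # transcript -> rule
    ntrna_variant: dict        # transcript -> variant kind
    events: list               # ASEvent catalog (PSI filled later)
    event_map: dict            # ntRNA transcript -> event id
    ntrna_scan_seqs: dict      # ntRNA transcript -> scan-region sequence
    mirna_seqs: dict
    lncrna_seqs: dict
    mirna_ids: list
    lncrna_ids: list


def generate_annotation(
    n_genes: int = 40,
    isoforms_per_gene: int = 2,
    seed: int = 0,
    ntrna_fraction: float = 0.75,
    fraction_short: float = 0.25,
    n_mirnas: int = 30,
    n_lncrnas: int = 60,
) -> AnnotationBundle:
    """Two-source transcript models plus sequences and a splicing-event catalog.

    Each gene gets one (or more) RefSeq NM isoform of six 200-nt exons; a
    ``ntrna_fraction`` of genes additionally carry one ntRNA isoform
    satisfying exactly one classification rule, realized through one unique
    splice feature whose corresponding splicing event enters the catalog.
    Genes without an ntRNA contribute a decoy event in intron 3.
    """
    if n_genes < 1 or isoforms_per_gene < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))

    rules = list(_VARIANT_FOR_RULE)
    n_nt = round(ntrna_fraction * n_genes)
    n_short = round(fraction_short * n_nt)

    transcripts, ntrna_rules, ntrna_variant, events, event_map = [], {}, {}, [], {}
    for i in range(n_genes):
        gene = f"G{i + 1:03d}"
        off = i * 100_000 + 1
        exons = [(off + 500 * j, off + 500 * j + 199) for j in range(6)]
        nm = TranscriptModel(f"NM_{i + 1:06d}", gene, "refseq", "protein_coding",
                             f"CCDS{i + 1}", "+", tuple(exons))
        transcripts.append(nm)
        for extra in range(isoforms_per_gene - 2):
            transcripts.append(
                TranscriptModel(f"NM_{i + 1:06d}_{extra + 2}", gene, "refseq",
                                "protein_coding", f"CCDS{i + 1}", "+", tuple(exons))
            )
        if i < n_nt:
            rule = rules[i % 4]
            variant = "double_skip" if i < n_short else _VARIANT_FOR_RULE[rule]
            if rule == "short_75pct":
                variant = "double_skip"
            v_exons, ev_iv = _variant_exons(exons, variant)
            tid, src, biotype, ccds = _ntrna_identity(i, rule)
            transcripts.append(
                TranscriptModel(tid, gene, src, biotype, ccds, "+", tuple(v_exons))
            )
            ntrna_rules[tid] = rule
            ntrna_variant[tid] = variant
            ev_id = f"{gene}_{10000 + i}_{_EVENT_TYPE_FOR_VARIANT[variant]}"
            events.append(ASEvent.from_id(ev_id, ev_iv))
            event_map[tid] = ev_id
        else:
            stype = ["ES", "RI", "AA", "AT"][i % 4]
            iv = (exons[3][1] + 50, exons[3][1] + 120)  # inside intron 4
            events.append(ASEvent.from_id(f"{gene}_{20000 + i}_{stype}", iv))

    mirna_ids = [f"hsa-miR-{100 + i}-5p" for i in range(n_mirnas)]
    lncrna_ids = [f"LNC{i + 1:04d}" for i in range(n_lncrnas)]
    # draw miRNAs whose seed cores neither collide nor occur inside another
    # miRNA's planted 8mer site string (so planted sites stay unambiguous)
    mirna_seqs, cores, site_strs = {}, set(), []
    for mid in mirna_ids:
        while True:
            s = _random_seq(rng, 22)
            core = _revcomp(s[1:7])
            site = _revcomp(s[1:8]) + "A"
            if core in cores:
                continue
            if any(c in site for c in cores):
                continue
            if any(core in prev for prev in site_strs):
                continue
            break
        cores.add(core)
        site_strs.append(site)
        mirna_seqs[mid] = s.replace("T", "U")

    scan = {tid: _scrub(_random_seq(rng, 300), cores, rng) for tid in ntrna_rules}
    lnc = {lid: _scrub(_random_seq(rng, 400), cores, rng) for lid in lncrna_ids}
    return AnnotationBundle(transcripts, ntrna_rules, ntrna_variant, events,
                            event_map, scan, mirna_seqs, lnc, mirna_ids, lncrna_ids)


def _variant_exons(exons, variant):
    if variant == "retained_intron":
        merged = (exons[1][0], exons[2][1])
        v = [exons[0], merged] + exons[3:]
        iv = (exons[1][1] + 1, exons[2][0] - 1)
    elif variant == "double_skip":
        v = [exons[0], exons[1]] + exons[4:]
        iv = exons[2]  # the (first) skipped exon
    elif variant == "alt_promoter":
        novel = (exons[0][1] + 51, exons[0][1] + 150)  # inside intron 1
        v = [novel] + exons[1:]
        iv = novel
    elif variant == "alt_donor":
        ext = (exons[1][0], exons[1][1] + 50)
        v = [exons[0], ext] + exons[2:]
        iv = ext
    else:
        raise ValueError(variant)
    return v, iv


def _ntrna_identity(i, rule):
    if rule == "nr_prefix":
        return f"NR_{i + 1:06d}", "refseq", "misc_RNA", None
    if rule == "not_protein_coding":
        return f"ENST{i + 1:08d}", "ensembl", "processed_transcript", None
    if rule == "no_ccds":
        return f"ENST{i + 1:08d}", "ensembl", "protein_coding", None
    return f"ENST{i + 1:08d}", "ensembl", "protein_coding", f"CCDS{i + 1}"


# ---------------------------------------------------------------------------
# expression + PSI
# ---------------------------------------------------------------------------

def tumor_normal_ids(n_tumor: int, n_normal: int) -> tuple[list[str], list[str]]:
    t = [f"TCGA_{i + 1:04d}_01" for i in range(n_tumor)]
    n = [f"TCGA_{i + 1:04d}_11" for i in range(n_normal)]
    return t, n


def _nb_counts(rng, mean, dispersion):
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return mean
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean)).astype(float)


@dataclass
class ExpressionBundle:
    mrna: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    psi: pd.DataFrame            # events x samples
    event_meta: pd.DataFrame     # event id, gene, splice type, interval
    factors: pd.DataFrame        # tumor-sample latent module factors
    truth: SyntheticTruth


def generate_expression_and_psi(
    ann: AnnotationBundle,
    n_tumor: int = 250,
    n_normal: int = 50,
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> ExpressionBundle:
    """Expression matrices, the PSI table, and the full planted truth.

    Tumor samples carry two latent factors defining the planted coexpression
    blocks; the first block (hub event, hub miRNA/lncRNA partners) later
    drives survival.  Planted log2 fold changes act on group means.
    """
    cfg = config or SyntheticConfig()
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    t_ids, n_ids = tumor_normal_ids(n_tumor, n_normal)
    samples = t_ids + n_ids
    is_tumor = np.array([1] * n_tumor + [0] * n_normal)

    factors = pd.DataFrame(
        {"f1": rng.normal(size=n_tumor), "f2": rng.normal(size=n_tumor)},
        index=t_ids,
    )
    f_all = pd.DataFrame(0.0, index=samples, columns=["f1", "f2"])
    f_all.loc[t_ids] = factors

    # --- network / module layout --------------------------------------------
    nt_events = [ann.event_map[t] for t in sorted(ann.event_map)]
    if len(nt_events) < cfg.n_independent_ntrnas:
        raise ValueError("annotation has too few ntRNA events for the config")
    indep = nt_events[: cfg.n_independent_ntrnas]
    hub_event = indep[0]
    net_mirnas = ann.mirna_ids[: cfg.n_network_mirnas]
    de_mirnas = ann.mirna_ids[: cfg.n_de_mirnas]
    net_lncrnas = ann.lncrna_ids[: cfg.n_network_lncrnas]
    de_lncrnas = ann.lncrna_ids[: cfg.n_de_lncrnas]

    modules: dict[str, str] = {}
    m1 = indep[:2] + net_mirnas[:2] + net_lncrnas[:10]
    m2 = indep[2:4] + net_mirnas[2:4] + net_lncrnas[10:22]
    for f in m1:
        modules[f] = "block1"
    for f in m2:
        modules[f] = "block2"
    loading = {}
    for f in m1:
        loading[f] = ("f1", 1.0)
    for f in m2:
        loading[f] = ("f2", 1.0)

    # --- planted seed sites ---------------------------------------------------
    ev_to_tid = {v: k for k, v in ann.event_map.items()}
    seed_sites = []
    scan_seqs = dict(ann.ntrna_scan_seqs)
    lnc_seqs = dict(ann.lncrna_seqs)
    core_of = {m: _revcomp(s.replace("U", "T")[1:7])
               for m, s in ann.mirna_seqs.items()}
    all_cores = set(core_of.values())
    rng_sites = np.random.default_rng(np.random.SeedSequence([seed, 33]))

    plan: dict[tuple[str, str], list[str]] = {}  # (kind, target) -> miRNA ids
    plan[("nt", ev_to_tid[hub_event])] = list(net_mirnas)
    for k, ev in enumerate(indep[1:], start=1):
        plan.setdefault(("nt", ev_to_tid[ev]), []).append(
            net_mirnas[k % cfg.n_network_mirnas])
    for j, mid in enumerate(net_mirnas):
        for t in range(8):
            lnc_id = net_lncrnas[(8 * j + t) % cfg.n_network_lncrnas]
            plan.setdefault(("lnc", lnc_id), []).append(mid)

    for (kind, tid), mids in plan.items():
        target_seqs = scan_seqs if kind == "nt" else lnc_seqs
        mids = sorted(set(mids))
        sites = [
            _revcomp(ann.mirna_seqs[m].replace("U", "T")[1:8]) + "A"  # 8mer
            for m in mids
        ]
        target_seqs[tid], positions = _plant_sites(
            target_seqs[tid], sites, all_cores, {core_of[m] for m in mids},
            rng_sites)
        for m, pos in zip(mids, positions):
            seed_sites.append((m, tid, "8mer", pos))

    # --- expression matrices --------------------------------------------------
    def expr_matrix(ids, de: dict, prefix_rng):
        base = np.exp(prefix_rng.normal(np.log(300.0), 0.6, len(ids)))
        rows = []
        for g, b in zip(ids, base):
            lfc = de.get(g, 0.0)
            load = loading.get(g)
            shift = 0.0
            if load:
                w = cfg.module_loading_expr
                # lognormal mean correction: the factor acts on tumor samples
                # only and must not bias the tumor group mean
                shift = w * f_all[load[0]].to_numpy() - 0.5 * w**2 * is_tumor
            log_mu = (np.log(b) + np.log(2.0) * lfc * is_tumor + shift
                      + prefix_rng.normal(0, cfg.expr_log_sd, len(samples)))
            rows.append(_nb_counts(prefix_rng, np.exp(log_mu), cfg.nb_dispersion))
        return pd.DataFrame(rows, index=ids, columns=samples)

    rng_e = np.random.default_rng(np.random.SeedSequence([seed, 44]))
    gene_ids = sorted({t.gene_id for t in ann.transcripts})
    # a realistic gene population mixes DE and non-DE genes (the median-FDR
    # rule presumes that); hosts of the planted independent events stay null
    host_genes = {ev.rsplit("_", 2)[0] for ev in indep}
    gene_de = {}
    for gi, g in enumerate(g for g in gene_ids if g not in host_genes):
        if gi % 3 != 2:  # two thirds of non-host genes are DE
            gene_de[g] = cfg.gene_de_log2fc if gi % 2 == 0 else -cfg.gene_de_log2fc
    mrna = expr_matrix(gene_ids, gene_de, rng_e)
    # low-expression decoys: zero in ~70% of samples
    for k in range(cfg.n_lowexpr_features):
        on = rng_e.random(len(samples)) > 0.7
        mrna.loc[f"LOWEXP{k + 1}"] = np.where(on, rng_e.poisson(20, len(samples)), 0)
    low_expressed = [f"LOWEXP{k + 1}" for k in range(cfg.n_lowexpr_features)]

    mir_de = {m: cfg.de_log2fc if i % 2 == 0 else -cfg.de_log2fc
              for i, m in enumerate(de_mirnas)}
    for m in net_mirnas:
        mir_de[m] = cfg.de_log2fc
    lnc_de = {l: cfg.de_log2fc if i % 2 == 0 else -cfg.de_log2fc
              for i, l in enumerate(de_lncrnas)}
    for l in net_lncrnas:
        lnc_de[l] = cfg.de_log2fc
    mirna = expr_matrix(ann.mirna_ids, mir_de, rng_e)
    lncrna = expr_matrix(ann.lncrna_ids, lnc_de, rng_e)

    # --- PSI table ------------------------------------------------------------
    rng_p = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    psi_de = {hub_event: cfg.hub_psi_log2fc}
    for ev in indep[1:]:
        psi_de[ev] = cfg.other_psi_log2fc
    rows = {}
    for ev in ann.events:
        base = cfg.base_psi
        lfc = psi_de.get(ev.event_id, 0.0)
        mean = np.minimum(base * 2.0 ** (lfc * is_tumor), 0.9)
        load = loading.get(ev.event_id)
        shift = (cfg.module_loading_psi * f_all[load[0]].to_numpy()
                 if load else 0.0)
        z = rng_p.normal(0, cfg.psi_logit_sd, len(samples)) if cfg.psi_logit_sd > 0 \
            else 0.0
        rows[ev.event_id] = expit(logit(mean) + shift + z)
    psi = pd.DataFrame(rows).T
    psi.columns = samples

    event_meta = pd.DataFrame(
        [
            {"event_id": e.event_id, "gene": e.gene, "splice_type": e.splice_type,
             "start": e.interval[0], "end": e.interval[1]}
            for e in ann.events
        ]
    ).set_index("event_id")

    coef_names = {"__hub_event__": hub_event, "__hub_mirna__": net_mirnas[0],
                  "__hub_lncrna__": net_lncrnas[0]}
    prognostic = {coef_names.get(k, k): v for k, v in cfg.prognostic_coefs.items()}

    truth = SyntheticTruth(
        planted_de={
            "mirna": mir_de,
            "lncrna": lnc_de,
            "ntrna_psi": psi_de,
            "gene": gene_de,
        },
        planted_seed_sites=seed_sites,
        planted_modules=modules,
        planted_prognostic=prognostic,
        planted_immune=dict(cfg.immune_coefs),
        planted_methyl={},
        event_map=dict(ann.event_map),
        independent_ntrnas=list(indep),
        hub_event=hub_event,
        ntrna_rules=dict(ann.ntrna_rules),
        low_expressed=low_expressed,
        rng_seed=seed,
    )
    # planted sequences live in the bundle copies
    ann.ntrna_scan_seqs = scan_seqs
    ann.lncrna_seqs = lnc_seqs
    return ExpressionBundle(mrna, mirna, lncrna, psi, event_meta, factors, truth)


# ---------------------------------------------------------------------------
# clinical survival
# ---------------------------------------------------------------------------

def generate_clinical_survival(
    features: pd.DataFrame,
    coefficients: dict[str, float],
    censoring_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.12,
    followup_cap: float = 12.0,
) -> pd.DataFrame:
    """Survival + clinical covariates from a proportional-hazards model.

    ``features`` is features x samples; the linear predictor applies the
    given coefficients to the z-scored rows.  Event times are exponential
    with hazard ``baseline_hazard * exp(lp)``; censoring is exponential,
    tuned to roughly the requested rate, plus an administrative follow-up cap
    (both disabled when ``censoring_rate`` is 0).
    """
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring rate must be in [0, 1)")
    unknown = [f for f in coefficients if f not in features.index]
    if unknown:
        raise KeyError(f"coefficient features not in data: {unknown}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 66]))
    samples = features.columns
    lp = np.zeros(len(samples))
    for f, c in coefficients.items():
        x = features.loc[f].to_numpy(float)
        sd = x.std()
        lp += c * (x - x.mean()) / (sd if sd > 0 else 1.0)

    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    if censoring_rate > 0:
        lam_c = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = np.minimum(rng.exponential(1.0 / lam_c, len(samples)),
                            followup_cap)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(samples), int)
    time = np.maximum(time, 1e-4)

    p_hi = expit(0.8 * lp)  # worse biology -> higher grade/stage odds
    grade = np.where(rng.random(len(samples)) < p_hi, "G3&G4", "G1&G2")
    t_stage = np.where(rng.random(len(samples)) < 0.35 + 0.2 * (p_hi - 0.5),
                       "T3&T4", "T1&T2")
    m_stage = rng.choice(["M0", "M1", "MX"], len(samples), p=[0.79, 0.145, 0.065])
    n_stage = rng.choice(["N0", "N1", "NX"], len(samples), p=[0.436, 0.034, 0.53])
    sex = rng.choice(["male", "female"], len(samples), p=[0.65, 0.35])
    age = np.clip(rng.normal(61, 11, len(samples)).round(), 26, 90)

    return pd.DataFrame(
        {
            "os_time": time,
            "os_status": event,
            "age": age,
            "sex": sex,
            "grade": grade,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "m_stage": m_stage,
        },
        index=samples,
    )


# ---------------------------------------------------------------------------
# immune + methylation
# ---------------------------------------------------------------------------

def generate_immune_and_methylation(
    factors: pd.DataFrame,
    hub_psi: dict[str, pd.Series],
    config: SyntheticConfig | None = None,
    seed: int = 0,
    n_cell_types: int = 24,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, pd.DataFrame]:
    """Immune abundances, methylation betas, probe map and DNMT expression.

    The planted immune cells load on the prognostic factor f1 (Tcm
    negatively), so they differ between risk groups downstream; planted
    probes are negatively correlated with their assigned ntRNA event's PSI at
    the configured magnitude; DNMT expression rises with hub-event PSI.
    """
    cfg = config or SyntheticConfig()
    if n_cell_types < 1:
        raise ValueError("need at least one cell type")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    samples = factors.index
    n = len(samples)
    f1 = factors["f1"].to_numpy()

    cells = IMMUNE_CELLS[:n_cell_types]
    imm = {}
    for cell in cells:
        coef = cfg.immune_coefs.get(cell, 0.0)
        load = 0.6 * np.sign(coef) if coef else 0.0
        imm[cell] = np.exp(np.log(0.05) + load * f1 + rng.normal(0, 0.5, n))
    immune = pd.DataFrame(imm, index=samples)

    r = cfg.methyl_target_r
    probes, probe_map, planted = {}, {}, {}
    pid = 0
    for ev, psi in hub_psi.items():
        z = (psi - psi.mean()) / psi.std()
        for _ in range(3):
            pid += 1
            probe = f"cg{pid:08d}"
            w = r * z.to_numpy() + np.sqrt(1 - r**2) * rng.normal(0, 1, n)
            probes[probe] = np.clip(0.5 + 0.15 * w, 0.01, 0.99)
            probe_map[probe] = ev
            planted[probe] = [ev, r]
    null_targets = list(hub_psi)
    for k in range(cfg.n_null_probes):
        pid += 1
        probe = f"cg{pid:08d}"
        probes[probe] = np.clip(rng.normal(0.5, 0.15, n), 0.01, 0.99)
        probe_map[probe] = null_targets[k % len(null_targets)]
    beta = pd.DataFrame(probes, index=samples).T

    hub = next(iter(hub_psi.values()))
    zhub = ((hub - hub.mean()) / hub.std()).to_numpy()
    dnmt = pd.DataFrame(
        {
            g: np.exp(np.log(200.0) + 0.5 * zhub + rng.normal(0, 0.4, n))
            for g in ("DNMT1", "DNMT3A", "DNMT3B")
        },
        index=samples,
    ).T
    return immune, beta, {"map": probe_map, "planted": planted}, dnmt


# ---------------------------------------------------------------------------
# orchestration + IO
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    annotation: AnnotationBundle
    expression: ExpressionBundle
    clinical: pd.DataFrame
    immune: pd.DataFrame
    beta: pd.DataFrame
    probe_map: dict
    dnmt: pd.DataFrame
    truth: SyntheticTruth


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """The full synthetic cohort under one config and one seed."""
    cfg = config or SyntheticConfig()
    ann = generate_annotation(cfg.n_genes, cfg.isoforms_per_gene, cfg.seed,
                              cfg.ntrna_fraction, cfg.fraction_short,
                              cfg.n_mirnas, cfg.n_lncrnas)
    expr = generate_expression_and_psi(ann, cfg.n_tumor, cfg.n_normal, cfg, cfg.seed)
    truth = expr.truth

    t_ids = list(expr.factors.index)
    feats = pd.concat(
        [
            expr.psi.loc[:, t_ids],
            np.log2(expr.mirna.loc[:, t_ids] + 1),
            np.log2(expr.lncrna.loc[:, t_ids] + 1),
        ]
    )
    imm_pre, beta, probe_info, dnmt = generate_immune_and_methylation(
        expr.factors,
        {ev: expr.psi.loc[ev, t_ids] for ev in truth.independent_ntrnas[:2]},
        cfg, cfg.seed,
    )
    surv_feats = pd.concat([feats, imm_pre.T])
    coefs = {**truth.planted_prognostic, **truth.planted_immune}
    clinical = generate_clinical_survival(
        surv_feats, coefs, cfg.censoring_rate, cfg.seed,
        cfg.baseline_hazard, cfg.followup_cap_years,
    )
    truth.planted_methyl = probe_info["planted"]
    return SyntheticDataset(cfg, ann, expr, clinical, imm_pre, beta,
                            probe_info["map"], dnmt, truth)


def _write_fasta(seqs: dict, path):
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


def read_fasta(path) -> dict:
    seqs, name = {}, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    return seqs


_FMT = "%.8g"


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Serialize every input file plus the truth JSON (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(ds.annotation.transcripts, out / "annotation.gtf")
    _write_fasta(ds.annotation.ntrna_scan_seqs, out / "ntrna_regions.fa")
    _write_fasta(ds.annotation.mirna_seqs, out / "mirnas.fa")
    _write_fasta(ds.annotation.lncrna_seqs, out / "lncrnas.fa")
    ds.expression.mrna.to_csv(out / "expr_mrna.tsv", sep="\t", float_format=_FMT)
    ds.expression.mirna.to_csv(out / "expr_mirna.tsv", sep="\t", float_format=_FMT)
    ds.expression.lncrna.to_csv(out / "expr_lncrna.tsv", sep="\t", float_format=_FMT)
    ase = ds.expression.event_meta.join(ds.expression.psi)
    ase.to_csv(out / "ase_psi.tsv", sep="\t", float_format=_FMT)
    ds.clinical.to_csv(out / "clinical.tsv", sep="\t", float_format=_FMT)
    ds.immune.to_csv(out / "immune.tsv", sep="\t", float_format=_FMT)
    ds.beta.to_csv(out / "methylation_beta.tsv", sep="\t", float_format=_FMT)
    pd.Series(ds.probe_map, name="event_id").rename_axis("probe").to_csv(
        out / "probe_map.tsv", sep="\t")
    ds.dnmt.to_csv(out / "dnmt_expr.tsv", sep="\t", float_format=_FMT)
    (out / "truth.json").write_text(ds.truth.to_json())


def load_truth(path) -> SyntheticTruth:
    return SyntheticTruth(**json.loads(Path(path).read_text()))
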
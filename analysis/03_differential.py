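"""Differential expression and the gene-independent ntRNA selection."""

from common import RUN_DIR, pipeline_config
from ntriplenet.workflow import run_full_pipeline


def main():
    report = run_full_pipeline(pipeline_config(), upto="differential_selection")
    c = report["counts"]
    r = c["retained_features"]
    print(f"after the 60% zero-fraction filter: {r['gene']} genes, "
          f"{r['mirna']} miRNAs, {r['lncrna']} lncRNAs "
          f"({c['retained_total']} features total)")
    print(f"{c['independent_ntrnas']} gene-independent DE ntRNAs "
          f"(event FDR <= 10th percentile, |log2FC| > 1, gene FDR >= median): "
          f"{', '.join(report['selected_ntrnas'])}")
    print(f"{c['de_mirnas']} DEmiRNAs and {c['de_lncrnas']} DElncRNAs "
          f"(FDR < 0.05, |log2FC| > 1)")
    print(f"tables: {RUN_DIR}/de_*.tsv")


if __name__ == "__main__":
    main()
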
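"""Gene and immune LASSO Cox risk models with median-split KM analysis."""

from common import pipeline_config
from ntriplenet.workflow import run_full_pipeline


def main():
    report = run_full_pipeline(pipeline_config(), upto="immune_risk_model")
    c = report["counts"]
    print(f"4:1 split: {c['train_samples']} training / {c['test_samples']} test")
    gm = report["gene_model"]
    terms = " + ".join(f"{v:.3f}*{k}" for k, v in gm["coefficients"].items())
    print(f"Riskscore_gene = {terms}")
    km = report["gene_km"]
    print(f"high vs low Riskscore_gene log-rank p: train {km['train_logrank_p']:.2e},"
          f" test {km['test_logrank_p']:.3g}")
    im = report["immune_model"]
    print(f"immune cells passing both screens ({c['cells_both']}): "
          f"{', '.join(im['screened_both'])}")
    terms = " + ".join(f"{v:.3f}*{k}" for k, v in im["coefficients"].items())
    print(f"Riskscore_immune = {terms}")


if __name__ == "__main__":
    main()
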
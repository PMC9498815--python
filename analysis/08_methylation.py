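"""DNMT association, probe-PSI correlation, and key methylation sites."""

from common import RUN_DIR, pipeline_config
from ntriplenet.workflow import run_full_pipeline


def main():
    report = run_full_pipeline(pipeline_config(), upto="methylation")
    keys = report["key_methylation_sites"]
    print(f"{len(keys)} key methylation sites (negative probe-PSI correlation "
          f"AND survival association, both FDR < 0.05):")
    print("  " + ", ".join(keys))
    print(f"tables: {RUN_DIR}/dnmt_tests.tsv, {RUN_DIR}/probe_correlations.tsv, "
          f"{RUN_DIR}/probe_survival.tsv")


if __name__ == "__main__":
    main()
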
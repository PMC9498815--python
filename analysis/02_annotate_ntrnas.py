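"""Classify transcripts as ntRNA, extract unique splice tags, and match them
to named splicing events."""

from common import RUN_DIR, pipeline_config
from ntriplenet.workflow import run_full_pipeline


def main():
    report = run_full_pipeline(pipeline_config(), upto="classify_and_match")
    c = report["counts"]
    print(f"{c['ntrna_transcripts']} transcripts classified as ntRNA")
    print(f"{c['unique_tags']} ntRNA-unique splice tags extracted")
    print(f"{c['matched_ntrnas']} ntRNAs matched to a splicing event "
          f"(PSI-quantifiable)")
    print(f"tables: {RUN_DIR}/classification.tsv, {RUN_DIR}/ntrna_tags.tsv")


if __name__ == "__main__":
    main()
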
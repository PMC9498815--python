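"""Coexpression modules, the survival-associated key module, and hub
selection by five-centrality top-15 intersection."""

from common import RUN_DIR, pipeline_config
from ntriplenet.workflow import run_full_pipeline


def main():
    report = run_full_pipeline(pipeline_config(), upto="hub_selection")
    c = report["counts"]
    print(f"soft threshold power: {report['soft_threshold_power']}")
    print(f"{c['modules']} non-grey modules; key module: "
          f"{report['key_module']} (strongest |cor| with OS status)")
    print(f"key-module network: {c['key_module_network_nodes']} nodes; "
          f"{c['hub_nodes']} hubs in the top 15 of all five centralities:")
    print("  " + ", ".join(report["hub_nodes"]))
    print(f"tables: {RUN_DIR}/module_trait_cor.tsv, {RUN_DIR}/centrality.tsv")


if __name__ == "__main__":
    main()
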
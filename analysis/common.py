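"""Shared paths and the default run configuration for the analysis scripts."""

from pathlib import Path

from ntriplenet.workflow import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
RUN_DIR = ROOT / "results" / "run"
SEED = 1


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(data_dir=str(DATA_DIR), out_dir=str(RUN_DIR), seed=SEED)
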
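import pytest

from ntriplenet.synthetic import SyntheticConfig, generate_dataset, write_dataset
from ntriplenet.workflow import PipelineConfig, run_full_pipeline


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic cohort (seed 1), shared across the suite."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory, dataset):
    out = tmp_path_factory.mktemp("synthetic_cohort")
    write_dataset(dataset, out)
    return out


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory, data_dir):
    out = tmp_path_factory.mktemp("pipeline_run")
    return run_full_pipeline(
        PipelineConfig(data_dir=str(data_dir), out_dir=str(out), seed=1))
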
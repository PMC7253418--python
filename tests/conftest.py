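import pytest

from isoatlas.pipeline import PipelineConfig, run_pipeline
from isoatlas.simulate import SimConfig, simulate_all, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic dataset at a fixed seed."""
    return simulate_all(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_dir(dataset, tmp_path_factory):
    """The default dataset written out as its standard text formats."""
    outdir = tmp_path_factory.mktemp("simdata")
    write_dataset(dataset, outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_result(sim_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig.for_simulated_dir(sim_dir, outdir=str(outdir), seed=7)
    report = run_pipeline(cfg)
    return report, outdir
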
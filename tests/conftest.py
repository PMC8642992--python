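import warnings

import pytest

from circorf.annotate import reconstruct_sequence
from circorf.pipeline import run_pipeline
from circorf.simulate import SimConfig, generate_genome, plant_circrnas


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def truth_and_bsjs(genome, sim_config):
    return plant_circrnas(genome, sim_config)


@pytest.fixture(scope="session")
def truth(truth_and_bsjs):
    return truth_and_bsjs[0]


@pytest.fixture(scope="session")
def coding_truth(truth):
    return [t for t in truth if t.true_coding]


@pytest.fixture(scope="session")
def analog(coding_truth):
    """The planted 959-nt single-exon coding circle (ORF start 80, 295 aa)."""
    return coding_truth[0]


@pytest.fixture(scope="session")
def events(genome, truth_and_bsjs):
    _, bsjs = truth_and_bsjs
    return [reconstruct_sequence(r, genome) for r in bsjs]


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(None, outdir)
    return report, outdir
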
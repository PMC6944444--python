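import numpy as np
import pytest

from madascan import pipeline as pipeline_mod
from madascan import simulate as sim_mod

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def default_repertoire():
    """Reference synthetic repertoire (default study conditions, seed 1)."""
    config = sim_mod.SimConfig(seed=1)
    records, truths = sim_mod.generate_repertoire(config)
    return config, records, truths


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = pipeline_mod.synthetic_config(outdir, seed=1)
    return pipeline_mod.run_pipeline(config)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))
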
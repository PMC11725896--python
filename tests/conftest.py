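import warnings

import numpy as np
import pytest

from seedatlas import RunConfig, SimConfig, run_all
from seedatlas.simulate import generate_bulk


@pytest.fixture(scope="session")
def standard_config():
    """The standard synthetic seed: spec'd sizes, seed 7."""
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def pipeline_state(standard_config):
    """One full pipeline run on the standard fixture, shared by all tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, state = run_all(RunConfig(sim=standard_config, seed=7),
                                return_state=True)
    failed = [n for n, s in report["stages"].items() if s.get("status") == "failed"]
    assert not failed, f"pipeline stages failed: {failed}"
    return report, state


@pytest.fixture(scope="session")
def bulk_world(pipeline_state):
    _report, state = pipeline_state
    return state["bulk_counts"], state["samples"], state["truth"]


@pytest.fixture(scope="session")
def null_world():
    """A seed with no planted structure at all: every gene is null."""
    cfg = SimConfig(n_genes=1000,
                    subregions={"A": "embryo", "B": "embryo"},
                    stages=("cot",), replicates=3,
                    n_universal=0, n_specific_per_subregion=0,
                    n_regional_per_region=0, module_sizes=(),
                    module_subregions=(), cluster_subregions=(),
                    n_tf_random=50, seed=11)
    return generate_bulk(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
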
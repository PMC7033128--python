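import numpy as np
import pytest

import neurostage as ns


@pytest.fixture(scope="session")
def small_cohort():
    """Two-stage planted cohort shared by read-only tests."""
    config = ns.planted_cohort_config(
        stages=("T1N0", "N1"), n_tumor=25, n_control=12, seed=11,
    )
    cohort, truth = ns.simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cohort):
    config, cohort, truth = small_cohort
    directory = tmp_path_factory.mktemp("fixture")
    pathways = ns.default_pathway_catalog(config)
    ns.write_fixture(cohort, truth, directory, pathways=pathways)
    return directory


@pytest.fixture(scope="session")
def fixture_catalog(fixture_dir):
    return ns.load_catalog(fixture_dir / "annotations.gmt", ns.simulate.NEURAL_TERMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
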
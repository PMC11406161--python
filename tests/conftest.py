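import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ewlphylo as e

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def phylo():
    trees = e.sample_trees(50, seed=1)
    return e.phylo_correlation(e.mean_branch_tree(trees))


@pytest.fixture(scope="session")
def table1_truth():
    return e.truth_parameters("table1")


@pytest.fixture(scope="session")
def small_experiment(phylo, table1_truth):
    """12 animals (1 per treatment cell per species), 4 weighings each."""
    design = e.make_design(1, e.DEFAULT_PROFILES, seed=3)
    sim = e.simulate_experiment(design, table1_truth, seed=4, phylo=phylo)
    return design, sim


@pytest.fixture(scope="session")
def small_frame(small_experiment):
    design, sim = small_experiment
    return e.build_model_frame(sim.series, design, coding=sim.coding)


@pytest.fixture(scope="session")
def medium_experiment(phylo, table1_truth):
    """Mid-sized experiment used by the fitting tests (48 animals)."""
    design = e.make_design(4, e.DEFAULT_PROFILES, seed=7)
    sim = e.simulate_experiment(design, table1_truth, seed=8, phylo=phylo)
    frame = e.build_model_frame(sim.series, design, coding=sim.coding)
    return design, sim, frame


def make_individual(
    ind_id="x1",
    species="Xenopus_tropicalis",
    svl=34.0,
    housing="h1",
    date="d1",
    water=False,
    temp=26.0,
):
    return e.Individual(
        id=ind_id,
        species=species,
        svl_mm=svl,
        housing_group=housing,
        date=date,
        treatment=e.Treatment(water, temp),
    )


@pytest.fixture
def zero_variance_truth(table1_truth):
    return e.TruthTable(
        coefficients=dict(table1_truth.coefficients),
        variances={k: 0.0 for k in table1_truth.variances},
        rho=0.7,
    )
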
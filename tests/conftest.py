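import numpy as np
import pytest
from hypothesis import settings

import allotraj as at
from allotraj.workflow import run_sex_threshold

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_counts():
    return at.load_survey_counts()


@pytest.fixture(scope="session")
def six_species_sim():
    """One moderate synthetic dataset (6 species, n=40 each) with ground truth."""
    spec = at.SimulationSpec(n_species=6, n_per_species=40, seed=3)
    params = at.simulate_species_params(spec)
    dataset = at.simulate_dataset(params, spec)
    return spec, params, dataset


@pytest.fixture(scope="session")
def six_species_result(six_species_sim):
    """Full pipeline run on the 6-species dataset (199 permutations for speed)."""
    spec, params, dataset = six_species_sim
    config = at.StudyConfig(seed=11, n_permutations=199)
    return run_sex_threshold(dataset, sex="F", min_n=10, config=config, tree=params.tree)


@pytest.fixture(scope="session")
def tiny_tree():
    import dendropy

    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
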
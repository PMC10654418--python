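import numpy as np
import pandas as pd
import pytest

import seasdm as ss


@pytest.fixture(scope="session")
def small_env_spec() -> ss.EnvSpec:
    return ss.EnvSpec(grid=ss.GridSpec(60, 60, 50.0), seed=11)


@pytest.fixture(scope="session")
def small_env(small_env_spec) -> ss.EnvStack:
    return ss.generate_env_stack(small_env_spec)


@pytest.fixture(scope="session")
def community(small_env_spec) -> list[ss.NicheSpec]:
    return ss.default_niches(small_env_spec, seed=7)


@pytest.fixture(scope="session")
def groups(community) -> dict[str, str]:
    return {n.species: n.group for n in community}


@pytest.fixture(scope="session")
def survey(small_env, community):
    table, truth = ss.simulate_survey(
        small_env, community, ss.SurveySpec(n_sites=1500, seed=5)
    )
    return table, truth


@pytest.fixture(scope="session")
def matrix(survey, groups) -> ss.OccurrenceMatrix:
    table, _ = survey
    return ss.prepare_survey(table, groups=groups, min_occurrence=50, seed=3)


def make_survey_table(rows) -> pd.DataFrame:
    """Record table from (site_id, x, y, year, species, quantity) tuples."""
    df = pd.DataFrame(rows, columns=["site_id", "x", "y", "year", "species", "quantity"])
    df["method"] = "biomass"
    return df[["site_id", "x", "y", "year", "method", "species", "quantity"]]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
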
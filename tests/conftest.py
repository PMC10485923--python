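"""Shared fixtures: a small synthetic protein with its peptide map and
corrected uptake table, reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hdx2ss.rfu_correction import correct_table
from hdx2ss.synthetic_fixtures import (
    FixtureConfig,
    make_peptide_map,
    make_protein,
    make_uptake,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    return FixtureConfig(n_residues=60, seed=1)


@pytest.fixture(scope="session")
def small_protein(small_cfg):
    return make_protein(small_cfg)


@pytest.fixture(scope="session")
def small_map(small_protein, small_cfg):
    return make_peptide_map(small_protein, small_cfg)


@pytest.fixture(scope="session")
def small_uptake(small_protein, small_map, small_cfg):
    return make_uptake(small_protein, small_map, cfg=small_cfg)


@pytest.fixture(scope="session")
def small_corrected(small_uptake):
    return correct_table(small_uptake)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
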
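"""Shared fixtures: a small synthetic study reused across test modules.

The reduced study keeps every bone at one tenth of the scanned point count
so registration-dependent tests run in seconds; acceptance tests build
their own full-scale inputs where the check demands it.
"""

import numpy as np
import pytest

from wingkin.registration import FitOptions, fit_all
from wingkin.synthetic import (
    compose_chain,
    default_specs,
    generate_bone_cloud,
    make_table1_poses,
    pose_clouds,
)

SEED = 11


@pytest.fixture(scope="session")
def small_specs():
    return default_specs(seed=SEED, subsample=10)


@pytest.fixture(scope="session")
def base_clouds(small_specs):
    return {b: generate_bone_cloud(s) for b, s in small_specs.items()}


@pytest.fixture(scope="session")
def truth_relative():
    return make_table1_poses()


@pytest.fixture(scope="session")
def truth_absolute(truth_relative):
    return compose_chain(truth_relative)


@pytest.fixture(scope="session")
def posture_clouds(base_clouds, truth_absolute):
    return pose_clouds(base_clouds, truth_absolute, overlap_fraction=0.8, seed=SEED)


@pytest.fixture(scope="session")
def small_fits(posture_clouds):
    return fit_all(posture_clouds, FitOptions(n_starts=12, seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
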
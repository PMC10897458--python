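"""Shared fixtures: RNG and a reduced stress-test suite.

The session-scoped ``stress_suite`` runs the full clustering pipeline on
a reduced number of movies per morphology class (the full protocol uses
50 per class); the acceptance tests share its results so the expensive
pipeline runs once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from smorph import simulate
from smorph.protocols import STRESS_CLASSES, run_stress_suite

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

#: movies per class in the reduced stress suite
N_MOVIES = 4
BASE_SEED = 1


@pytest.fixture(scope="session")
def stress_suite():
    """Reduced stress test: N_MOVIES movies per class, scored per assembly."""
    return {
        klass: run_stress_suite(klass, N_MOVIES, BASE_SEED)
        for klass in STRESS_CLASSES
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_isotropic_movie():
    spec = simulate.MovieSpec(n_assemblies={"isotropic": 3}, seed=7)
    return simulate.assemble_movie(spec)
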
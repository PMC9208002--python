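"""Shared fixtures: small synthetic atlases and cohorts.

Everything is generated programmatically at session scope so expensive
objects (rendered cohorts) are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from msfnc.simulate import (
    CohortSpec,
    StateSpec,
    hierarchical_covariance,
    make_hierarchical_sources,
    render_cohort,
)

GRID = (26, 26, 10)
ATLAS_KW = dict(child_radius=2.2, smooth_ratio=0.5, sep_ratio=2.8)


@pytest.fixture(scope="session")
def atlas():
    """4 coarse sources, each split into 2 fine sources."""
    return make_hierarchical_sources(GRID, 4, 2, seed=1, **ATLAS_KW)


@pytest.fixture(scope="session")
def states_single(atlas):
    cov = hierarchical_covariance(atlas.hierarchy, rho=0.35)
    return StateSpec([cov])


@pytest.fixture(scope="session")
def small_cohort(atlas, states_single):
    """8 subjects (2 per diagnosis x sex cell), quiet conditions: no motion,
    modest noise — used for decomposition unit tests."""
    cohort = CohortSpec(
        n_per_cell=2, seed=3, noise_sd=0.05, motion_amp=0.0, source_amplitude=1.0
    )
    datasets, truth = render_cohort(atlas, states_single, cohort, T=150)
    return datasets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
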
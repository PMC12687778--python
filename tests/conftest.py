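"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from salnet import CohortConfig, generate_atlas, generate_cohort


def small_config(**overrides):
    """A fast desk-scale cohort: 24-voxel grid, few regions/subjects."""
    base = dict(
        n_high=12, n_low=12, n_control=6,
        grid=24,
        n_cortical_per_hemi=8, n_subcortical_per_hemi=2, n_midline=2,
        n_lobes=3, n_latents=2,
        affected_cortical_per_block=3, affected_subcortical_per_block=1,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    return generate_atlas(small_cfg)


@pytest.fixture(scope="session")
def default_atlas():
    """The full-size default atlas (75+13 regions per hemisphere, 48 grid)."""
    return generate_atlas(CohortConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
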
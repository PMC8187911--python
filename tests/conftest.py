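"""Shared fixtures.

The expensive growth simulations are session-scoped and shared: one bundle
per builtin experiment configuration at a deliberately coarse resolution
(13 mm target edge length, 2 sub-increments per growth interval) so the
whole suite stays within a desk-scale time budget.
"""

import numpy as np
import pytest

from calvaria.experiments import builtin_configs, run_experiment
from calvaria.synthetic_skull import CraniotomySpec, SkullParams, generate_calvaria

SUITE_MESH_SIZE = 13.0
SUITE_SUBSTEPS = 2


@pytest.fixture(scope="session")
def suite_configs():
    return builtin_configs(mesh_size=SUITE_MESH_SIZE, n_substeps=SUITE_SUBSTEPS)


@pytest.fixture(scope="session")
def grid_bundles(suite_configs):
    """Lazily-run, cached experiment bundles keyed by config name."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = run_experiment(suite_configs[name])
        return cache[name]

    return get


@pytest.fixture(scope="session")
def skull_coarse():
    """Model II skull with craniotomies at suite resolution."""
    return generate_calvaria(
        SkullParams(mesh_size=SUITE_MESH_SIZE, csf_thickness=0.0,
                    craniotomy_spec=CraniotomySpec())
    )


@pytest.fixture(scope="session")
def skull_plain():
    """Model II skull without craniotomies (fused sagittal intact)."""
    return generate_calvaria(
        SkullParams(mesh_size=SUITE_MESH_SIZE, csf_thickness=0.0),
        with_craniotomies=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
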
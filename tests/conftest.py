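"""Shared fixtures: small geometries, designs and one session-level dataset run."""

import logging

import numpy as np
import pytest

from taskpca import GroupAnalysis
from taskpca.design import generate_task_design
from taskpca.simulate import (
    DatasetConfig,
    VolumeGeometry,
    ellipsoid_mask,
    generate_pattern_templates,
    reduced_geometry,
    simulate_dataset,
)

logging.getLogger("taskpca").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_geometry():
    return VolumeGeometry(dims=(20, 24, 17))


@pytest.fixture(scope="session")
def small_mask(small_geometry):
    return ellipsoid_mask(small_geometry)


@pytest.fixture(scope="session")
def small_patterns(small_geometry, small_mask):
    return generate_pattern_templates(small_geometry, small_mask, seed=0)


@pytest.fixture(scope="session")
def design224():
    return generate_task_design(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def run_group_analysis(config, geometry, master_seed):
    """Simulate a dataset and push every acquisition through the group pipeline."""
    mask, truth, designs, acqs = simulate_dataset(config, geometry, master_seed)
    group = GroupAnalysis(
        reference1=truth.pattern_images[0],
        reference2=truth.pattern_images[1],
        conditions=tuple(config.conditions),
    )
    metas = []
    for acq, design, matrix, meta in acqs:
        group.add_acquisition(matrix, design, acq)
        metas.append(meta)
    return mask, truth, group, group.run(), metas


@pytest.fixture(scope="session")
def default_dataset_run():
    """The default synthetic study (10 subjects x 2 conditions x 2 runs) on the
    reduced 40 x 48 x 34 grid, fully analysed.  Shared across acceptance tests."""
    geometry = reduced_geometry(0.5)
    mask, truth, group, results, metas = run_group_analysis(
        DatasetConfig(), geometry, master_seed=0
    )
    return {
        "geometry": geometry,
        "mask": mask,
        "truth": truth,
        "group": group,
        "results": results,
        "metas": metas,
    }
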
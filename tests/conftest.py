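"""Shared fixtures: small synthetic runs and cohorts."""

import numpy as np
import pytest

from cofluct.data import Confounds, ParcelSeries, SubjectRun
from cofluct.regressors import TaskDesign
from cofluct.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def task_design():
    """Two blocks per condition in a 280-frame, TR 2 s run."""
    blocks = [
        ("incongruent", 14.0, 56.0),
        ("congruent", 84.0, 56.0),
        ("incongruent", 154.0, 56.0),
        ("congruent", 224.0, 56.0),
    ]
    return TaskDesign(blocks, n_frames=280, tr=2.0)


def make_confounds(rng, n_frames):
    return Confounds(
        motion=np.cumsum(rng.normal(0, 0.01, size=(n_frames, 6)), axis=0),
        white_matter=rng.normal(size=n_frames),
        csf=rng.normal(size=n_frames),
        global_signal=rng.normal(size=n_frames),
    )


@pytest.fixture
def task_run(rng, task_design):
    """Pure-noise task run with 8 regions."""
    n_frames, n_regions = task_design.n_frames, 8
    data = rng.normal(size=(n_frames, n_regions))
    return SubjectRun(
        parcels=ParcelSeries(data, tr=task_design.tr),
        confounds=make_confounds(rng, n_frames),
        design=task_design,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale dissociation cohort shared across slower tests."""
    config = CohortConfig(
        n_subjects=6, n_regions=16, n_systems=4, n_modulated_edges=8, seed=42
    )
    return generate_cohort(config)
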
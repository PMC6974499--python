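"""Shared fixtures: small synthetic cohorts and hand-built volume sets."""

from __future__ import annotations

import numpy as np
import pytest

from ssmpca import (
    DeriveConfig,
    SyntheticCohortSpec,
    VolumeSet,
    derive_pattern,
    generate_cohort,
)
from ssmpca.synthetic_data import CameraArm


def make_volume_set(volumes, groups=None, cameras=None, ids=None) -> VolumeSet:
    """VolumeSet from a (n, X, Y, Z) array with an all-true mask."""
    volumes = np.asarray(volumes, dtype=float)
    n = volumes.shape[0]
    return VolumeSet(
        data=volumes.reshape(n, -1, order="C").copy(),
        mask=np.ones(volumes.shape[1:], dtype=bool),
        affine=np.eye(4),
        subject_ids=list(ids) if ids is not None else [f"s{i:02d}" for i in range(n)],
        group_labels=np.array(groups if groups is not None else ["control"] * n, dtype=object),
        camera_labels=np.array(cameras if cameras is not None else ["cam0"] * n, dtype=object),
    )


def small_spec(**overrides) -> SyntheticCohortSpec:
    """Fast cohort spec: 12x14x12 grid, 8+8 subjects, mild noise."""
    defaults = dict(
        grid_shape=(12, 14, 12),
        cameras=[CameraArm("cam0", 8, 8)],
        voxel_noise_sd=0.02,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticCohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """(VolumeSet, SyntheticTruth) for quick pipeline tests."""
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def small_pattern(small_cohort):
    """A derived pattern on the small cohort (session-cached)."""
    vs, _ = small_cohort
    return derive_pattern(vs, DeriveConfig()).pattern


@pytest.fixture(scope="session")
def default_cohort():
    """Reference-condition cohort (20+20, default grid), one seed."""
    return generate_cohort(SyntheticCohortSpec(seed=11))


def random_positive_volumes(rng, n, grid):
    """Strictly positive random intensity volumes."""
    return np.exp(0.3 * rng.standard_normal((n, *grid)) + 4.0)
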
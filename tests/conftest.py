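from __future__ import annotations

import numpy as np
import pytest

from hipporad.image_io import ROIPatch


def tiny_patch(values: np.ndarray, mask: np.ndarray | None = None, label: str = "left_caudal") -> ROIPatch:
    """Construct a patch directly, bypassing the 27-voxel minimum used for
    real ROIs, so brute-force oracles can run on hand-sized grids."""
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(values.shape, dtype=np.uint8)
    mask = np.asarray(mask, dtype=np.uint8)
    return ROIPatch(values=values, mask=mask, label=label, n_voxels=int(mask.sum()))


def random_patch(rng: np.random.Generator, shape=(5, 5, 5), p_fg: float = 0.8) -> ROIPatch:
    """Random small patch with a random (non-empty) foreground mask."""
    values = rng.normal(100.0, 10.0, shape)
    mask = (rng.random(shape) < p_fg).astype(np.uint8)
    if not mask.any():
        mask.flat[0] = 1
    return tiny_patch(values, mask)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180925)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-effect cohort shared across tests (session-scoped for speed)."""
    from hipporad.synthetic import CohortConfig, make_cohort

    config = CohortConfig(
        n_per_group={"NC": 4, "aMCI": 3, "AD": 4},
        roi_semi_axes=(4.0, 3.0, 3.0),
        seed=11,
    )
    return make_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    from hipporad.pipeline import extract_cohort_features

    return extract_cohort_features(small_cohort.subjects)
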
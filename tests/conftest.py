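import numpy as np
import pytest

import statedyn as sd


@pytest.fixture(scope="session")
def small_design() -> sd.StudyDesign:
    """Desk-scale two-group design: 6 excerpts, 400 volumes."""
    return sd.make_design(
        groups={"younger": 3, "older": 3},
        n_volumes=400,
        category_counts={"self_selected": 2, "popular": 2, "novel": 2},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_gt(small_design) -> sd.GroundTruth:
    return sd.sample_ground_truth(
        small_design, n_states=4, n_rois=8, separation=2.0, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, small_gt) -> sd.SyntheticDataset:
    return sd.simulate_dataset(small_design, small_gt, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
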
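import numpy as np
import pytest

from replidyn.synthetic_data import (GroundTruthConfig, SyntheticCell,
                                     gen_nucleus_image)


@pytest.fixture(scope="session")
def untreated_config() -> GroundTruthConfig:
    return GroundTruthConfig.untreated(seed=11)


@pytest.fixture(scope="session")
def treated_config() -> GroundTruthConfig:
    return GroundTruthConfig.treated(seed=12)


@pytest.fixture(scope="session")
def noiseless_config() -> GroundTruthConfig:
    return GroundTruthConfig(seed=13, image_noise_sigma=0.0, dapi_cv=0.0,
                             intensity_cv=0.0, duration_jitter_cv=0.0)


@pytest.fixture(scope="session")
def early_cell() -> SyntheticCell:
    return SyntheticCell("cell_early", "untreated", "early",
                         true_content=1.2, true_speed=1.0)


@pytest.fixture(scope="session")
def rendered_early(untreated_config, early_cell):
    """One default-noise early-S nucleus render with its ground truth."""
    return gen_nucleus_image(untreated_config, early_cell, seed=17)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
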
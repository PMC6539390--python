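import numpy as np
import pytest

from chromasense import DatasetDesign, ResponseModel, generate_dataset, split_by_batch
from chromasense.synthetic import dataset_to_frame


@pytest.fixture(scope="session")
def default_frame():
    """Full-design dataset (8 batches, default response), seed 0."""
    return dataset_to_frame(generate_dataset(8, DatasetDesign(), seed=0))


@pytest.fixture(scope="session")
def two_component_frame():
    """Dataset whose response has exactly 2 informative components."""
    design = DatasetDesign(response=ResponseModel.two_component())
    return dataset_to_frame(generate_dataset(8, design, seed=0))


@pytest.fixture(scope="session")
def two_component_split(two_component_frame):
    return split_by_batch(two_component_frame, 6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
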
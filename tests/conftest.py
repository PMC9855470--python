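import numpy as np
import pytest

from chemfuse import LabeledDataset, CompoundRecord, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """Seeded synthetic library of 60 compounds with both label signals."""
    return generate(SyntheticSpec(n_compounds=60, seed=0))


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Four handcrafted compounds, two DILI-positive."""
    records = [
        CompoundRecord("c1", "CCO", True, {"HepG2": 6.0}, {"HepG2": False}),
        CompoundRecord("c2", "c1ccccc1", False, {"HepG2": 4.0}, {"HepG2": False}),
        CompoundRecord("c3", "CC(=O)O", True, {}, {}),
        CompoundRecord("c4", "CCN", False, {"Huh7": 5.0}, {"Huh7": False}),
    ]
    return LabeledDataset(records=records, name="tiny")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
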
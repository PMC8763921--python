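import numpy as np
import pytest

from microda import CountTable, GroupLabels, MethodConfig
from microda.simulate import SyntheticSpec, generate_dataset


@pytest.fixture
def toy_table() -> CountTable:
    """4 features x 6 samples with a clear group contrast in f0."""
    counts = np.array(
        [
            [50, 40, 60, 5, 4, 6],
            [10, 12, 11, 10, 12, 11],
            [0, 0, 1, 0, 1, 0],
            [40, 48, 28, 85, 83, 83],
        ]
    )
    return CountTable(
        feature_ids=("f0", "f1", "f2", "f3"),
        sample_ids=("a1", "a2", "a3", "b1", "b2", "b3"),
        counts=counts,
    )


@pytest.fixture
def toy_labels() -> GroupLabels:
    return GroupLabels(
        {"a1": "ctrl", "a2": "ctrl", "a3": "ctrl", "b1": "case", "b2": "case", "b3": "case"},
        ("ctrl", "case"),
    )


@pytest.fixture(scope="session")
def null_dataset():
    spec = SyntheticSpec(n_taxa=60, n_samples_per_group=(15, 15), seed=314)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def spiked_dataset():
    spec = SyntheticSpec(
        n_taxa=60,
        n_samples_per_group=(25, 25),
        n_da=5,
        fold_changes=(10.0,) * 5,
        zero_inflation=0.05,
        seed=2718,
    )
    return generate_dataset(spec)


@pytest.fixture
def cfg() -> MethodConfig:
    return MethodConfig(seed=99)
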
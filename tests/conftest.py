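import numpy as np
import pytest

from trophograd.core_data import AsvTable


@pytest.fixture
def small_table() -> AsvTable:
    counts = np.array([
        [10, 0, 3, 7],
        [5, 5, 0, 10],
        [0, 8, 2, 0],
    ])
    return AsvTable(["s1", "s2", "s3"], ["a1", "a2", "a3", "a4"], counts,
                    "bacteria")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
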
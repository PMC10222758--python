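import numpy as np
import pytest

import morphostat as ms


@pytest.fixture(scope="session")
def full_design() -> ms.LineageDesign:
    """The 20-strain study layout: 4 backgrounds x (original + 4 steps)."""
    return ms.study_design()


@pytest.fixture(scope="session")
def two_bg_design() -> ms.LineageDesign:
    """A compact 6-strain lineage: 2 backgrounds x (original + 2 steps)."""
    return ms.study_design(backgrounds=("K7", "K6"), steps=("GE01", "GE21"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_gaussian_specs(n: int, block_id=None) -> list[ms.ParameterSpec]:
    return [
        ms.ParameterSpec(f"C{101 + i}_A", "gaussian", 0.0, 1.0, block_id)
        for i in range(n)
    ]
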
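import numpy as np
import pandas as pd
import pytest

from scentsel import ScentMatrix, Study, SyntheticTruth, generate_study


@pytest.fixture
def toy_matrix() -> ScentMatrix:
    """6 inflorescence samples x 3 compounds with known occurrence counts."""
    vals = pd.DataFrame(
        {
            "c_a": [1.0, 2.0, 0.0, 3.0, 4.0, 0.0],   # 4 occurrences
            "c_b": [1.0, 0.0, 2.0, 0.0, 0.0, 3.0],   # 3 occurrences
            "c_c": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],   # 6 occurrences
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    return ScentMatrix(vals, mode="absolute")


@pytest.fixture
def small_study() -> Study:
    truth = SyntheticTruth(
        populations={"north": [("JOS", 25)], "south": [("DAO", 25)]},
        n_compounds=20,
        seed=11,
    )
    study, _ = generate_study(truth)
    return study


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
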
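import numpy as np
import pytest

from pinecrown.growth import ModelSpec
from pinecrown.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def sbl_small():
    """Small mixed-model length dataset (~160 primaries)."""
    return generate_dataset(GeneratorConfig(seed=11, n_trees=12,
                                            response_law="SBL_mixed"))


@pytest.fixture(scope="session")
def sbl_small_df(sbl_small):
    return sbl_small.to_frame()


@pytest.fixture(scope="session")
def sbl_fixed_df():
    """Population-average length data (no random effects)."""
    return generate_dataset(
        GeneratorConfig(seed=12, n_trees=12, response_law="SBL_fixed")
    ).to_frame()


@pytest.fixture(scope="session")
def noisefree_m7_df():
    """Deterministic Roeecp responses: all variances zero."""
    cfg = GeneratorConfig(
        seed=13, n_trees=6, response_law="SBL_fixed",
        fixed_effects={"a": 0.188, "a1": 3.0e-4, "b": 0.974, "c": 0.002},
        level1_cov=np.zeros((2, 2)), level2_var=0.0, sigma2=0.0)
    return generate_dataset(cfg).to_frame()


@pytest.fixture(scope="session")
def sbl_spec():
    return ModelSpec("M7", {"a": "PDINC"})


@pytest.fixture(scope="session")
def sbd_spec():
    return ModelSpec("M7", {"b": "PBD"})
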
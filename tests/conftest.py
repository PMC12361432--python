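import numpy as np
import pytest

from ccr9map.synthetic import NoiseModel, ToyEnsembleSpec, VariantTruth, generate_toy_ensemble


@pytest.fixture(scope="session")
def toy_ensemble():
    """Five-model toy bundle with graded planted activation distances."""
    spec = ToyEnsembleSpec(activation_distance=[3.0, 4.5, 6.0, 7.5, 9.0])
    return generate_toy_ensemble(spec, seed=7)


@pytest.fixture
def wt_truth():
    return VariantTruth("WT")


@pytest.fixture
def quiet_noise():
    return NoiseModel(trace_cv=0.0, mfi_log_sd=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
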
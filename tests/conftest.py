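import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sflt1kin.model_core import median_parameters

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def median():
    """Reference parameter set (delayed model) shipped with the package."""
    return median_parameters()


@pytest.fixture(scope="session")
def noiseless_datasets(median):
    """Preprocessed noiseless datasets in all three study designs."""
    from sflt1kin.data_io import preprocess
    from sflt1kin.synthetic_data import default_designs, generate_dataset

    params, spec = median
    return [
        preprocess(generate_dataset(params, spec, d))
        for d in default_designs(noise_cv=0.0, seed=123)
    ]
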
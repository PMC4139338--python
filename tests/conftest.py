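import numpy as np
import pytest

from gpordinal import Hyperparameters, ThresholdSet, fit
from gpordinal.synthetic import generate_cohort, spec_from_preset

#: small Powell budget used by tests that only need a reasonable fit
FAST_FIT = {"maxiter": 3, "ftol": 1e-3}


@pytest.fixture(scope="session")
def toy_cohort():
    """Balanced 4-class cohort, 5 features, clear but noisy signal."""
    spec = spec_from_preset("toy", seed=11)
    fm, y, truth = generate_cohort(spec)
    return fm, y, truth


@pytest.fixture(scope="session")
def toy_model(toy_cohort):
    fm, y, _ = toy_cohort
    return fit(fm.values, y, **FAST_FIT)


@pytest.fixture(scope="session")
def fixed_model(toy_cohort):
    """Laplace posterior at fixed hyperparameters (no evidence search)."""
    fm, y, _ = toy_cohort
    hyper = Hyperparameters(1.0, 1.0, ThresholdSet(-1.5, (1.5, 1.5)))
    return fit(fm.values, y, init=hyper, optimize=False)
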
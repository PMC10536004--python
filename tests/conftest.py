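import numpy as np
import pytest

from teacat.fitting import fit_series
from teacat.model import build_final_structure
from teacat.synthetic import default_truth, generate_cohort


@pytest.fixture(scope="session")
def structure():
    return build_final_structure()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def cohort_seed1(truth):
    """The default noisy study cohort: 19 subjects × 4 catechins, seed 1."""
    return generate_cohort(truth, n_subjects=19, seed=1)


@pytest.fixture(scope="session")
def fitted_cohort_seed1(cohort_seed1, structure):
    """Per-series fits of the default cohort (expensive; shared across tests)."""
    return [(s, fit_series(s, structure)) for s in cohort_seed1.series]


def random_params(structure, rng, lo=1e-3, hi=10.0):
    """Admissible random parameter set: coefficients log-uniform in [lo, hi]."""
    from teacat.fitting import default_initialization

    init = default_initialization(structure)
    updates = {
        e: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for e in init.values
        if init.status.get(e) == "adjustable" or init.status.get(e) == "fixed"
    }
    return init.with_values(updates).resolve()
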
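import numpy as np
import pytest

import ccmi
from ccmi.design import select_subcohort
from ccmi.missingness import induce_independent


@pytest.fixture(scope="session")
def observed_registry():
    """Default observed-variant parameters and RR outcome spec."""
    return ccmi.make_scenario_params("observed", "observed", "RR")


@pytest.fixture(scope="session")
def masked_sample(observed_registry):
    """A case-cohort sample with 30% MCAR-incomplete covariates.

    Shared read-only input for imputation/estimation tests; tests must not
    mutate it.
    """
    params, spec = observed_registry
    rng = np.random.default_rng(424242)
    cohort = ccmi.generate_cohort(params, spec, 1200, rng)
    masked = induce_independent(cohort, 30.0, rng)
    return select_subcohort(masked, 0.40, rng), cohort
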
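import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from delaydisc import cohort as sc
from delaydisc import inference as inf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: quick profile for fits inside unit tests (diagnostics still meaningful)
QUICK_MCMC = inf.McmcConfig(n_chains=4, n_samples_per_chain=250, n_warmup=300, seed=11)


@pytest.fixture(scope="session")
def small_direct_cohort():
    """16-participant single-group cohort with split discount rates."""
    pos, _ = sc.direct_k_scenario(16)
    return sc.sample_cohort(pos, None, seed=3)


@pytest.fixture(scope="session")
def small_direct_data(small_direct_cohort):
    """Study-1 titration data generated on objective delays."""
    return sc.simulate_study1(small_direct_cohort, seed=3, time_basis="objective")


@pytest.fixture(scope="session")
def small_split_fit(small_direct_data):
    """Condition-split objective-basis fit of the small cohort."""
    spec = inf.DiscountModelSpec(k_structure="split_by_condition", time_basis="objective")
    return inf.fit_hierarchical(small_direct_data["choices"], spec, QUICK_MCMC)
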
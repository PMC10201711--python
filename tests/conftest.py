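import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seroselect as ss

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def small_tensor():
    """3 samples x 10 peptides x 4 replicates with hand-set signal."""
    rng = np.random.default_rng(42)
    rfu = rng.lognormal(np.log(400), 0.5, size=(3, 10, 4))
    # sample 0 binds peptide 0 (all replicates hot), sample 1 binds peptide 1
    rfu[0, 0, :] = [30000, 32000, 28000, 31000]
    rfu[1, 1, :] = [25000, 26000, 500, 27000]
    samples = ["A", "B", "C"]
    peptides = [f"pep{i}" for i in range(10)]
    return ss.BindingTensor(samples, peptides, rfu, n_replicates=4)


@pytest.fixture(scope="session")
def reference_annotations():
    return ss.reference_cohort_annotations()


@pytest.fixture(scope="session")
def simulated_default():
    """One default synthetic cohort shared across read-only tests."""
    return ss.simulate_cohort(ss.SimConfig(seed=123))
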
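import numpy as np
import pytest

from coxdist import (
    NetworkSpec,
    SurvivalDataset,
    SyntheticSpec,
    simulate_cohort,
    train_distribution_net,
    train_hazard,
)

# learning rate / epoch budget sized for full-batch Adam on cohorts of ~1000-2000
FAST_TRAIN = dict(learning_rate=1e-2, epochs=1500)

RECOVERY_BETA = (1.0, -1.0, 0.5, 0.0, 0.0)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Synthetic cohort with known log-hazard, 30% censoring, plus truth."""
    spec = SyntheticSpec(n=2000, beta=RECOVERY_BETA, censor_rate=0.3, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def holdout_cohort():
    """Independent cohort from the same generative truth, for held-out checks."""
    spec = SyntheticSpec(n=1000, beta=RECOVERY_BETA, censor_rate=0.3, seed=43)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def hazard_model(recovery_cohort):
    ds, _ = recovery_cohort
    return train_hazard(ds, NetworkSpec(seed=7, **FAST_TRAIN))


@pytest.fixture(scope="session")
def survival_model(recovery_cohort, hazard_model):
    ds, _ = recovery_cohort
    return train_distribution_net(ds, hazard_model, NetworkSpec(seed=8, **FAST_TRAIN))


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    n = 12
    return SurvivalDataset(
        rng.uniform(size=(n, 3)), ["a", "b", "c"],
        rng.uniform(1.0, 10.0, size=n), rng.integers(0, 2, size=n),
    )
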
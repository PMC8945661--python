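import numpy as np
import pandas as pd
import pytest

from tempodisc import CohortConfig, default_items, generate_dataset


@pytest.fixture(scope="session")
def items():
    return default_items()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast end-to-end tests."""
    return CohortConfig(
        group_sizes=(30, 20, 34),
        sex_counts_m=(12, 9, 20),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full 84/54/104 cohort at seed 1 (shared across tests)."""
    return generate_dataset(CohortConfig(seed=1))


def simulate_choices(rng, k, sigma, n_items):
    """Random items log-uniform inside the instrument ranges, with
    choices drawn from the hyperbolic/softmax model."""
    from scipy.special import expit

    ss = np.exp(rng.uniform(np.log(840), np.log(3990), n_items))
    ll = ss * np.exp(rng.uniform(np.log(1.2), np.log(3.0), n_items))
    dd = np.exp(rng.uniform(np.log(4), np.log(939), n_items))
    sv = ll / (1 + k * dd)
    chose = (rng.random(n_items) < expit(sigma * (ss - sv))).astype(float)
    items = pd.DataFrame({"item_id": np.arange(n_items), "ss_amount": ss,
                          "ll_amount": ll, "delay_days": dd})
    return chose, items
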
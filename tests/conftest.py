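import numpy as np
import pytest

import mistkit as mk


@pytest.fixture(scope="session")
def mist20():
    return mk.builtin_bank("MIST-20")


@pytest.fixture(scope="session")
def mist8():
    return mk.builtin_bank("MIST-8")


@pytest.fixture(scope="session")
def mist16():
    return mk.builtin_bank("MIST-16")


@pytest.fixture(scope="session")
def norms_us():
    return mk.load_norms("US", "MIST-20")


@pytest.fixture(scope="session")
def planted_2factor():
    """Binary data with two planted factors (10 items each, n=400)."""
    spec = mk.PoolSpec(n_factors=2, items_per_factor=10, loading_range=(0.6, 0.8))
    return mk.simulate_item_pool(spec, mk.SimConfig(n=400, seed=3))


@pytest.fixture(scope="session")
def planted_4factor():
    """Binary data with four planted factors (4 items each, n=1000)."""
    spec = mk.PoolSpec(n_factors=4, items_per_factor=4, loading_range=(0.65, 0.8))
    return mk.simulate_item_pool(spec, mk.SimConfig(n=1000, seed=11))


def random_response(bank, rng, p_fake=0.5, p_missing=0.0):
    labels = {}
    for it in bank.items:
        u = rng.random()
        if u < p_missing:
            labels[it.id] = "missing"
        else:
            labels[it.id] = "fake" if rng.random() < p_fake else "real"
    return mk.ResponseVector(respondent_id="r", labels=labels)
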
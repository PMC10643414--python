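import numpy as np
import pytest

from accessmarket import MarketParams, build_market, run_status_quo
from accessmarket.synth import SynthSpec, gen_market


@pytest.fixture
def params():
    """Baseline elasticities: eta=1 (cost), epsilon=2 (value)."""
    return MarketParams(eta=1.0, epsilon=2.0)


@pytest.fixture(scope="session")
def small_market():
    """A solved 6x6 synthetic market with status-quo policies, shared across tests."""
    syn = gen_market(SynthSpec(seed=11, n_sellers=6, n_buyers=6))
    market = build_market(syn.sellers, syn.buyers)
    return run_status_quo(market, **syn.anchor)


def random_endowments(rng, n):
    """Right-skewed positive endowments, normalized to shares."""
    v = rng.lognormal(0.0, 1.0, n)
    return v / v.sum()
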
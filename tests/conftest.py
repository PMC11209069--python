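import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def soa():
    """Calibrated Sea-of-Azov parametrisation (site, inputs, params)."""
    from hgbalance import soa_fixture

    return soa_fixture()


@pytest.fixture(scope="session")
def soa_solution(soa):
    """Steady-state solution of the Sea-of-Azov balance with frozen defaults."""
    from hgbalance import build_d_values, compute_loading_budget, solve_steady_state

    site, inputs, params = soa
    loads = compute_loading_budget(site, inputs, params)
    d = build_d_values(site, params)
    return solve_steady_state(loads, d, site, params), loads, d


@pytest.fixture(scope="session")
def scenarios_100():
    """100 seeded synthetic scenarios with oracle ground truths."""
    from hgbalance.synthetic import generate_site

    return [generate_site(seed) for seed in range(100)]
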
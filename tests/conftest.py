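import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tree():
    """6-leaf rooted amniote-like tree with labeled internal nodes."""
    from urnafate.synthetic_data import default_tree

    return default_tree()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """A fully noise-free simulated dataset with expression attached."""
    from urnafate.synthetic_data import (
        SimParams,
        default_tree,
        simulate_expression,
        simulate_family_evolution,
    )

    params = SimParams(seed=11, families=("U1", "U2", "U3"))
    ds = simulate_family_evolution(default_tree(), params)
    simulate_expression(ds, mean_depth=60.0, n_samples=4, seed=11)
    return ds
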
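import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hpcoevo as h

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def full_params() -> h.HPCParams:
    """Reference full-coevolution setting (the package defaults)."""
    return h.HPCParams()


@pytest.fixture
def decoupled_params(full_params) -> h.HPCParams:
    """Zero cross-utilities, no variation: two independent logistic maps."""
    from dataclasses import replace

    return replace(
        full_params,
        utility_per_capita_type_n_plants_to_humans=0.0,
        utility_per_capita_type_1_plants_to_humans=0.0,
        utility_per_capita_type_n_humans_to_plants=0.0,
        utility_per_capita_type_1_humans_to_plants=0.0,
        undirected_variation_humans=0.0,
        undirected_variation_plants=0.0,
    )


def random_valid_params(rng: np.random.Generator) -> h.HPCParams:
    """A random valid parameter set spanning the model's working ranges."""
    return h.HPCParams(
        initial_population_humans=float(rng.uniform(1, 200)),
        initial_population_plants=float(rng.uniform(1, 500)),
        number_types_humans=int(rng.integers(2, 12)),
        number_types_plants=int(rng.integers(2, 12)),
        undirected_variation_humans=float(rng.uniform(0, 0.5)),
        undirected_variation_plants=float(rng.uniform(0, 0.5)),
        intrinsic_growth_rate_humans=float(rng.uniform(0, 0.5)),
        intrinsic_growth_rate_plants=float(rng.uniform(0, 0.5)),
        utility_per_capita_type_n_plants_to_humans=float(rng.uniform(0, 3)),
        utility_per_capita_type_1_plants_to_humans=float(rng.uniform(0, 3)),
        utility_per_capita_type_n_humans_to_plants=float(rng.uniform(0, 3)),
        utility_per_capita_type_1_humans_to_plants=float(rng.uniform(0, 3)),
        utility_other_to_type_n_plants=float(rng.uniform(0, 150)),
        utility_other_to_type_1_plants=float(rng.uniform(0, 150)),
        utility_other_to_type_n_humans=float(rng.uniform(0, 150)),
        utility_other_to_type_1_humans=float(rng.uniform(0, 150)),
        max_area=float(rng.uniform(50, 2000)),
    )


def random_valid_state(params: h.HPCParams, rng: np.random.Generator) -> h.ModelState:
    pop_h = rng.uniform(0.05, 1.0, params.number_types_humans)
    pop_h /= pop_h.sum()
    pop_p = rng.uniform(0.05, 1.0, params.number_types_plants)
    pop_p /= pop_p.sum()
    return h.ModelState(
        humans=float(rng.uniform(0, 300)),
        plants=float(rng.uniform(0, 300)),
        type_proportions_humans=pop_h,
        type_proportions_plants=pop_p,
        time=0,
    )
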
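"""Pure per-step mathematics of the coupled mutualism/coevolution map.

One synchronous step composes, with everything frozen at the time-``t``
state:

1. aggregate utilities and baselines from the type mix,
2. carrying capacities (the plant one capped by ``max_area``),
3. per-type fitness scores from the weight of the partner's contribution,
4. a discrete logistic (Verhulst-Pearl) update of each population,
5. deterministic relaxation toward the uniform type mix (undirected
   variation) followed by a replicator update of the type proportions.

All functions are deterministic; no randomness enters the dynamics.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ParameterError, ReplicatorStagnationWarning
from .params import HPCParams, ModelState, StepDiagnostics, type_profiles

__all__ = [
    "interpolate_type_values",
    "aggregate_utilities",
    "carrying_capacities",
    "logistic_update",
    "undirected_variation",
    "fitness_scores",
    "replicator_update",
    "step",
    "diagnostics_at",
]


def interpolate_type_values(value_type_1: float, value_type_n: float, n: int) -> np.ndarray:
    """Per-type values: linear interpolation between the type-1 and type-n endpoints.

    Entry ``i`` (1-based) equals
    ``value_type_1 + (i - 1) * (value_type_n - value_type_1) / (n - 1)``;
    the first and last entries equal the two inputs exactly.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ParameterError("number of types n must be an integer >= 2")
    return np.linspace(float(value_type_1), float(value_type_n), int(n))


def aggregate_utilities(
    state: ModelState, params: HPCParams
) -> tuple[float, float, float, float]:
    """Population-level utilities ``(U_HP, U_PH, U_bH, U_bP)`` at the given state.

    Cross-utilities sum the per-capita contribution of each type weighted by
    its share and scaled by the giving population's size; baselines are the
    share-weighted per-type utilities from other resources.
    """
    prof = type_profiles(params)
    pop_h = state.type_proportions_humans
    pop_p = state.type_proportions_plants
    u_hp = state.humans * float(pop_h @ prof.utility_per_capita_humans_to_plants)
    u_ph = state.plants * float(pop_p @ prof.utility_per_capita_plants_to_humans)
    u_bh = float(pop_h @ prof.utility_other_to_humans)
    u_bp = float(pop_p @ prof.utility_other_to_plants)
    return u_hp, u_ph, u_bh, u_bp


def carrying_capacities(
    u_ph: float, u_bh: float, u_hp: float, u_bp: float, max_area: float
) -> tuple[float, float]:
    """``K_H = U_PH + U_bH``; ``K_P = min(U_HP + U_bP, max_area)``."""
    return u_ph + u_bh, min(u_hp + u_bp, max_area)


def logistic_update(pop: float, r: float, k: float) -> float:
    """Discrete logistic step ``pop + r*pop - r*pop**2/k``, clipped at 0.

    Zero carrying capacity is a declared degenerate case: the population
    decays as ``pop * (1 - r)`` (clipped at 0) rather than dividing by zero.
    """
    if pop < 0 or r < 0 or k < 0:
        raise ParameterError("logistic_update requires pop, r, k >= 0")
    if k == 0.0:
        return max(pop * (1.0 - r), 0.0)
    return max(pop + r * pop - r * pop * pop / k, 0.0)


def undirected_variation(pop: np.ndarray, v: float) -> np.ndarray:
    """Relax the type mix toward uniformity: ``pop + v * (1/n - pop)``.

    ``v = 0`` leaves the mix untouched; ``v = 1`` yields the uniform vector.
    """
    if not 0.0 <= v <= 1.0:
        raise ParameterError("undirected_variation level v must lie in [0, 1]")
    pop = np.asarray(pop, dtype=float)
    return pop + v * (1.0 / pop.size - pop)


def fitness_scores(n: int, u_b: float, u_other_pop: float) -> np.ndarray:
    """Per-type fitness ``((n - i) * U_b + i * U_other) / (U_b + U_other)``, i = 1..n.

    The score is affine in the type index: when the partner population
    contributes nothing the least mutualistic type wins (entry ``n - i``),
    and when other resources contribute nothing the most mutualistic type
    wins (entry ``i``). A zero denominator is a declared degenerate case
    returning a vector of ones (no selection).
    """
    if u_b < 0 or u_other_pop < 0:
        raise ParameterError("fitness_scores requires nonnegative utilities")
    idx = np.arange(1, int(n) + 1, dtype=float)
    total = u_b + u_other_pop
    if total == 0.0:
        return np.ones(int(n))
    return ((n - idx) * u_b + idx * u_other_pop) / total


def replicator_update(pop: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Reweight shares by fitness: ``f_i p_i / sum_j f_j p_j``.

    If the total fitness mass is zero the limit is undefined; the
    distribution is returned unchanged and a
    :class:`~hpcoevo.exceptions.ReplicatorStagnationWarning` is emitted.
    """
    pop = np.asarray(pop, dtype=float)
    weighted = np.asarray(fitness, dtype=float) * pop
    total = float(weighted.sum())
    if total == 0.0:
        warnings.warn(
            "total fitness mass is zero; type distribution frozen",
            ReplicatorStagnationWarning,
            stacklevel=2,
        )
        return pop.copy()
    return weighted / total


def _ols_slope(y: np.ndarray) -> float:
    """OLS slope of ``y`` against the 1-based index (no closed form assumed)."""
    x = np.arange(1, y.size + 1, dtype=float)
    return float(np.polyfit(x, np.asarray(y, dtype=float), 1)[0])


def _coevo(pop: np.ndarray) -> float:
    n = pop.size
    weights = np.arange(n, dtype=float) / (n - 1)
    return float(pop @ weights) * 2.0 - 1.0


def diagnostics_at(state: ModelState, params: HPCParams) -> StepDiagnostics:
    """All derived quantities of the time-``t`` state (no update applied)."""
    u_hp, u_ph, u_bh, u_bp = aggregate_utilities(state, params)
    k_h, k_p = carrying_capacities(u_ph, u_bh, u_hp, u_bp, params.max_area)
    fit_h = fitness_scores(params.number_types_humans, u_bh, u_ph)
    fit_p = fitness_scores(params.number_types_plants, u_bp, u_hp)
    return StepDiagnostics(
        utility_humans_to_plants=u_hp,
        utility_plants_to_humans=u_ph,
        utility_other_to_humans=u_bh,
        utility_other_to_plants=u_bp,
        carrying_capacity_humans=k_h,
        carrying_capacity_plants=k_p,
        fitness_humans=fit_h,
        fitness_plants=fit_p,
        coevolution_coefficient_humans=_coevo(state.type_proportions_humans),
        coevolution_coefficient_plants=_coevo(state.type_proportions_plants),
        dependency_coefficient_humans=_ols_slope(fit_h),
        dependency_coefficient_plants=_ols_slope(fit_p),
    )


def step(state: ModelState, params: HPCParams) -> tuple[ModelState, StepDiagnostics]:
    """One synchronous step: returns the time ``t+1`` state and time-``t`` diagnostics.

    Populations move by the logistic update with the time-``t`` carrying
    capacities; type mixes move by undirected variation followed by the
    replicator update with the time-``t`` fitness scores.
    """
    diag = diagnostics_at(state, params)
    new_h = logistic_update(
        state.humans, params.intrinsic_growth_rate_humans, diag.carrying_capacity_humans
    )
    new_p = logistic_update(
        state.plants, params.intrinsic_growth_rate_plants, diag.carrying_capacity_plants
    )
    stagnated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ReplicatorStagnationWarning)
        pop_h = replicator_update(
            undirected_variation(state.type_proportions_humans, params.undirected_variation_humans),
            diag.fitness_humans,
        )
        pop_p = replicator_update(
            undirected_variation(state.type_proportions_plants, params.undirected_variation_plants),
            diag.fitness_plants,
        )
        stagnated = any(issubclass(w.category, ReplicatorStagnationWarning) for w in caught)
    if stagnated:
        diag = StepDiagnostics(**{**diag.__dict__, "replicator_stagnated": True})
    # guard against float drift so the state invariant (sum == 1 within
    # 1e-12) survives arbitrarily long trajectories
    pop_h = pop_h / pop_h.sum()
    pop_p = pop_p / pop_p.sum()
    new_state = ModelState(
        humans=new_h,
        plants=new_p,
        type_proportions_humans=pop_h,
        type_proportions_plants=pop_p,
        time=state.time + 1,
    )
    return new_state, diag
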
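"""Trajectories, output statistics, end-state detection and classification.

A run iterates the synchronous step map until both population levels and
both type distributions change by less than ``10**-reltol_exponential``
between consecutive steps (an absolute tolerance on every component), or
until the iteration cap. Runs that hit the cap with sustained population
variance over the final window are classified as oscillatory; converged
runs are classified by comparing the final coevolution coefficients with
the coevolution threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core import (
    _coevo,
    _ols_slope,
    diagnostics_at,
    fitness_scores,
)
from .exceptions import NonConvergenceWarning
from .params import (
    HPCParams,
    ModelState,
    StepDiagnostics,
    initial_state,
    type_profiles,
)

__all__ = [
    "EndState",
    "Trajectory",
    "RunResult",
    "coevolution_coefficient",
    "dependency_coefficient",
    "has_converged",
    "register_timing",
    "classify_end_state",
    "run",
    "run_summary",
    "summarize_trajectory",
]

#: Fraction of the trajectory tail inspected for sustained oscillation.
OSCILLATION_WINDOW_FRACTION = 0.1
#: Oscillatory iff the tail variance exceeds max(REL * mean^2, ABS).
OSCILLATION_RELATIVE_VARIANCE = 1e-2
OSCILLATION_ABSOLUTE_VARIANCE = 1e-6


class EndState(str, Enum):
    """Terminal regime of a run."""

    NO_COEVOLUTION = "no_coevolution"
    FULL_COEVOLUTION = "full_coevolution"
    PARTIAL_STATIONARY = "partial_stationary"
    OSCILLATORY = "oscillatory"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def coevolution_coefficient(pop: np.ndarray) -> float:
    """Where a type distribution sits between all-type-1 (-1) and all-type-n (+1).

    ``(sum_i pop_i * (i - 1) / (n - 1)) * 2 - 1`` for 1-based type index i.
    """
    pop = np.asarray(pop, dtype=float)
    return _coevo(pop)


def dependency_coefficient(fitness: np.ndarray) -> float:
    """OLS slope of the fitness scores against the type index (1..n).

    Positive slope: selection favours the most mutualistic types; negative:
    the least. Computed as an actual least-squares fit, not a closed form.
    """
    fitness = np.asarray(fitness, dtype=float)
    if fitness.size < 2:
        raise ValueError("dependency_coefficient requires at least two types")
    return _ols_slope(fitness)


def has_converged(prev: ModelState, curr: ModelState, reltol_exponential: float) -> bool:
    """True iff every component changed by strictly less than ``10**-eps``.

    Checks both population levels and the sup-norm change of both type
    distributions, so a run only halts once the type mixes are stable too.
    """
    tol = 10.0 ** (-reltol_exponential)
    return (
        abs(curr.humans - prev.humans) < tol
        and abs(curr.plants - prev.plants) < tol
        and float(np.max(np.abs(curr.type_proportions_humans - prev.type_proportions_humans))) < tol
        and float(np.max(np.abs(curr.type_proportions_plants - prev.type_proportions_plants))) < tol
    )


def register_timing(coevo_series: Sequence[float], coevolution_threshold: float) -> int | None:
    """First index whose coefficient exceeds the threshold and never falls back.

    Returns ``None`` when no persistent crossing occurs. Oscillatory runs
    cross repeatedly; only a crossing sustained through the end of the
    series counts as a completed shift.
    """
    series = np.asarray(coevo_series, dtype=float)
    if series.size == 0:
        raise ValueError("coevolution series must be nonempty")
    below = np.flatnonzero(series <= coevolution_threshold)
    if below.size == 0:
        return 0
    candidate = int(below[-1]) + 1
    return candidate if candidate < series.size else None


def _is_oscillatory(humans: np.ndarray, plants: np.ndarray) -> bool:
    """Sustained variance over the last 10% of steps marks an oscillation."""
    window = max(2, int(round(OSCILLATION_WINDOW_FRACTION * humans.size)))
    for series in (humans[-window:], plants[-window:]):
        mean = float(series.mean())
        threshold = max(
            OSCILLATION_RELATIVE_VARIANCE * mean * mean, OSCILLATION_ABSOLUTE_VARIANCE
        )
        if float(series.var()) > threshold:
            return True
    return False


def classify_end_state(
    converged: bool,
    coevo_humans: float,
    coevo_plants: float,
    coevolution_threshold: float,
    humans_series: np.ndarray | None = None,
    plants_series: np.ndarray | None = None,
) -> EndState:
    """Map final coefficients and convergence status to one of the four regimes.

    Non-converged runs with sustained late-window population variance are
    oscillatory; otherwise the stationary rules apply (with a warning for
    slow, non-oscillating runs that merely ran out of iterations).
    """
    if not converged:
        if (
            humans_series is not None
            and plants_series is not None
            and _is_oscillatory(np.asarray(humans_series), np.asarray(plants_series))
        ):
            return EndState.OSCILLATORY
        warnings.warn(
            "run hit the iteration cap without converging or oscillating; "
            "classifying by the stationary rules",
            NonConvergenceWarning,
            stacklevel=2,
        )
    above_h = coevo_humans > coevolution_threshold
    above_p = coevo_plants > coevolution_threshold
    if above_h and above_p:
        return EndState.FULL_COEVOLUTION
    if above_h or above_p:
        return EndState.PARTIAL_STATIONARY
    return EndState.NO_COEVOLUTION


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed sequence of states and same-time diagnostics."""

    params: HPCParams
    states: tuple[ModelState, ...]
    diagnostics: tuple[StepDiagnostics, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.diagnostics):
            raise ValueError("states and diagnostics must have equal length")
        times = [s.time for s in self.states]
        if times != list(range(len(times))):
            raise ValueError("state times must increase from 0 in unit steps")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def humans(self) -> np.ndarray:
        return np.array([s.humans for s in self.states])

    @property
    def plants(self) -> np.ndarray:
        return np.array([s.plants for s in self.states])

    @property
    def coevolution_coefficient_humans(self) -> np.ndarray:
        return np.array([d.coevolution_coefficient_humans for d in self.diagnostics])

    @property
    def coevolution_coefficient_plants(self) -> np.ndarray:
        return np.array([d.coevolution_coefficient_plants for d in self.diagnostics])

    @property
    def carrying_capacity_plants(self) -> np.ndarray:
        return np.array([d.carrying_capacity_plants for d in self.diagnostics])

    @property
    def carrying_capacity_humans(self) -> np.ndarray:
        return np.array([d.carrying_capacity_humans for d in self.diagnostics])


@dataclass(frozen=True)
class RunResult:
    """End-state class, final coefficients, timings and duration of one run."""

    end_state_class: EndState
    final_state: ModelState
    coevolution_coefficient_humans: float
    coevolution_coefficient_plants: float
    dependency_coefficient_humans: float
    dependency_coefficient_plants: float
    timing_humans: int | None
    timing_plants: int | None
    time_end: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "end_state_class": self.end_state_class.value,
            "humans": self.final_state.humans,
            "plants": self.final_state.plants,
            "coevolution_coefficient_humans": self.coevolution_coefficient_humans,
            "coevolution_coefficient_plants": self.coevolution_coefficient_plants,
            "dependency_coefficient_humans": self.dependency_coefficient_humans,
            "dependency_coefficient_plants": self.dependency_coefficient_plants,
            "timing_humans": self.timing_humans,
            "timing_plants": self.timing_plants,
            "time_end": self.time_end,
            "converged": self.converged,
        }


def _simulate_arrays(
    params: HPCParams,
    pop_h0: np.ndarray,
    pop_p0: np.ndarray,
    record_types: bool,
) -> dict:
    """Fast array-level run loop shared by `run` and the sweep machinery."""
    prof = type_profiles(params)
    upc_hp = prof.utility_per_capita_humans_to_plants
    upc_ph = prof.utility_per_capita_plants_to_humans
    base_h = prof.utility_other_to_humans
    base_p = prof.utility_other_to_plants
    n_h = params.number_types_humans
    n_p = params.number_types_plants
    idx_h = np.arange(1, n_h + 1, dtype=float)
    idx_p = np.arange(1, n_p + 1, dtype=float)
    wc_h = 2.0 * (idx_h - 1.0) / (n_h - 1.0)
    wc_p = 2.0 * (idx_p - 1.0) / (n_p - 1.0)
    r_h = params.intrinsic_growth_rate_humans
    r_p = params.intrinsic_growth_rate_plants
    v_h = params.undirected_variation_humans
    v_p = params.undirected_variation_plants
    max_area = params.max_area
    tol = params.reltol
    t_max = params.max_iterations

    h = float(params.initial_population_humans)
    p = float(params.initial_population_plants)
    pop_h = np.array(pop_h0, dtype=float)
    pop_p = np.array(pop_p0, dtype=float)

    humans = np.empty(t_max + 1)
    plants = np.empty(t_max + 1)
    coevo_h = np.empty(t_max + 1)
    coevo_p = np.empty(t_max + 1)
    humans[0], plants[0] = h, p
    coevo_h[0] = float(pop_h @ wc_h) - 1.0
    coevo_p[0] = float(pop_p @ wc_p) - 1.0
    pops_h = [pop_h.copy()] if record_types else None
    pops_p = [pop_p.copy()] if record_types else None

    converged = False
    t_end = t_max
    uniform_h = 1.0 / n_h
    uniform_p = 1.0 / n_p
    for t in range(t_max):
        u_bh = float(pop_h @ base_h)
        u_bp = float(pop_p @ base_p)
        u_ph = p * float(pop_p @ upc_ph)
        u_hp = h * float(pop_h @ upc_hp)
        k_h = u_ph + u_bh
        k_p = min(u_hp + u_bp, max_area)

        # logistic updates with the time-t capacities
        if k_h == 0.0:
            h1 = max(h * (1.0 - r_h), 0.0)
        else:
            h1 = max(h + r_h * h - r_h * h * h / k_h, 0.0)
        if k_p == 0.0:
            p1 = max(p * (1.0 - r_p), 0.0)
        else:
            p1 = max(p + r_p * p - r_p * p * p / k_p, 0.0)

        # fitness with time-t utilities; affine in the type index
        tot_h = u_bh + u_ph
        if tot_h == 0.0:
            fit_h = np.ones(n_h)
        else:
            fit_h = ((n_h - idx_h) * u_bh + idx_h * u_ph) / tot_h
        tot_p = u_bp + u_hp
        if tot_p == 0.0:
            fit_p = np.ones(n_p)
        else:
            fit_p = ((n_p - idx_p) * u_bp + idx_p * u_hp) / tot_p

        # undirected variation then replicator, frozen at time-t fitness
        var_h = pop_h + v_h * (uniform_h - pop_h)
        var_p = pop_p + v_p * (uniform_p - pop_p)
        w_h = fit_h * var_h
        s_h = float(w_h.sum())
        new_pop_h = var_h if s_h == 0.0 else w_h / s_h
        w_p = fit_p * var_p
        s_p = float(w_p.sum())
        new_pop_p = var_p if s_p == 0.0 else w_p / s_p

        step_converged = (
            abs(h1 - h) < tol
            and abs(p1 - p) < tol
            and float(np.max(np.abs(new_pop_h - pop_h))) < tol
            and float(np.max(np.abs(new_pop_p - pop_p))) < tol
        )

        h, p = h1, p1
        pop_h, pop_p = new_pop_h, new_pop_p
        humans[t + 1], plants[t + 1] = h, p
        coevo_h[t + 1] = float(pop_h @ wc_h) - 1.0
        coevo_p[t + 1] = float(pop_p @ wc_p) - 1.0
        if record_types:
            pops_h.append(pop_h.copy())
            pops_p.append(pop_p.copy())
        if step_converged:
            converged = True
            t_end = t + 1
            break

    n_rec = t_end + 1
    out = {
        "humans": humans[:n_rec],
        "plants": plants[:n_rec],
        "coevo_humans": coevo_h[:n_rec],
        "coevo_plants": coevo_p[:n_rec],
        "final_pop_humans": pop_h,
        "final_pop_plants": pop_p,
        "time_end": t_end,
        "converged": converged,
    }
    if record_types:
        out["pops_humans"] = pops_h
        out["pops_plants"] = pops_p
    return out


def _result_from_arrays(params: HPCParams, arrays: dict) -> RunResult:
    final = ModelState(
        humans=float(arrays["humans"][-1]),
        plants=float(arrays["plants"][-1]),
        type_proportions_humans=arrays["final_pop_humans"] / arrays["final_pop_humans"].sum(),
        type_proportions_plants=arrays["final_pop_plants"] / arrays["final_pop_plants"].sum(),
        time=arrays["time_end"],
    )
    diag = diagnostics_at(final, params)
    end_state = classify_end_state(
        arrays["converged"],
        diag.coevolution_coefficient_humans,
        diag.coevolution_coefficient_plants,
        params.coevolution_threshold,
        arrays["humans"],
        arrays["plants"],
    )
    return RunResult(
        end_state_class=end_state,
        final_state=final,
        coevolution_coefficient_humans=diag.coevolution_coefficient_humans,
        coevolution_coefficient_plants=diag.coevolution_coefficient_plants,
        dependency_coefficient_humans=diag.dependency_coefficient_humans,
        dependency_coefficient_plants=diag.dependency_coefficient_plants,
        timing_humans=register_timing(arrays["coevo_humans"], params.coevolution_threshold),
        timing_plants=register_timing(arrays["coevo_plants"], params.coevolution_threshold),
        time_end=arrays["time_end"],
        converged=arrays["converged"],
    )


def run(
    params: HPCParams,
    type_proportions_humans: np.ndarray | None = None,
    type_proportions_plants: np.ndarray | None = None,
) -> tuple[Trajectory, RunResult]:
    """Simulate from the initial state until convergence or the iteration cap.

    Returns the full trajectory (states plus same-time diagnostics) and the
    summarised result. The dynamics are deterministic: identical inputs
    yield identical outputs.
    """
    start = initial_state(params, type_proportions_humans, type_proportions_plants)
    arrays = _simulate_arrays(
        params, start.type_proportions_humans, start.type_proportions_plants, record_types=True
    )
    states = [
        ModelState(
            humans=float(arrays["humans"][t]),
            plants=float(arrays["plants"][t]),
            type_proportions_humans=arrays["pops_humans"][t],
            type_proportions_plants=arrays["pops_plants"][t],
            time=t,
        )
        for t in range(arrays["time_end"] + 1)
    ]
    diagnostics = [diagnostics_at(s, params) for s in states]
    trajectory = Trajectory(params=params, states=tuple(states), diagnostics=tuple(diagnostics))
    return trajectory, _result_from_arrays(params, arrays)


def run_summary(
    params: HPCParams,
    type_proportions_humans: np.ndarray | None = None,
    type_proportions_plants: np.ndarray | None = None,
) -> RunResult:
    """Like :func:`run` but skips trajectory materialisation (used by sweeps)."""
    start = initial_state(params, type_proportions_humans, type_proportions_plants)
    arrays = _simulate_arrays(
        params, start.type_proportions_humans, start.type_proportions_plants, record_types=False
    )
    return _result_from_arrays(params, arrays)


def summarize_trajectory(trajectory: Trajectory) -> RunResult:
    """Recompute the run summary from a recorded trajectory."""
    params = trajectory.params
    states = trajectory.states
    converged = len(states) >= 2 and has_converged(
        states[-2], states[-1], params.reltol_exponential
    )
    arrays = {
        "humans": trajectory.humans,
        "plants": trajectory.plants,
        "coevo_humans": trajectory.coevolution_coefficient_humans,
        "coevo_plants": trajectory.coevolution_coefficient_plants,
        "final_pop_humans": states[-1].type_proportions_humans,
        "final_pop_plants": states[-1].type_proportions_plants,
        "time_end": states[-1].time,
        "converged": converged,
    }
    return _result_from_arrays(params, arrays)
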
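"""Model parameters, state, and per-step diagnostics.

The model couples a human and a plant population through mutualistic
utilities. Each population is split into ``n`` ordered types, from the least
(type 1) to the most (type n) mutualistic; per-type utilities are linear
interpolations between the type-1 and type-n endpoint parameters. Field
names follow the R notation of the original description (e.g.
``utility_per_capita_type_n_plants_to_humans``) so configuration files and
output tables are self-documenting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from functools import lru_cache
from typing import Iterator

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "HPCParams",
    "ModelState",
    "StepDiagnostics",
    "TypeProfiles",
    "type_profiles",
    "PARAM_FIELD_NAMES",
    "INTEGER_FIELDS",
    "EXPLORABLE_FIELDS",
]

#: Fields that must hold integers.
INTEGER_FIELDS = frozenset(
    {"number_types_humans", "number_types_plants", "max_iterations"}
)

#: The 15 parameters explored in sensitivity analyses (all model parameters
#: except the two initial populations and the three run-control settings).
EXPLORABLE_FIELDS = (
    "number_types_humans",
    "number_types_plants",
    "undirected_variation_humans",
    "undirected_variation_plants",
    "intrinsic_growth_rate_humans",
    "intrinsic_growth_rate_plants",
    "utility_per_capita_type_n_plants_to_humans",
    "utility_per_capita_type_1_plants_to_humans",
    "utility_per_capita_type_n_humans_to_plants",
    "utility_per_capita_type_1_humans_to_plants",
    "utility_other_to_type_n_plants",
    "utility_other_to_type_1_plants",
    "utility_other_to_type_n_humans",
    "utility_other_to_type_1_humans",
    "max_area",
)


def _require(cond: bool, name: str, constraint: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {constraint}")


@dataclass(frozen=True)
class HPCParams:
    """The 17 model parameters plus the three run-control settings.

    Defaults are the package's reference setting: a full-coevolution
    scenario in which both populations shift to the most mutualistic types
    (see :mod:`hpcoevo.presets`).
    """

    initial_population_humans: float = 10.0
    initial_population_plants: float = 100.0
    number_types_humans: int = 10
    number_types_plants: int = 10
    undirected_variation_humans: float = 0.05
    undirected_variation_plants: float = 0.05
    intrinsic_growth_rate_humans: float = 0.05
    intrinsic_growth_rate_plants: float = 0.1
    utility_per_capita_type_n_plants_to_humans: float = 1.5
    utility_per_capita_type_1_plants_to_humans: float = 0.4
    utility_per_capita_type_n_humans_to_plants: float = 2.0
    utility_per_capita_type_1_humans_to_plants: float = 0.5
    utility_other_to_type_n_plants: float = 20.0
    utility_other_to_type_1_plants: float = 100.0
    utility_other_to_type_n_humans: float = 2.0
    utility_other_to_type_1_humans: float = 80.0
    max_area: float = 1000.0
    max_iterations: int = 5000
    reltol_exponential: float = 6.0
    coevolution_threshold: float = 0.5

    def __post_init__(self) -> None:
        p = self
        _require(p.initial_population_humans >= 0, "initial_population_humans", "must be >= 0")
        _require(p.initial_population_plants >= 0, "initial_population_plants", "must be >= 0")
        for name in ("number_types_humans", "number_types_plants"):
            v = getattr(p, name)
            _require(isinstance(v, (int, np.integer)) and not isinstance(v, bool), name, "must be an integer")
            _require(v >= 2, name, "must be >= 2")
        for name in ("undirected_variation_humans", "undirected_variation_plants"):
            _require(0.0 <= getattr(p, name) <= 1.0, name, "must lie in [0, 1]")
        for name in ("intrinsic_growth_rate_humans", "intrinsic_growth_rate_plants"):
            _require(getattr(p, name) >= 0, name, "must be >= 0")
        for name in (
            "utility_per_capita_type_n_plants_to_humans",
            "utility_per_capita_type_1_plants_to_humans",
            "utility_per_capita_type_n_humans_to_plants",
            "utility_per_capita_type_1_humans_to_plants",
            "utility_other_to_type_n_plants",
            "utility_other_to_type_1_plants",
            "utility_other_to_type_n_humans",
            "utility_other_to_type_1_humans",
        ):
            _require(getattr(p, name) >= 0, name, "must be >= 0")
        _require(p.max_area > 0, "max_area", "must be > 0 (may be infinite)")
        _require(
            isinstance(p.max_iterations, (int, np.integer)) and not isinstance(p.max_iterations, bool),
            "max_iterations", "must be an integer",
        )
        _require(p.max_iterations >= 1, "max_iterations", "must be >= 1")
        _require(p.reltol_exponential > 0, "reltol_exponential", "must be > 0")
        _require(
            -1.0 < p.coevolution_threshold < 1.0,
            "coevolution_threshold", "must lie in (-1, 1)",
        )

    @property
    def reltol(self) -> float:
        """Absolute convergence tolerance, ``10**-reltol_exponential``."""
        return 10.0 ** (-self.reltol_exponential)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PARAM_FIELD_NAMES: tuple[str, ...] = tuple(f.name for f in fields(HPCParams))


@dataclass(frozen=True)
class TypeProfiles:
    """Per-type parameter vectors implied by the interpolation endpoints."""

    utility_per_capita_humans_to_plants: np.ndarray  # length n_H
    utility_per_capita_plants_to_humans: np.ndarray  # length n_P
    utility_other_to_humans: np.ndarray  # length n_H
    utility_other_to_plants: np.ndarray  # length n_P


@lru_cache(maxsize=256)
def _profiles(
    n_h: int, n_p: int,
    u_h1p: float, u_hnp: float, u_p1h: float, u_pnh: float,
    u_bh1: float, u_bhn: float, u_bp1: float, u_bpn: float,
) -> TypeProfiles:
    return TypeProfiles(
        utility_per_capita_humans_to_plants=np.linspace(u_h1p, u_hnp, n_h),
        utility_per_capita_plants_to_humans=np.linspace(u_p1h, u_pnh, n_p),
        utility_other_to_humans=np.linspace(u_bh1, u_bhn, n_h),
        utility_other_to_plants=np.linspace(u_bp1, u_bpn, n_p),
    )


def type_profiles(params: HPCParams) -> TypeProfiles:
    """Interpolated per-type utility vectors for ``params`` (cached)."""
    return _profiles(
        params.number_types_humans,
        params.number_types_plants,
        params.utility_per_capita_type_1_humans_to_plants,
        params.utility_per_capita_type_n_humans_to_plants,
        params.utility_per_capita_type_1_plants_to_humans,
        params.utility_per_capita_type_n_plants_to_humans,
        params.utility_other_to_type_1_humans,
        params.utility_other_to_type_n_humans,
        params.utility_other_to_type_1_plants,
        params.utility_other_to_type_n_plants,
    )


def _check_proportions(vec: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    _require(arr.ndim == 1 and arr.size >= 2, name, "must be a vector of length >= 2")
    _require(bool(np.all(arr >= 0)), name, "entries must be >= 0")
    _require(abs(float(arr.sum()) - 1.0) <= 1e-12, name, "entries must sum to 1 within 1e-12")
    return arr


@dataclass(frozen=True)
class ModelState:
    """Populations and type-proportion vectors at one time step."""

    humans: float
    plants: float
    type_proportions_humans: np.ndarray
    type_proportions_plants: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        _require(self.humans >= 0, "humans", "must be >= 0")
        _require(self.plants >= 0, "plants", "must be >= 0")
        _require(self.time >= 0, "time", "must be >= 0")
        object.__setattr__(
            self, "type_proportions_humans",
            _check_proportions(self.type_proportions_humans, "type_proportions_humans"),
        )
        object.__setattr__(
            self, "type_proportions_plants",
            _check_proportions(self.type_proportions_plants, "type_proportions_plants"),
        )

    def __iter__(self) -> Iterator:
        yield from (self.humans, self.plants,
                    self.type_proportions_humans, self.type_proportions_plants)


@dataclass(frozen=True)
class StepDiagnostics:
    """Derived quantities of one step, computed from the same-time state.

    ``utility_humans_to_plants``/``utility_plants_to_humans`` are the
    aggregate cross-utilities, ``utility_other_to_*`` the baseline carrying
    capacities, ``fitness_*`` the per-type selection scores, and the
    coevolution/dependency coefficients summarise where each type
    distribution sits and which end of the spectrum selection favours.
    """

    utility_humans_to_plants: float
    utility_plants_to_humans: float
    utility_other_to_humans: float
    utility_other_to_plants: float
    carrying_capacity_humans: float
    carrying_capacity_plants: float
    fitness_humans: np.ndarray
    fitness_plants: np.ndarray
    coevolution_coefficient_humans: float
    coevolution_coefficient_plants: float
    dependency_coefficient_humans: float
    dependency_coefficient_plants: float
    replicator_stagnated: bool = False


def initial_state(
    params: HPCParams,
    type_proportions_humans: np.ndarray | None = None,
    type_proportions_plants: np.ndarray | None = None,
) -> ModelState:
    """Starting state: all mass on the least mutualistic type unless overridden."""
    if type_proportions_humans is None:
        type_proportions_humans = np.zeros(params.number_types_humans)
        type_proportions_humans[0] = 1.0
    if type_proportions_plants is None:
        type_proportions_plants = np.zeros(params.number_types_plants)
        type_proportions_plants[0] = 1.0
    return ModelState(
        humans=params.initial_population_humans,
        plants=params.initial_population_plants,
        type_proportions_humans=np.asarray(type_proportions_humans, dtype=float),
        type_proportions_plants=np.asarray(type_proportions_plants, dtype=float),
        time=0,
    )
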
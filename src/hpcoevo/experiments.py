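"""Parameter-space exploration: grids, Latin hypercube samples, importance
ranking of the coevolution/dependency coefficients, and tipping-point search.

Sweeps are deterministic given (design, seed). Latin hypercube samples are
drawn with one point per marginal stratum and selected among a fixed number
of candidate hypercubes by the maximin criterion (largest minimal pairwise
distance in normalised coordinates), a space-filling stand-in for
point-process design optimisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import qmc
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, train_test_split

from .exceptions import DegenerateTargetError, DesignError, NoBracketError
from .params import HPCParams, INTEGER_FIELDS, PARAM_FIELD_NAMES
from .simulate import EndState, run_summary

__all__ = [
    "SweepDesign",
    "SweepResult",
    "sample_lhs",
    "run_sweep",
    "rank_parameter_importance",
    "find_tipping_point",
    "IMPORTANCE_TARGETS",
]

#: Output columns recorded for every run of a sweep.
OUTPUT_COLUMNS = (
    "humans",
    "plants",
    "coevolution_coefficient_humans",
    "coevolution_coefficient_plants",
    "dependency_coefficient_humans",
    "dependency_coefficient_plants",
    "timing_humans",
    "timing_plants",
    "time_end",
    "converged",
    "end_state_class",
)

#: Short aliases accepted by :func:`rank_parameter_importance`.
IMPORTANCE_TARGETS: dict[str, str] = {
    "coevo_H": "coevolution_coefficient_humans",
    "coevo_P": "coevolution_coefficient_plants",
    "depend_H": "dependency_coefficient_humans",
    "depend_P": "dependency_coefficient_plants",
    "timing_H": "timing_humans",
    "timing_P": "timing_plants",
}

_INITIAL_POPULATION_FIELDS = ("initial_population_humans", "initial_population_plants")


def _validate_names(names: Sequence[str]) -> None:
    for name in names:
        if name not in PARAM_FIELD_NAMES:
            raise DesignError(f"unknown model parameter in design: {name!r}")


@dataclass(frozen=True)
class SweepDesign:
    """A grid or Latin-hypercube exploration over named model parameters."""

    mode: str  # "grid" | "lhs"
    grids: Mapping[str, Sequence[float]] | None = None
    ranges: Mapping[str, tuple[float, float]] | None = None
    n_samples: int = 1
    seed: int = 0
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("grid", "lhs"):
            raise DesignError(f"mode must be 'grid' or 'lhs', got {self.mode!r}")
        if self.mode == "grid":
            if not self.grids:
                raise DesignError("grid mode requires non-empty per-parameter grids")
            _validate_names(list(self.grids))
            for name, values in self.grids.items():
                if len(values) < 1:
                    raise DesignError(f"grid for {name!r} is empty")
        else:
            if not self.ranges:
                raise DesignError("lhs mode requires non-empty per-parameter ranges")
            _validate_names(list(self.ranges))
            for name, (lo, hi) in self.ranges.items():
                if not (math.isfinite(lo) and math.isfinite(hi)):
                    raise DesignError(f"range for {name!r} must be finite")
                if lo > hi:
                    raise DesignError(f"range for {name!r} has lower > upper")
            if self.n_samples < 1:
                raise DesignError("n_samples must be >= 1")

    @classmethod
    def grid(cls, grids: Mapping[str, Sequence[float]], **kwargs) -> "SweepDesign":
        return cls(mode="grid", grids=grids, **kwargs)

    @classmethod
    def lhs(
        cls, ranges: Mapping[str, tuple[float, float]], n_samples: int, seed: int = 0, **kwargs
    ) -> "SweepDesign":
        return cls(mode="lhs", ranges=ranges, n_samples=n_samples, seed=seed, **kwargs)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.grids) if self.mode == "grid" else list(self.ranges)

    def points(self) -> list[dict[str, float]]:
        """The explicit list of parameter vectors this design encodes."""
        if self.mode == "grid":
            names = list(self.grids)
            return [
                dict(zip(names, combo))
                for combo in itertools.product(*(self.grids[n] for n in names))
            ]
        return sample_lhs(self.ranges, self.n_samples, self.seed)


@dataclass(frozen=True)
class SweepResult:
    """One tidy record per run: the parameter vector plus all run outputs."""

    design: SweepDesign
    base: HPCParams
    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def sample_lhs(
    ranges: Mapping[str, tuple[float, float]],
    n_samples: int,
    seed: int = 0,
    n_candidates: int = 20,
) -> list[dict[str, float]]:
    """Maximin-selected Latin hypercube sample over the given ranges.

    Each marginal is stratified into ``n_samples`` equal bins with exactly
    one sample per bin. ``n_candidates`` hypercubes are drawn and the one
    with the largest minimal pairwise distance (in normalised coordinates)
    is returned. Deterministic for a given seed.
    """
    _validate_names(list(ranges))
    names = list(ranges)
    for name, (lo, hi) in ranges.items():
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise DesignError(f"range for {name!r} must be finite")
        if lo > hi:
            raise DesignError(f"range for {name!r} has lower > upper")
    if n_samples < 1:
        raise DesignError("n_samples must be >= 1")
    lower = np.array([ranges[n][0] for n in names])
    upper = np.array([ranges[n][1] for n in names])
    root = np.random.SeedSequence(seed)
    best_unit = None
    best_score = -np.inf
    for child in root.spawn(max(1, n_candidates)):
        sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(child))
        unit = sampler.random(n_samples)
        score = float(pdist(unit).min()) if n_samples > 1 else 0.0
        if score > best_score:
            best_score = score
            best_unit = unit
    scaled = qmc.scale(best_unit, lower, upper)
    return [dict(zip(names, map(float, row))) for row in scaled]


def _apply_point(base: HPCParams, point: Mapping[str, float]) -> HPCParams:
    cast = {
        name: int(round(value)) if name in INTEGER_FIELDS else float(value)
        for name, value in point.items()
    }
    return replace(base, **cast)


def run_sweep(design: SweepDesign, base: HPCParams | None = None) -> SweepResult:
    """Execute one run per design point, overriding ``base`` with its values."""
    if base is None:
        base = HPCParams()
    if design.max_iterations is not None:
        base = replace(base, max_iterations=design.max_iterations)
    records = []
    for point in design.points():
        params = _apply_point(base, point)
        result = run_summary(params)
        record = {name: getattr(params, name) for name in design.parameter_names}
        summary = result.to_dict()
        record.update(
            {
                "humans": summary["humans"],
                "plants": summary["plants"],
                "coevolution_coefficient_humans": summary["coevolution_coefficient_humans"],
                "coevolution_coefficient_plants": summary["coevolution_coefficient_plants"],
                "dependency_coefficient_humans": summary["dependency_coefficient_humans"],
                "dependency_coefficient_plants": summary["dependency_coefficient_plants"],
                "timing_humans": summary["timing_humans"],
                "timing_plants": summary["timing_plants"],
                "time_end": summary["time_end"],
                "converged": summary["converged"],
                "end_state_class": summary["end_state_class"],
            }
        )
        records.append(record)
    columns = design.parameter_names + list(OUTPUT_COLUMNS)
    return SweepResult(design=design, base=base, data=pd.DataFrame(records, columns=columns))


def rank_parameter_importance(
    sweep: SweepResult | pd.DataFrame,
    target: str,
    seed: int = 0,
    include_initial_populations: bool = False,
    n_estimators_grid: Sequence[int] = (100, 200),
    max_features_grid: Sequence = ("sqrt", 0.33, 1.0),
) -> pd.DataFrame:
    """Rank parameters by their power to predict a run-level output.

    Fits a random-forest regressor with the sweep's parameter columns as
    predictors, tuning the tree count and predictors-per-split by 10-fold
    cross-validation, then reports both the permutation importance
    (computed on a held-out quarter of the records, the %IncMSE analogue)
    and the impurity-decrease importance, sorted descending by the
    permutation measure. Initial populations are excluded by default.
    """
    data = sweep.data if isinstance(sweep, SweepResult) else sweep
    column = IMPORTANCE_TARGETS.get(target, target)
    if column not in data.columns:
        raise DesignError(
            f"unknown importance target {target!r}; expected one of "
            f"{sorted(IMPORTANCE_TARGETS)} or a result column name"
        )
    predictors = [c for c in data.columns if c in PARAM_FIELD_NAMES]
    if not include_initial_populations:
        predictors = [c for c in predictors if c not in _INITIAL_POPULATION_FIELDS]
    if not predictors:
        raise DesignError("sweep table contains no parameter columns to rank")
    subset = data[predictors + [column]].dropna()
    if len(subset) < 50:
        raise DesignError(
            f"importance ranking needs >= 50 usable records, got {len(subset)}"
        )
    y = subset[column].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        raise DegenerateTargetError(f"target {column!r} is constant across the sweep")
    X = subset[predictors].to_numpy(dtype=float)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=0.25, random_state=seed
    )
    search = GridSearchCV(
        RandomForestRegressor(random_state=seed),
        {
            "n_estimators": list(n_estimators_grid),
            "max_features": list(max_features_grid),
        },
        cv=10,
        n_jobs=1,
    )
    search.fit(X_train, y_train)
    forest = search.best_estimator_
    perm = permutation_importance(
        forest, X_test, y_test, n_repeats=10, random_state=seed
    )
    table = pd.DataFrame(
        {
            "parameter": predictors,
            "permutation_importance": perm.importances_mean,
            "impurity_importance": forest.feature_importances_,
        }
    ).sort_values("permutation_importance", ascending=False, ignore_index=True)
    table.attrs["best_hyperparameters"] = search.best_params_
    return table


def _classify_at(base: HPCParams, parameter: str, value: float) -> EndState:
    return run_summary(_apply_point(base, {parameter: value})).end_state_class


def find_tipping_point(
    base: HPCParams,
    parameter: str,
    bracket: tuple[float, float],
    rel_tol: float = 1e-3,
) -> float:
    """Bisect a parameter axis for the end-state class boundary.

    Requires the classes at the bracket ends to differ; narrows the bracket
    until its width falls below ``rel_tol`` times the initial width and
    returns the midpoint.
    """
    _validate_names([parameter])
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise DesignError("bracket must satisfy lo < hi")
    class_lo = _classify_at(base, parameter, lo)
    class_hi = _classify_at(base, parameter, hi)
    if class_lo == class_hi:
        raise NoBracketError(
            f"end-state class {class_lo.value!r} is identical at both bracket "
            f"ends of {parameter!r}; no boundary to bisect"
        )
    width_target = rel_tol * (hi - lo)
    while hi - lo > width_target:
        mid = 0.5 * (lo + hi)
        if _classify_at(base, parameter, mid) == class_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
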
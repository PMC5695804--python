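"""Parameter estimation: training objectives, optimizers, ensembles, AIC.

The training residual for one objective j is the two-term form

    O_j(k) = sum_i (Mhat_ij - yhat_ij)^2 + ((M'_j - max_i y_ij) / M'_j)^2

where hats denote min-max scaling over the sampled time points (lowest value
maps to 0, highest to 1), so the first term compares trajectory *shape*
while the second compares the absolute concentration *scale*: M'_j is the
largest measured concentration and max_i y_ij the largest simulated value.

Two objectives are trained by default: O1, the total C3a + C5a residual
without initiator, and O2, the same at the 1 mg/ml reference dose.

Search runs in log10 parameter space (kinetic constants span decades):
a hybrid warm start (multi-swarm particle swarm followed by dynamically
dimensioned search) minimizes the summed objective, then a multiobjective
simulated-annealing walk grows a Pareto archive of parameter sets whose
trade-off front approximates the optimal O1/O2 surface.  Fit quality is
scored by the Akaike information criterion against a log-uniform
random-parameter control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ModelDefinition
from .reaction_core import ParameterSet
from .simulator import Condition, IntegrationError, Trajectory, simulate

__all__ = [
    "DegenerateScalingError",
    "MeasurementTable",
    "TrainingObjective",
    "default_objectives",
    "scale_measurements",
    "objective",
    "summed_objective",
    "OptimizationResult",
    "dops_minimize",
    "dops_warm_start",
    "pareto_rank",
    "pareto_anneal",
    "ParameterEnsemble",
    "poets_ensemble",
    "aic",
    "aic_score",
    "random_parameter_control",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("condition", "dose_mg_ml", "species", "time", "value",
                       "units")


class DegenerateScalingError(ValueError):
    """Min-max scaling of a constant series is undefined."""


@dataclass
class MeasurementTable:
    """Observed species time series keyed by experimental condition.

    Wraps a tidy DataFrame with columns ``condition, dose_mg_ml, species,
    time, value, units`` and an optional ``split`` tag (train/validate).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        if (frame["time"] < 0).any():
            raise ValueError("measurement times must be non-negative")
        if (frame["value"] < 0).any():
            raise ValueError("measurement values must be non-negative")
        counts = frame.groupby(["condition", "species"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(
                f"need >= 2 time points per (condition, species); got {bad}"
            )

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def conditions(self) -> pd.DataFrame:
        return (
            self.frame[["condition", "dose_mg_ml"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def doses(self) -> np.ndarray:
        return np.sort(self.frame["dose_mg_ml"].unique())

    def series(self, dose: float, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one dose and species, time-sorted."""
        sel = self.frame[
            np.isclose(self.frame["dose_mg_ml"], dose)
            & (self.frame["species"] == species)
        ].sort_values("time")
        if sel.empty:
            raise KeyError(f"no measurements for dose={dose}, species={species!r}")
        return sel["time"].to_numpy(float), sel["value"].to_numpy(float)

    def n_measurements(self) -> int:
        return len(self.frame)

    def max_time(self, dose: float | None = None) -> float:
        frame = self.frame
        if dose is not None:
            frame = frame[np.isclose(frame["dose_mg_ml"], dose)]
        return float(frame["time"].max())


@dataclass(frozen=True)
class TrainingObjective:
    """One training objective: a dose bound to the species it scores."""

    label: str
    dose: float
    species: tuple[str, ...] = ("C3a", "C5a")


def default_objectives() -> list[TrainingObjective]:
    """O1: C3a+C5a residual without initiator; O2: at 1 mg/ml initiator."""
    return [
        TrainingObjective("O1", 0.0),
        TrainingObjective("O2", 1.0),
    ]


def scale_measurements(values: Sequence[float]) -> np.ndarray:
    """Min-max scale a series: (M - min) / (max - min)."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateScalingError("cannot min-max scale a constant series")
    return (v - lo) / (hi - lo)


def objective(
    params: ParameterSet,
    model: ModelDefinition,
    data: MeasurementTable,
    obj: TrainingObjective,
    traj: Trajectory | None = None,
    **sim_kwargs,
) -> float:
    """Shape + scale residual of one training objective.

    The simulation is interpolated to the measurement times, both series are
    min-max scaled for the shape term, and the scale term compares the
    largest measured concentration with the largest simulated value.
    Integration failure returns ``inf`` (with the cause logged) so
    optimizers treat the point as infeasible.
    """
    if traj is None:
        horizon = data.max_time(obj.dose)
        try:
            traj = simulate(
                model, params, condition=Condition(initiator_dose=obj.dose),
                t_span=(0.0, horizon), **sim_kwargs,
            )
        except IntegrationError as err:
            log.warning("objective %s: simulation failed: %s", obj.label, err)
            return math.inf
    total = 0.0
    for species in obj.species:
        times, measured = data.series(obj.dose, species)
        simulated = traj.at(species, times)
        try:
            m_hat = scale_measurements(measured)
        except DegenerateScalingError:
            raise DegenerateScalingError(
                f"constant measurement series for dose={obj.dose}, "
                f"species={species!r}"
            ) from None
        lo, hi = simulated.min(), simulated.max()
        y_hat = (
            np.zeros_like(simulated) if hi == lo
            else (simulated - lo) / (hi - lo)
        )
        m_scale = measured.max()
        total += float(np.sum((m_hat - y_hat) ** 2))
        total += float(((m_scale - simulated.max()) / m_scale) ** 2)
    return total


def objective_vector(
    params: ParameterSet,
    model: ModelDefinition,
    data: MeasurementTable,
    objectives: Sequence[TrainingObjective],
    **sim_kwargs,
) -> np.ndarray:
    return np.array(
        [objective(params, model, data, o, **sim_kwargs) for o in objectives]
    )


def summed_objective(
    params: ParameterSet,
    model: ModelDefinition,
    data: MeasurementTable,
    objectives: Sequence[TrainingObjective],
    **sim_kwargs,
) -> float:
    return float(np.sum(objective_vector(params, model, data, objectives,
                                         **sim_kwargs)))


# ---------------------------------------------------------------------------
# Hybrid warm-start optimizer (multi-swarm PSO -> dynamically dimensioned
# search), generic over array-valued objectives
# ---------------------------------------------------------------------------


@dataclass
class OptimizationResult:
    x: np.ndarray
    fun: float
    n_eval: int


def dops_minimize(
    fn: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    budget: int,
    seed: int,
    x0: np.ndarray | None = None,
    n_swarms: int = 3,
    particles_per_swarm: int = 8,
    switch_fraction: float = 0.2,
    stagnation_limit: int = 25,
) -> OptimizationResult:
    """Hybrid global-then-greedy search within box bounds.

    Phase 1 runs several independent particle swarms (sharing only their
    final best); phase 2 runs dynamically dimensioned search: a shrinking,
    randomly chosen subset of dimensions of the incumbent is perturbed each
    iteration and improvements are accepted greedily.  The switch happens at
    ``switch_fraction`` of the evaluation budget or after
    ``stagnation_limit`` non-improving swarm iterations, whichever is first;
    the default keeps the global phase short because in high dimension at
    desk-scale budgets the greedy phase does most of the work.
    Deterministic under a fixed seed; never evaluates outside bounds.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1 evaluation")
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    d = len(bounds)
    rng = np.random.default_rng(seed)

    best_x: np.ndarray | None = None
    best_f = math.inf
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal best_x, best_f, n_eval
        f = fn(x)
        n_eval += 1
        if f < best_f:
            best_f, best_x = f, x.copy()
        return f

    start = (lo + hi) / 2.0 if x0 is None else np.clip(np.asarray(x0, float), lo, hi)
    evaluate(start)

    # Phase 1: multi-swarm PSO
    pso_budget = int(switch_fraction * budget)
    n_part = n_swarms * particles_per_swarm
    if pso_budget > n_part and budget > 2:
        pos = rng.uniform(lo, hi, size=(n_part, d))
        pos[0] = start
        vel = rng.uniform(-1, 1, size=(n_part, d)) * (hi - lo) * 0.1
        pbest = pos.copy()
        pbest_f = np.array([evaluate(p) for p in pos])
        swarm_of = np.repeat(np.arange(n_swarms), particles_per_swarm)
        stagnant = 0
        w, c1, c2 = 0.7, 1.5, 1.5
        while n_eval + n_part <= pso_budget and stagnant < stagnation_limit:
            improved = False
            gbest = np.empty((n_swarms, d))
            for s in range(n_swarms):
                members = swarm_of == s
                gbest[s] = pbest[members][np.argmin(pbest_f[members])]
            r1 = rng.random((n_part, d))
            r2 = rng.random((n_part, d))
            vel = (
                w * vel
                + c1 * r1 * (pbest - pos)
                + c2 * r2 * (gbest[swarm_of] - pos)
            )
            pos = np.clip(pos + vel, lo, hi)
            for i in range(n_part):
                f = evaluate(pos[i])
                if f < pbest_f[i]:
                    pbest_f[i], pbest[i] = f, pos[i].copy()
                    improved = True
            stagnant = 0 if improved else stagnant + 1

    # Phase 2: dynamically dimensioned search around the incumbent
    remaining = budget - n_eval
    incumbent = best_x.copy()
    incumbent_f = best_f
    sigma = 0.2 * (hi - lo)
    for k in range(1, max(remaining, 0) + 1):
        # probability of perturbing each dimension shrinks with progress
        p = max(1.0 - math.log(k) / math.log(max(remaining, 2)), 1.0 / d)
        mask = rng.random(d) < p
        if not mask.any():
            mask[rng.integers(d)] = True
        cand = incumbent.copy()
        cand[mask] += sigma[mask] * rng.standard_normal(int(mask.sum()))
        # reflect at the bounds
        over, under = cand > hi, cand < lo
        cand[over] = np.clip(2 * hi[over] - cand[over], lo[over], hi[over])
        cand[under] = np.clip(2 * lo[under] - cand[under], lo[under], hi[under])
        f = evaluate(cand)
        if f < incumbent_f:
            incumbent, incumbent_f = cand, f

    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("no feasible point found within the budget")
    return OptimizationResult(x=best_x, fun=best_f, n_eval=n_eval)


def _log_bounds_of(params: ParameterSet) -> np.ndarray:
    return np.log10(params.bounds)


def dops_warm_start(
    model: ModelDefinition,
    data: MeasurementTable,
    objectives: Sequence[TrainingObjective] | None = None,
    budget: int = 500,
    seed: int = 0,
    x0: ParameterSet | None = None,
    **sim_kwargs,
) -> ParameterSet:
    """Single-objective warm start: minimize the summed training residual.

    The search runs in log10 parameter space within the model's bounds; the
    default start point is the center of the (log) bounds.  Returns the
    best-found parameter set.
    """
    objectives = objectives or default_objectives()
    template = model.parameters
    log_bounds = _log_bounds_of(template)

    def fn(log_x: np.ndarray) -> float:
        p = template.with_values(10.0 ** log_x)
        return summed_objective(p, model, data, objectives, **sim_kwargs)

    start = None if x0 is None else np.log10(x0.values)
    result = dops_minimize(fn, log_bounds, budget=budget, seed=seed, x0=start)
    return template.with_values(10.0 ** result.x)


# ---------------------------------------------------------------------------
# Pareto ranking and the multiobjective annealing ensemble
# ---------------------------------------------------------------------------


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_rank(objective_vectors: Sequence[Sequence[float]]) -> np.ndarray:
    """Layered non-dominated sorting; rank 0 is the non-dominated front."""
    F = np.asarray(objective_vectors, dtype=float)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("need at least one objective vector")
    n = F.shape[0]
    ranks = np.full(n, -1, dtype=int)
    remaining = np.arange(n)
    layer = 0
    while remaining.size:
        front = []
        for i in remaining:
            if not any(
                _dominates(F[j], F[i]) for j in remaining if j != i
            ):
                front.append(i)
        if not front:  # identical vectors all dominate nothing: take them all
            front = list(remaining)
        ranks[front] = layer
        remaining = np.array([i for i in remaining if i not in set(front)])
        layer += 1
    return ranks


@dataclass
class ParameterEnsemble:
    """A ranked collection of parameter sets with their objective vectors."""

    parameters: list[ParameterSet]
    objectives: np.ndarray  # (n, k)
    ranks: np.ndarray       # (n,)

    def __len__(self) -> int:
        return len(self.parameters)

    def subset(self, max_rank: int) -> "ParameterEnsemble":
        keep = np.flatnonzero(self.ranks < max_rank)
        return ParameterEnsemble(
            [self.parameters[i] for i in keep],
            self.objectives[keep],
            self.ranks[keep],
        )

    def best(self) -> ParameterSet:
        """Member with the smallest summed objective on the rank-0 front."""
        front = np.flatnonzero(self.ranks == 0)
        i = front[np.argmin(self.objectives[front].sum(axis=1))]
        return self.parameters[i]

    def to_frame(self) -> pd.DataFrame:
        names = self.parameters[0].names
        rows = pd.DataFrame(
            np.stack([p.values for p in self.parameters]), columns=list(names)
        )
        for k in range(self.objectives.shape[1]):
            rows[f"objective_{k + 1}"] = self.objectives[:, k]
        rows["pareto_rank"] = self.ranks
        return rows

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, template: ParameterSet) -> "ParameterEnsemble":
        frame = pd.read_csv(path)
        obj_cols = [c for c in frame.columns if c.startswith("objective_")]
        params = [
            template.with_values(row[list(template.names)].to_numpy(float))
            for _, row in frame.iterrows()
        ]
        return cls(
            params,
            frame[obj_cols].to_numpy(float),
            frame["pareto_rank"].to_numpy(int),
        )


def pareto_anneal(
    fn: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    x0: np.ndarray,
    iterations: int = 500,
    seed: int = 0,
    t0: float | None = None,
    cooling: float = 0.9,
    cooling_period: int = 20,
    step_scale: float = 0.05,
) -> tuple[list[np.ndarray], np.ndarray, int]:
    """Multiobjective simulated-annealing archive builder (generic).

    A random walk within box bounds proposes candidates; a candidate is
    accepted outright if it is non-dominated with respect to the current
    archive, and otherwise with Metropolis probability ``exp(-delta/T)`` on
    the increase of the summed objective.  The temperature cools
    geometrically from the scale of the initial objective.  Returns
    ``(archive points, archive objective matrix, n_accepted)``;
    deterministic under a fixed seed.
    """
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(bounds)
    rng = np.random.default_rng(seed)

    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fx = np.asarray(fn(x), dtype=float)
    if not np.all(np.isfinite(fx)):
        raise ValueError("start point is infeasible")

    archive_x = [x.copy()]
    archive_f = [fx.copy()]
    temperature = t0 if t0 is not None else max(float(fx.sum()), 1e-3)
    step = step_scale * (hi - lo)
    n_accepted = 0

    for it in range(iterations):
        cand = np.clip(x + step * rng.standard_normal(d), lo, hi)
        fc = np.asarray(fn(cand), dtype=float)
        if not np.all(np.isfinite(fc)):
            continue
        dominated = any(_dominates(f, fc) for f in archive_f)
        if not dominated:
            accept = True
        else:
            delta = float(fc.sum() - fx.sum())
            accept = delta <= 0 or rng.random() < math.exp(
                -delta / max(temperature, 1e-12)
            )
        if accept:
            x, fx = cand, fc
            archive_x.append(cand.copy())
            archive_f.append(fc.copy())
            n_accepted += 1
        if (it + 1) % cooling_period == 0:
            temperature *= cooling
    return archive_x, np.stack(archive_f), n_accepted


def poets_ensemble(
    model: ModelDefinition,
    data: MeasurementTable,
    objectives: Sequence[TrainingObjective] | None = None,
    start: ParameterSet | None = None,
    iterations: int = 500,
    seed: int = 0,
    target_size: int = 100,
    **anneal_kwargs,
) -> ParameterEnsemble:
    """Pareto-ensemble generation by multiobjective simulated annealing.

    Runs :func:`pareto_anneal` in log10 parameter space on the training
    objective vector (O1, O2).  Accepted sets enter the archive, whose
    Pareto ranks are refreshed on return; the archive is truncated to
    ``target_size`` by (rank, summed objective).  If nothing beyond the
    start point is accepted, the archive contains only the start point (a
    warning is logged).  Deterministic under a fixed seed.
    """
    sim_kwargs = anneal_kwargs.pop("sim_kwargs", {})
    objectives = objectives or default_objectives()
    start = start or model.parameters
    template = model.parameters
    log_bounds = _log_bounds_of(template)

    def fn(log_x: np.ndarray) -> np.ndarray:
        p = template.with_values(10.0 ** log_x)
        return objective_vector(p, model, data, objectives, **sim_kwargs)

    archive_x, F, n_accepted = pareto_anneal(
        fn, log_bounds, np.log10(start.values), iterations=iterations,
        seed=seed, **anneal_kwargs,
    )
    if n_accepted == 0:
        log.warning("annealing accepted no candidates; archive is the start point")
    ranks = pareto_rank(F)
    order = np.lexsort((F.sum(axis=1), ranks))[:target_size]
    params = [template.with_values(10.0 ** archive_x[i]) for i in order]
    return ParameterEnsemble(params, F[order], pareto_rank(F[order]))


# ---------------------------------------------------------------------------
# AIC and the random-parameter control
# ---------------------------------------------------------------------------


def aic_score(
    n_parameters: int,
    n_measurements: int,
    residual: float,
    scale: float,
    floor: float = -1e6,
) -> float:
    """AIC = 2 Np + Nm ln(residual / scale), with a floor for zero residual."""
    if n_measurements <= 0:
        raise ValueError("need at least one measurement")
    if residual == 0.0:
        return floor
    return 2.0 * n_parameters + n_measurements * math.log(residual / scale)


def aic(
    params: ParameterSet,
    model: ModelDefinition,
    data: MeasurementTable,
    n_parameters: int | None = None,
    norm: str = "sum_sq",
    floor: float = -1e6,
    **sim_kwargs,
) -> float:
    """Akaike information criterion 2 Np + Nm ln(residual / ||M||).

    The residual is the squared difference between simulation and
    measurement in natural units, summed over every measured point of every
    condition; ``||M||`` normalizes by the data scale, by default the sum of
    squared measurements (``norm='max_sq'`` uses Nm * max(M)^2 instead).
    A zero residual returns the configured floor.
    """
    n_p = model.n_parameters if n_parameters is None else n_parameters
    residual = 0.0
    n_m = 0
    all_values = data.frame["value"].to_numpy(float)
    for dose in data.doses():
        doserows = data.frame[np.isclose(data.frame["dose_mg_ml"], dose)]
        horizon = float(doserows["time"].max())
        try:
            traj = simulate(
                model, params, condition=Condition(initiator_dose=float(dose)),
                t_span=(0.0, horizon), **sim_kwargs,
            )
        except IntegrationError as err:
            log.warning("aic: simulation failed at dose %s: %s", dose, err)
            return math.inf
        for species in doserows["species"].unique():
            times, measured = data.series(float(dose), species)
            simulated = traj.at(species, times)
            residual += float(np.sum((measured - simulated) ** 2))
            n_m += len(measured)
    if n_m == 0:
        raise ValueError("no measurements")
    if norm == "sum_sq":
        scale = float(np.sum(all_values**2))
    elif norm == "max_sq":
        scale = n_m * float(np.max(all_values) ** 2)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return aic_score(n_p, n_m, residual, scale, floor=floor)


def random_parameter_control(
    template: ParameterSet, n: int, seed: int = 0
) -> list[ParameterSet]:
    """Log-uniform parameter draws within bounds (same order of magnitude
    coverage as the fitted sets), for the AIC control comparison."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    log_b = np.log10(template.bounds)
    draws = rng.uniform(log_b[:, 0], log_b[:, 1], size=(n, len(template)))
    return [template.with_values(10.0**row) for row in draws]
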
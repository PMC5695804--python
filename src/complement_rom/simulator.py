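"""Stiff ODE integration of the complement model, ensembles, and AUCs.

Convertase feedback makes the network stiff at high initiator doses, so the
default solver is an implicit variable-step BDF method (rtol 1e-6,
atol 1e-9).  States are clamped at zero inside the right-hand side and the
stored solution is clipped at zero (irreversible mass action can undershoot
by solver tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .network import ModelDefinition, knockdown
from .reaction_core import ParameterSet, RhsEvaluator

__all__ = [
    "Condition",
    "Trajectory",
    "EnsembleSummary",
    "IntegrationError",
    "simulate",
    "simulate_ensemble",
    "auc",
    "DEFAULT_T_SPAN",
]

log = logging.getLogger(__name__)

#: Default simulation horizon in hours; chosen so that nominal C3a reaches
#: its plateau at the reference initiator dose (1 mg/ml).
DEFAULT_T_SPAN: tuple[float, float] = (0.0, 6.0)


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the failing time and state snapshot."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (at t={t:.6g}, state={np.array2string(state, precision=4)})")
        self.t = t
        self.state = state


@dataclass(frozen=True)
class Condition:
    """One experimental condition: initiator dose plus optional knockdowns."""

    initiator_dose: float = 0.0
    knockdowns: Mapping[str, float] = field(default_factory=dict)  # species -> percent
    label: str = ""

    def inputs(self, model: ModelDefinition) -> dict[str, float]:
        inputs = dict(model.external_inputs)
        inputs[model.initiator] = self.initiator_dose
        return inputs


@dataclass
class Trajectory:
    """Time-stamped state matrix from one simulation."""

    t: np.ndarray  # (T,)
    y: np.ndarray  # (T, M)
    species: tuple[str, ...]
    condition: Condition

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def series(self, species: str) -> np.ndarray:
        try:
            return self.y[:, self.species.index(species)]
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def at(self, species: str, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of one species at requested times."""
        return np.interp(times, self.t, self.series(species))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=list(self.species))
        frame.insert(0, "time", self.t)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: Condition | None = None) -> "Trajectory":
        frame = pd.read_csv(path)
        species = tuple(c for c in frame.columns if c != "time")
        return cls(
            t=frame["time"].to_numpy(),
            y=frame[list(species)].to_numpy(),
            species=species,
            condition=condition or Condition(),
        )


def simulate(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    ic: Mapping[str, float] | None = None,
    condition: Condition | None = None,
    t_span: tuple[float, float] = DEFAULT_T_SPAN,
    n_points: int = 200,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the model under one condition and return the trajectory.

    ``params`` defaults to the model's nominal parameter set; ``ic``
    overrides individual initial conditions (in nM) before any knockdowns
    declared on the condition are applied.
    """
    params = params or model.parameters
    condition = condition or Condition()
    if t_span[1] <= t_span[0]:
        raise ValueError("t_span must be positive")

    base = dict(model.initial_conditions)
    if ic:
        base.update(ic)
    for target, pct in condition.knockdowns.items():
        base = knockdown(base, [target], pct)
    x0 = model.initial_state(base)

    rhs = RhsEvaluator(model, params, condition.inputs(model))
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(
        rhs, t_span, x0, method=method, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else t_span[0]
        state = sol.y[:, -1] if sol.t.size else x0
        raise IntegrationError(f"integration failed: {sol.message}", t_fail, state)
    return Trajectory(
        t=sol.t, y=np.clip(sol.y.T, 0.0, None),
        species=model.species_ids, condition=condition,
    )


@dataclass
class EnsembleSummary:
    """Per-species ensemble mean with 99% bands (mean CI and value interval)."""

    t: np.ndarray
    species: tuple[str, ...]
    mean: np.ndarray            # (T, M)
    mean_ci_lower: np.ndarray   # 99% t-interval of the mean
    mean_ci_upper: np.ndarray
    value_lower: np.ndarray     # 0.5 / 99.5 percentiles of simulated values
    value_upper: np.ndarray
    n_members: int
    n_failed: int

    def series(self, species: str, which: str = "mean") -> np.ndarray:
        j = self.species.index(species)
        return getattr(self, which if which != "mean" else "mean")[:, j]


def simulate_ensemble(
    model: ModelDefinition,
    ensemble: Sequence[ParameterSet],
    ic: Mapping[str, float] | None = None,
    condition: Condition | None = None,
    t_span: tuple[float, float] = DEFAULT_T_SPAN,
    n_points: int = 200,
    **kwargs,
) -> EnsembleSummary:
    """Simulate every member; failures are logged, skipped, and counted."""
    members = list(ensemble)
    if not members:
        raise ValueError("ensemble must be non-empty")
    stack = []
    n_failed = 0
    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    for i, params in enumerate(members):
        try:
            traj = simulate(model, params, ic=ic, condition=condition,
                            t_span=t_span, t_eval=t_eval, **kwargs)
        except IntegrationError as err:
            n_failed += 1
            log.warning("ensemble member %d failed: %s", i, err)
            continue
        stack.append(traj.y)
    if not stack:
        raise IntegrationError("every ensemble member failed", t_span[0],
                               np.zeros(model.n_species))
    cube = np.stack(stack)  # (n_ok, T, M)
    n_ok = cube.shape[0]
    mean = cube.mean(axis=0)
    if n_ok > 1:
        sem = cube.std(axis=0, ddof=1) / np.sqrt(n_ok)
        half = stats.t.ppf(0.995, df=n_ok - 1) * sem
    else:
        half = np.zeros_like(mean)
    return EnsembleSummary(
        t=t_eval,
        species=model.species_ids,
        mean=mean,
        mean_ci_lower=mean - half,
        mean_ci_upper=mean + half,
        value_lower=np.percentile(cube, 0.5, axis=0),
        value_upper=np.percentile(cube, 99.5, axis=0),
        n_members=n_ok,
        n_failed=n_failed,
    )


def auc(
    traj: Trajectory,
    species: str,
    t0: float | None = None,
    tf: float | None = None,
) -> float:
    """Trapezoidal area under one species curve over [t0, tf]."""
    t0 = traj.t[0] if t0 is None else t0
    tf = traj.t[-1] if tf is None else tf
    if t0 < traj.t[0] - 1e-12 or tf > traj.t[-1] + 1e-12:
        raise ValueError(f"[{t0}, {tf}] outside trajectory span")
    y = traj.series(species)
    inside = (traj.t > t0) & (traj.t < tf)
    tt = np.concatenate(([t0], traj.t[inside], [tf]))
    yy = np.concatenate(
        ([np.interp(t0, traj.t, y)], y[inside], [np.interp(tf, traj.t, y)])
    )
    return float(np.trapezoid(yy, tt))
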
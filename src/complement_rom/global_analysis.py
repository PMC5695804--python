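"""Global perturbation analysis: Sobol sensitivity, pairwise displacement
clustering, and knockdown robustness coefficients.

* Variance-based sensitivity uses the Saltelli radial sampling scheme —
  ``N (2d + 2)`` parameter sets from base matrices A and B plus the cross
  matrices AB_i / BA_i — and the Jansen estimator of the total-order index,
  with a bootstrap confidence interval.  The analyzed output is by default
  the training residual of one objective.
* Pairwise analysis perturbs every parameter pair by a fixed fraction
  (default 10%), measures the euclidean displacement between the perturbed
  and nominal system state (full trajectory by default), averages the
  displacement over an ensemble, log10-transforms, and clusters parameters
  into high / medium / low response groups by Ward hierarchical clustering.
* Robustness coefficients are log10 ratios of a marker's AUC after versus
  before a knockdown of C3 and/or C5 initial conditions, evaluated with and
  without lectin initiator and averaged over an ensemble subset.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import qmc

from .estimation import MeasurementTable, TrainingObjective, objective
from .network import ModelDefinition
from .reaction_core import ParameterSet
from .simulator import (
    Condition,
    IntegrationError,
    Trajectory,
    auc,
    simulate,
    DEFAULT_T_SPAN,
)

__all__ = [
    "ZeroVarianceError",
    "SensitivityResult",
    "saltelli_sample",
    "sobol_total_indices",
    "sensitivity_analysis",
    "PairwiseResponseMatrix",
    "pairwise_displacement",
    "robustness_coefficient",
    "RobustnessTable",
    "robustness_study",
    "LOG_DISPLACEMENT_FLOOR",
]

log = logging.getLogger(__name__)

LOG_DISPLACEMENT_FLOOR = 1e-12


class ZeroVarianceError(ValueError):
    """All model evaluations identical: sensitivity indices undefined."""


# ---------------------------------------------------------------------------
# Saltelli sampling and the Jansen total-order estimator
# ---------------------------------------------------------------------------


def saltelli_sample(
    bounds: np.ndarray,
    N: int,
    d: int | None = None,
    seed: int = 0,
    scale: str = "log",
) -> np.ndarray:
    """N(2d+2) parameter vectors in the Saltelli radial layout.

    Rows are ordered: N rows of base matrix A, N rows of base matrix B,
    then d blocks AB_i (A with column i taken from B), then d blocks BA_i.
    Sampling uses a scrambled Sobol' sequence in 2d dimensions; parameter
    values are placed log-uniformly within bounds by default (kinetic
    constants span decades; ``scale='linear'`` is available).
    """
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    if d is None:
        d = len(bounds)
    if len(bounds) != d:
        raise ValueError("bounds length must equal d")
    if N < 2 or d < 1:
        raise ValueError("need N >= 2 and d >= 1")
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # N need not be a power of two (e.g. the N = 400 full-scale design);
        # scrambling keeps the estimator unbiased without exact balance
        warnings.simplefilter("ignore", UserWarning)
        base = sampler.random(N)
    A, B = base[:, :d], base[:, d:]
    blocks = [A, B]
    for i in range(d):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(d):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    unit = np.vstack(blocks)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if scale == "log":
        if np.any(lo <= 0):
            raise ValueError("log-scale sampling requires positive bounds")
        return 10.0 ** (np.log10(lo) + unit * (np.log10(hi) - np.log10(lo)))
    if scale == "linear":
        return lo + unit * (hi - lo)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass
class SensitivityResult:
    """Total-order Sobol indices with bootstrap confidence intervals."""

    names: tuple[str, ...]
    total_order: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_base: int
    d: int
    objective_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "total_order": self.total_order,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sobol_total_indices(
    y: np.ndarray,
    N: int,
    d: int,
    names: Sequence[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
    objective_label: str = "",
) -> SensitivityResult:
    """Total-order indices from evaluations in the Saltelli layout.

    Uses the Jansen estimator  S_Ti = mean((f_A - f_ABi)^2) / (2 V)  averaged
    with its mirror on (B, BA_i), where V is the variance over the A and B
    evaluations.  95% bootstrap confidence intervals resample the N base
    rows.
    """
    y = np.asarray(y, dtype=float)
    expected = N * (2 * d + 2)
    if y.size != expected:
        raise ValueError(f"expected {expected} evaluations, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("evaluations must be finite")
    yA, yB = y[:N], y[N:2 * N]
    yAB = y[2 * N:(2 + d) * N].reshape(d, N)
    yBA = y[(2 + d) * N:].reshape(d, N)

    def estimate(idx: np.ndarray) -> np.ndarray:
        base = np.concatenate([yA[idx], yB[idx]])
        V = base.var()
        if V == 0.0:
            raise ZeroVarianceError("model output has zero variance")
        st_a = 0.5 * np.mean((yA[idx] - yAB[:, idx]) ** 2, axis=1) / V
        st_b = 0.5 * np.mean((yB[idx] - yBA[:, idx]) ** 2, axis=1) / V
        return 0.5 * (st_a + st_b)

    full = np.arange(N)
    st = estimate(full)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, d))
    for b in range(n_boot):
        idx = rng.integers(0, N, size=N)
        try:
            boots[b] = estimate(idx)
        except ZeroVarianceError:
            boots[b] = st
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    names = tuple(names) if names is not None else tuple(
        f"p{i + 1}" for i in range(d)
    )
    return SensitivityResult(names, st, lo, hi, N, d, objective_label)


def sensitivity_analysis(
    model: ModelDefinition,
    data: MeasurementTable,
    obj: TrainingObjective,
    N: int = 64,
    seed: int = 0,
    bounds: np.ndarray | None = None,
    **sim_kwargs,
) -> SensitivityResult:
    """End-to-end Sobol analysis of the training residual for one objective.

    Infeasible evaluations (failed integrations) are imputed with the worst
    finite residual so the estimator stays defined.
    """
    template = model.parameters
    b = template.bounds if bounds is None else np.asarray(bounds, float)
    d = len(template)
    X = saltelli_sample(b, N, d, seed=seed)
    y = np.empty(len(X))
    for i, row in enumerate(X):
        y[i] = objective(template.with_values(row), model, data, obj,
                         **sim_kwargs)
    bad = ~np.isfinite(y)
    if bad.any():
        log.warning("sensitivity: %d/%d evaluations failed; imputing worst",
                    int(bad.sum()), len(y))
        y[bad] = y[~bad].max() if (~bad).any() else 0.0
    return sobol_total_indices(
        y, N, d, names=template.names, seed=seed,
        objective_label=obj.label,
    )


# ---------------------------------------------------------------------------
# Pairwise perturbation displacement and clustering
# ---------------------------------------------------------------------------


@dataclass
class PairwiseResponseMatrix:
    """d x d log10 mean displacements with 3-cluster parameter labels."""

    names: tuple[str, ...]
    log10_displacement: np.ndarray  # (d, d)
    labels: dict[str, str]          # parameter -> high | medium | low
    cluster_id: np.ndarray          # (d,)
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.log10_displacement, index=list(self.names),
            columns=list(self.names),
        )
        return frame


def _state_vector(traj: Trajectory, distance: str) -> np.ndarray:
    if distance == "trajectory":
        return traj.y.ravel()
    if distance == "final":
        return traj.y[-1]
    raise ValueError(f"unknown distance {distance!r}")


def pairwise_displacement(
    model: ModelDefinition,
    ensemble: Sequence[ParameterSet],
    condition: Condition | None = None,
    delta: float = 0.10,
    parameters: Sequence[str] | None = None,
    distance: str = "trajectory",
    t_span: tuple[float, float] = DEFAULT_T_SPAN,
    n_points: int = 100,
    n_clusters: int = 3,
    **sim_kwargs,
) -> PairwiseResponseMatrix:
    """Euclidean displacement of the system state under pairwise +delta
    parameter perturbations, ensemble-averaged and clustered.

    For p != q both parameters are increased by ``delta``; the diagonal cell
    applies the compounded (1+delta)^2 factor to the single parameter.  The
    displacement vector is the full trajectory on a common output grid by
    default (``distance='final'`` uses the terminal state).  Parameters are
    grouped into exactly ``n_clusters`` response clusters by Ward linkage on
    the matrix rows; labels high/medium/low follow cluster-mean order.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    members = list(ensemble)
    if not members:
        raise ValueError("ensemble must be non-empty")
    condition = condition or Condition(initiator_dose=1.0)
    names = tuple(parameters) if parameters else tuple(model.parameters.names)
    d = len(names)
    t_eval = np.linspace(t_span[0], t_span[1], n_points)

    sums = np.zeros((d, d))
    counts = np.zeros((d, d), dtype=int)
    n_failed = 0
    for params in members:
        nominal = simulate(model, params, condition=condition, t_span=t_span,
                           t_eval=t_eval, **sim_kwargs)
        ref = _state_vector(nominal, distance)
        for a, pa in enumerate(names):
            for b, pb in enumerate(names):
                if b < a:
                    continue  # symmetric by construction
                factors = {pa: 1.0 + delta, pb: 1.0 + delta}
                if a == b:
                    factors = {pa: (1.0 + delta) ** 2}
                perturbed = params.with_values(
                    {k: params[k] * f for k, f in factors.items()}
                )
                try:
                    traj = simulate(model, perturbed, condition=condition,
                                    t_span=t_span, t_eval=t_eval, **sim_kwargs)
                except IntegrationError as err:
                    n_failed += 1
                    log.warning("pairwise (%s, %s): %s", pa, pb, err)
                    continue
                dist = float(
                    np.linalg.norm(_state_vector(traj, distance) - ref)
                )
                sums[a, b] += dist
                counts[a, b] += 1
                if a != b:
                    sums[b, a] += dist
                    counts[b, a] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    logD = np.log10(np.maximum(mean, LOG_DISPLACEMENT_FLOOR))

    if d >= max(n_clusters, 2):
        Z = linkage(logD, method="ward")
        cluster_id = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        cluster_id = np.arange(1, d + 1)
    order = np.argsort(
        [-logD[cluster_id == c].mean() for c in np.unique(cluster_id)]
    )
    rank_of = {c: r for r, c in enumerate(np.unique(cluster_id)[order])}
    level_names = ["high", "medium", "low"]
    labels = {
        name: level_names[min(rank_of[cluster_id[i]], len(level_names) - 1)]
        for i, name in enumerate(names)
    }
    return PairwiseResponseMatrix(names, logD, labels, cluster_id, n_failed)


# ---------------------------------------------------------------------------
# Robustness coefficients
# ---------------------------------------------------------------------------


def robustness_coefficient(
    nominal: Trajectory,
    perturbed: Trajectory,
    marker: str,
    t0: float | None = None,
    tf: float | None = None,
) -> float:
    """log10 of the marker's AUC ratio, perturbed over nominal.

    Zero means the perturbation left the marker unchanged; positive values
    indicate increased, negative decreased, marker abundance.
    """
    denom = auc(nominal, marker, t0, tf)
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"nominal AUC of {marker!r} is zero; robustness undefined"
        )
    num = auc(perturbed, marker, t0, tf)
    if num <= 0.0:
        return -math.inf
    return math.log10(num / denom)


@dataclass
class RobustnessTable:
    """Ensemble-mean robustness coefficients per knockdown cell."""

    frame: pd.DataFrame  # marker, perturbation, level, dose, alpha_mean, ...

    def cell(
        self, marker: str, perturbation: str, level: float, dose: float
    ) -> float:
        sel = self.frame[
            (self.frame["marker"] == marker)
            & (self.frame["perturbation"] == perturbation)
            & np.isclose(self.frame["level_pct"], level)
            & np.isclose(self.frame["dose_mg_ml"], dose)
        ]
        if sel.empty:
            raise KeyError((marker, perturbation, level, dose))
        return float(sel["alpha_mean"].iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def robustness_study(
    model: ModelDefinition,
    ensemble: Sequence[ParameterSet],
    levels: Sequence[float] = (50.0, 90.0, 99.0),
    perturbations: Sequence[tuple[str, ...]] = (("C3",), ("C5",), ("C3", "C5")),
    doses: Sequence[float] = (0.0, 1.0),
    markers: Sequence[str] = ("C3a", "C5a"),
    t_span: tuple[float, float] = DEFAULT_T_SPAN,
    **sim_kwargs,
) -> RobustnessTable:
    """Full factorial knockdown study, ensemble-averaged.

    For every ensemble member, each dose gets one nominal simulation and one
    per (perturbation, level); coefficients are averaged over members.
    Failed cells propagate as NaN with a flag in ``n_failed``.
    """
    members = list(ensemble)
    if not members:
        raise ValueError("ensemble subset must be non-empty")
    rows = []
    cells: dict[tuple, list[float]] = {}
    failed: dict[tuple, int] = {}
    for params in members:
        for dose in doses:
            nominal = simulate(
                model, params, condition=Condition(initiator_dose=dose),
                t_span=t_span, **sim_kwargs,
            )
            for targets, level in product(perturbations, levels):
                key_base = ("+".join(targets), level, dose)
                cond = Condition(
                    initiator_dose=dose,
                    knockdowns={t: level for t in targets},
                )
                try:
                    perturbed = simulate(model, params, condition=cond,
                                         t_span=t_span, **sim_kwargs)
                except IntegrationError as err:
                    log.warning("robustness %s: %s", key_base, err)
                    for marker in markers:
                        failed[(marker,) + key_base] = (
                            failed.get((marker,) + key_base, 0) + 1
                        )
                    continue
                for marker in markers:
                    alpha = robustness_coefficient(nominal, perturbed, marker)
                    cells.setdefault((marker,) + key_base, []).append(alpha)
    for (marker, pert, level, dose), values in sorted(cells.items()):
        arr = np.asarray(values)
        rows.append(
            {
                "marker": marker,
                "perturbation": pert,
                "level_pct": level,
                "dose_mg_ml": dose,
                "alpha_mean": float(arr.mean()) if arr.size else math.nan,
                "alpha_std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n_members": int(arr.size),
                "n_failed": failed.get((marker, pert, level, dose), 0),
            }
        )
    return RobustnessTable(pd.DataFrame(rows))
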
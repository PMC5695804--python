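"""Synthetic C3a/C5a time-series generation for the full pipeline.

The generator emulates the structure of in-vitro zymosan dose-response
experiments: C3a and C5a sampled at a handful of time points per condition
over the initiator doses {0, 0.001, 0.01, 0.1, 1} mg/ml, with C3a running
orders of magnitude above C5a, and multiplicative log-normal measurement
noise (immunoassay-like constant CV).  Conditions at 0 and 1 mg/ml are
tagged for training; the intermediate doses are tagged for validation, so a
train/validate split with two training and three validation conditions per
species falls out of the default protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import MeasurementTable
from .network import ModelDefinition
from .reaction_core import ParameterSet
from .simulator import Condition, simulate, DEFAULT_T_SPAN

__all__ = ["SyntheticProtocol", "generate", "train_validate_split"]


@dataclass(frozen=True)
class SyntheticProtocol:
    """Study design for one synthetic data set.

    ``sigma`` is the log-normal noise scale (0.05 corresponds to a ~5%
    coefficient of variation); time points are spread evenly over the
    simulation horizon, excluding t = 0.
    """

    doses: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1, 1.0)
    n_times: int = 8
    sigma: float = 0.05
    seed: int = 0
    species: tuple[str, ...] = ("C3a", "C5a")
    t_span: tuple[float, float] = DEFAULT_T_SPAN
    train_doses: tuple[float, ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.n_times < 2:
            raise ValueError("need >= 2 time points per condition")

    def times(self) -> np.ndarray:
        return np.linspace(self.t_span[0], self.t_span[1],
                           self.n_times + 1)[1:]


def generate(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    protocol: SyntheticProtocol | None = None,
    **sim_kwargs,
) -> MeasurementTable:
    """Simulate each dose, sample, apply noise value * exp(sigma * xi).

    Deterministic under the protocol seed.  Each condition is tagged
    ``train`` or ``validate`` according to ``protocol.train_doses``.
    """
    protocol = protocol or SyntheticProtocol()
    params = params or model.parameters
    rng = np.random.default_rng(protocol.seed)
    times = protocol.times()
    records = []
    for dose in protocol.doses:
        traj = simulate(
            model, params, condition=Condition(initiator_dose=dose),
            t_span=protocol.t_span, **sim_kwargs,
        )
        split = "train" if dose in protocol.train_doses else "validate"
        for species in protocol.species:
            clean = traj.at(species, times)
            noise = np.exp(protocol.sigma * rng.standard_normal(len(times)))
            for t, v in zip(times, clean * noise):
                records.append(
                    {
                        "condition": f"zymosan_{dose:g}",
                        "dose_mg_ml": dose,
                        "species": species,
                        "time": float(t),
                        "value": float(v),
                        "units": "nM",
                        "split": split,
                    }
                )
    return MeasurementTable(pd.DataFrame.from_records(records))


def train_validate_split(
    table: MeasurementTable,
) -> tuple[MeasurementTable, MeasurementTable]:
    """Disjoint partition of a tagged table into (train, validate)."""
    frame = table.frame
    if "split" not in frame.columns or frame["split"].isna().any():
        raise ValueError("measurement table has untagged rows")
    train = frame[frame["split"] == "train"].reset_index(drop=True)
    validate = frame[frame["split"] == "validate"].reset_index(drop=True)
    if validate.empty:
        raise ValueError("no rows tagged 'validate'")
    if train.empty:
        raise ValueError("no rows tagged 'train'")
    return MeasurementTable(train), MeasurementTable(validate)
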
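"""Rate laws and rule-based control algebra for reduced-order kinetic models.

The modeling idiom combines ordinary differential equations with logical
control rules.  Each species balance is

    dx_i/dt = tau_i * sum_j sigma_ij * r_j * v_j

where ``sigma_ij`` is the stoichiometric coefficient of species ``i`` in
reaction ``j``, ``r_j`` is a kinetic term (saturation, mass action, or first
order), and ``v_j`` in [0, 1] is a control term built from Hill-type transfer
functions combined by a ``min`` or ``max`` integration rule.  ``tau_i`` is a
dimensionless time-scale factor that absorbs unmodeled effects; in the
complement model it scales with the initiator dose for C5a/C5b and is 1 for
every other species.

This layer is network-agnostic: it defines the domain types (:class:`Species`,
:class:`Reaction`, :class:`ControlRule`, :class:`ParameterSet`), the three
rate laws, control-rule evaluation, and right-hand-side assembly.  The
concrete complement network lives in :mod:`complement_rom.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "InvalidRuleError",
    "ConfigurationError",
    "InputError",
    "Species",
    "Reaction",
    "ControlFactor",
    "ControlRule",
    "ParameterSet",
    "INITIATOR_REFERENCE",
    "hill_transfer",
    "integrate_control",
    "saturation_rate",
    "mass_action_rate",
    "evaluate_rhs",
    "RhsEvaluator",
]

#: Reference initiator level z* (mg/ml) for the time-scale rule tau = z/z*.
INITIATOR_REFERENCE = 1.0

#: Prefix marking a reference to an external input (e.g. "@zymosan") rather
#: than a state variable in reaction enzyme / control actor fields.
INPUT_PREFIX = "@"


class ModelError(Exception):
    """Base class for model-construction and evaluation errors."""


class InvalidRuleError(ModelError):
    """A transfer function or control rule has invalid constants."""


class ConfigurationError(ModelError):
    """A reaction, rule, or reference is structurally inconsistent."""


class InputError(ModelError):
    """A required external input (e.g. initiator dose) is missing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """One state variable of the network.

    Parameters
    ----------
    id : str
        Short symbolic name, unique within a model (e.g. ``"C3a"``).
    index : int
        Position in the state vector; indices form a contiguous 0-based range.
    time_scale_rule : str
        ``"constant"`` (tau = 1) or ``"initiator"`` (tau = z/z*).
    """

    id: str
    index: int
    time_scale_rule: str = "constant"

    def __post_init__(self) -> None:
        if self.time_scale_rule not in ("constant", "initiator"):
            raise ConfigurationError(
                f"species {self.id!r}: unknown time_scale_rule "
                f"{self.time_scale_rule!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """One rate process.

    ``rate_law`` is one of ``saturation`` (enzyme-catalyzed Hill-saturation
    kinetics), ``mass_action`` (irreversible product-of-reactants), or
    ``first_order`` (single-reactant linear rate, a mass-action special case
    kept explicit for readability of model files).

    ``parameter_refs`` maps rate-law roles to parameter names:
    ``k_max`` always; ``K`` and ``eta`` for saturation reactions.
    ``enzyme`` names a species, or an external input with an ``"@"`` prefix.
    """

    id: str
    rate_law: str
    stoichiometry: Mapping[str, float]
    parameter_refs: Mapping[str, str]
    enzyme: str | None = None
    substrate: str | None = None

    def __post_init__(self) -> None:
        if self.rate_law not in ("saturation", "mass_action", "first_order"):
            raise ConfigurationError(
                f"reaction {self.id!r}: unknown rate law {self.rate_law!r}"
            )
        reactants = self.reactants()
        if self.rate_law == "saturation":
            if self.substrate is None or self.enzyme is None:
                raise ConfigurationError(
                    f"saturation reaction {self.id!r} must name exactly one "
                    "substrate and one enzyme/input"
                )
            for role in ("k_max", "K", "eta"):
                if role not in self.parameter_refs:
                    raise ConfigurationError(
                        f"saturation reaction {self.id!r} missing parameter "
                        f"role {role!r}"
                    )
        else:
            if not reactants:
                raise ConfigurationError(
                    f"reaction {self.id!r} has no reactant (sigma < 0)"
                )
            if "k_max" not in self.parameter_refs:
                raise ConfigurationError(
                    f"reaction {self.id!r} missing parameter role 'k_max'"
                )
        if self.rate_law == "first_order" and len(reactants) != 1:
            raise ConfigurationError(
                f"first-order reaction {self.id!r} must have exactly one "
                "reactant"
            )

    def reactants(self) -> dict[str, float]:
        """Species consumed by this reaction (sigma < 0)."""
        return {s: c for s, c in self.stoichiometry.items() if c < 0}


@dataclass(frozen=True)
class ControlFactor:
    """One regulatory influence on a rate: a Hill transfer function.

    ``gain`` may be a parameter name (str) or a literal constant; ``order``
    likewise.  ``actor`` is a species id or an ``"@"``-prefixed input.
    """

    actor: str
    direction: str  # "activating" | "inhibiting"
    gain: str | float
    order: str | float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("activating", "inhibiting"):
            raise ConfigurationError(
                f"control factor on {self.actor!r}: direction must be "
                "'activating' or 'inhibiting'"
            )


@dataclass(frozen=True)
class ControlRule:
    """Integration of one or more transfer functions into v_j in [0, 1]."""

    target_reaction: str
    integration: str  # "min" | "max"
    factors: tuple[ControlFactor, ...]

    def __post_init__(self) -> None:
        if self.integration not in ("min", "max"):
            raise ConfigurationError(
                f"control rule on {self.target_reaction!r}: integration must "
                "be 'min' or 'max'"
            )
        object.__setattr__(self, "factors", tuple(self.factors))


@dataclass
class ParameterSet:
    """Named, bounded, strictly positive kinetic constants.

    ``names`` fixes the parameter order used throughout the package
    (optimizers, sensitivity sampling, ensemble files all use this order).
    """

    names: tuple[str, ...]
    values: np.ndarray
    bounds: np.ndarray  # (K, 2) lower/upper

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(-1, 2)
        if len(self.names) != self.values.size or len(self.names) != len(
            self.bounds
        ):
            raise ConfigurationError("parameter names/values/bounds mismatch")
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("duplicate parameter names")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def with_values(self, values: np.ndarray | Mapping[str, float]) -> "ParameterSet":
        """Copy with new values (array in declaration order, or a mapping)."""
        if isinstance(values, Mapping):
            new = self.values.copy()
            for name, v in values.items():
                new[self._index[name]] = v
        else:
            new = np.asarray(values, dtype=float)
        return ParameterSet(self.names, new, self.bounds)

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty means valid)."""
        problems = []
        for n, v, (lo, hi) in zip(self.names, self.values, self.bounds):
            if v <= 0:
                problems.append(f"parameter {n!r} is not positive ({v})")
            if not (lo <= v <= hi):
                problems.append(
                    f"parameter {n!r} = {v} outside bounds [{lo}, {hi}]"
                )
        return problems


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def hill_transfer(x: float, K: float, n: float, direction: str = "activating") -> float:
    """Hill-type regulatory transfer function, bounded in [0, 1].

    Activating: x^n / (K^n + x^n).  Inhibiting: 1 - x^n / (K^n + x^n).
    ``x`` is an actor abundance, ``K`` the half-effect gain, ``n`` the order.
    """
    if K <= 0 or n <= 0:
        raise InvalidRuleError(f"hill_transfer requires K > 0 and n > 0, got K={K}, n={n}")
    if x < 0:
        raise InvalidRuleError(f"hill_transfer requires x >= 0, got {x}")
    if x == 0.0:
        h = 0.0
    elif x <= K:
        u = (x / K) ** n  # ratio <= 1: no overflow
        h = u / (1.0 + u)
    else:
        u = (K / x) ** n
        h = 1.0 / (1.0 + u)
    return h if direction == "activating" else 1.0 - h


def integrate_control(
    rule: ControlRule | None,
    levels: Mapping[str, float],
    params: Mapping[str, float] | ParameterSet | None = None,
) -> float:
    """Evaluate a control rule into v in [0, 1].

    ``levels`` maps species ids and ``"@"``-prefixed input names to
    abundances.  A reaction with no rule returns 1 (no modifying factors).
    """
    if rule is None or not rule.factors:
        return 1.0
    outputs = []
    for f in rule.factors:
        if f.actor not in levels:
            raise ConfigurationError(f"control actor {f.actor!r} not resolvable")
        gain = _resolve(f.gain, params)
        order = _resolve(f.order, params)
        outputs.append(hill_transfer(levels[f.actor], gain, order, f.direction))
    return min(outputs) if rule.integration == "min" else max(outputs)


def _resolve(ref: str | float, params: Mapping[str, float] | ParameterSet | None) -> float:
    if isinstance(ref, str):
        if params is None or ref not in params:
            raise ConfigurationError(f"parameter reference {ref!r} not resolvable")
        return params[ref]
    return float(ref)


def saturation_rate(
    k_max: float, enzyme_level: float, x_s: float, K: float, eta: float
) -> float:
    """Enzyme-catalyzed saturation rate k_max * eps * x^eta / (K^eta + x^eta)."""
    if K <= 0:
        raise InvalidRuleError(f"saturation constant must be positive, got {K}")
    if min(k_max, enzyme_level, x_s, eta) < 0:
        raise InvalidRuleError("saturation_rate arguments must be non-negative")
    if x_s == 0.0 or enzyme_level == 0.0:
        return 0.0
    if x_s <= K:
        u = (x_s / K) ** eta
        sat = u / (1.0 + u)
    else:
        sat = 1.0 / (1.0 + (K / x_s) ** eta)
    return k_max * enzyme_level * sat


def mass_action_rate(
    k_max: float,
    reactant_levels: Sequence[float],
    stoichiometry: Sequence[float],
) -> float:
    """Irreversible mass-action rate k_max * prod_s x_s^(-sigma_s).

    ``stoichiometry`` holds the (negative) reactant coefficients; there is no
    reverse term because all binding interactions are treated as irreversible.
    """
    levels = np.asarray(reactant_levels, dtype=float)
    sigma = np.asarray(stoichiometry, dtype=float)
    if levels.size == 0:
        raise ConfigurationError("mass_action_rate requires at least one reactant")
    if np.any(sigma >= 0):
        raise ConfigurationError("reactant stoichiometric coefficients must be negative")
    if np.any(levels < 0):
        raise InvalidRuleError("reactant levels must be non-negative")
    return float(k_max * np.prod(levels ** (-sigma)))


# ---------------------------------------------------------------------------
# Right-hand-side assembly
# ---------------------------------------------------------------------------


class RhsEvaluator:
    """Precompiled right-hand side dx/dt = tau * S (r o v) for one model.

    Compiles species indices, the stoichiometric matrix, per-reaction rate
    closures, and control rules once, so repeated evaluation inside an ODE
    solver avoids dictionary lookups.  States are clamped at zero before
    rate evaluation (irreversible kinetics can numerically undershoot).
    """

    def __init__(self, model, params: ParameterSet, inputs: Mapping[str, float]):
        species = sorted(model.species, key=lambda s: s.index)
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate species ids")
        if [s.index for s in species] != list(range(len(species))):
            raise ConfigurationError("species indices must be contiguous from 0")
        self.species_ids = ids
        self.index = {s.id: s.index for s in species}
        self.n = len(species)
        self.params = params
        self.inputs = dict(inputs)

        # time-scale factors
        self.tau = np.ones(self.n)
        scaled = [s for s in species if s.time_scale_rule == "initiator"]
        if scaled:
            initiator = getattr(model, "initiator", None)
            if initiator is None or initiator not in self.inputs:
                raise InputError(
                    "initiator-scaled species present but initiator dose "
                    f"{initiator!r} not in inputs"
                )
            z = float(self.inputs[initiator])
            # tau = z/z* captures initiator-driven unmodeled effects; with no
            # initiator there is nothing to scale by, so tau stays 1.
            tau = z / INITIATOR_REFERENCE if z > 0 else 1.0
            for s in scaled:
                self.tau[s.index] = tau

        # stoichiometric matrix and per-reaction evaluation plans
        reactions = list(model.reactions)
        self.reaction_ids = [r.id for r in reactions]
        self.S = np.zeros((self.n, len(reactions)))
        self._plans = []
        controls = dict(getattr(model, "controls", {}) or {})
        for j, rxn in enumerate(reactions):
            for sid, coeff in rxn.stoichiometry.items():
                if sid not in self.index:
                    raise ConfigurationError(
                        f"reaction {rxn.id!r} names unknown species {sid!r}"
                    )
                self.S[self.index[sid], j] = coeff
            self._plans.append(self._compile_reaction(rxn, controls.get(rxn.id)))

    def _level_getter(self, ref: str):
        """Return f(y) -> abundance for a species id or '@' input reference."""
        if ref.startswith(INPUT_PREFIX):
            name = ref[len(INPUT_PREFIX):]
            if name not in self.inputs:
                raise InputError(f"external input {name!r} not provided")
            value = float(self.inputs[name])
            return lambda y: value
        if ref not in self.index:
            raise ConfigurationError(f"unknown species reference {ref!r}")
        idx = self.index[ref]
        return lambda y: y[idx]

    def _compile_reaction(self, rxn: Reaction, rule: ControlRule | None):
        p = self.params
        for ref in rxn.parameter_refs.values():
            if ref not in p:
                raise ConfigurationError(
                    f"reaction {rxn.id!r} references undeclared parameter {ref!r}"
                )
        if rxn.rate_law == "saturation":
            k = p.index(rxn.parameter_refs["k_max"])
            K = p.index(rxn.parameter_refs["K"])
            eta = p.index(rxn.parameter_refs["eta"])
            enzyme = self._level_getter(rxn.enzyme)
            sub = self._level_getter(rxn.substrate)

            def kinetic(y, v, k=k, K=K, eta=eta, enzyme=enzyme, sub=sub):
                return saturation_rate(v[k], enzyme(y), sub(y), v[K], v[eta])

        elif rxn.rate_law == "mass_action":
            k = p.index(rxn.parameter_refs["k_max"])
            reactants = rxn.reactants()
            idx = np.array([self.index[s] for s in reactants])
            powers = -np.array([reactants[s] for s in reactants], dtype=float)

            def kinetic(y, v, k=k, idx=idx, powers=powers):
                return v[k] * float(np.prod(y[idx] ** powers))

        else:  # first_order
            k = p.index(rxn.parameter_refs["k_max"])
            (sid, coeff), = rxn.reactants().items()
            idx = self.index[sid]
            power = -coeff

            def kinetic(y, v, k=k, idx=idx, power=power):
                return v[k] * y[idx] ** power

        control = self._compile_control(rule)
        return kinetic, control

    def _compile_control(self, rule: ControlRule | None):
        if rule is None or not rule.factors:
            return None
        factors = []
        for f in rule.factors:
            getter = self._level_getter(f.actor)
            gain = (
                self.params.index(f.gain) if isinstance(f.gain, str) else None
            )
            gain_value = None if isinstance(f.gain, str) else float(f.gain)
            order = (
                self.params.index(f.order) if isinstance(f.order, str) else None
            )
            order_value = None if isinstance(f.order, str) else float(f.order)
            factors.append((getter, f.direction, gain, gain_value, order, order_value))
        agg = min if rule.integration == "min" else max

        def control(y, v):
            outs = []
            for getter, direction, gi, gv, oi, ov in factors:
                K = v[gi] if gi is not None else gv
                n = v[oi] if oi is not None else ov
                outs.append(hill_transfer(getter(y), K, n, direction))
            return agg(outs)

        return control

    def rates(self, y: np.ndarray, values: np.ndarray | None = None) -> np.ndarray:
        """Controlled reaction rates r_j * v_j at clamped state y."""
        v = self.params.values if values is None else values
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        out = np.empty(len(self._plans))
        for j, (kinetic, control) in enumerate(self._plans):
            r = kinetic(y, v)
            if control is not None:
                r *= control(y, v)
            out[j] = r
        return out

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.tau * (self.S @ self.rates(y))


def evaluate_rhs(
    model,
    state: np.ndarray,
    params: ParameterSet,
    inputs: Mapping[str, float],
) -> np.ndarray:
    """State-derivative vector dx/dt at one state (convenience wrapper).

    Equivalent to ``RhsEvaluator(model, params, inputs)(0, state)``; build the
    evaluator directly for repeated calls.
    """
    return RhsEvaluator(model, params, inputs)(0.0, np.asarray(state, dtype=float))
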
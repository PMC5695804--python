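"""The reduced-order lectin + alternative complement network.

The shipped default model has 18 state variables and 28 free kinetic
parameters.  It covers:

* lectin-pathway initiation: zymosan-gated cleavage of C4 and C2 into their
  a/b fragments (the trigger is an activating Hill gate on the initiator
  dose, so the gate closes when no zymosan is present);
* classical-pathway (CP) C3 convertase assembly from one C4 fragment plus
  one C2 fragment (irreversible mass action), and its C3-cleaving activity
  under C4BP inhibitory control;
* alternative-pathway (AP) initiation as a lumped first-order tickover of C3
  into C3a + C3b (factor B and factor D treated as in excess), AP C3
  convertase formation from C3b, and its activity under factor H control;
* C5 convertase assembly (CP or AP C3 convertase + one more C3b) and C5
  cleavage into C5a + C5b by either convertase, with the C5a/C5b balances
  carrying the initiator-scaled time factor;
* first-order clearance of the C3a and C5a anaphylatoxins.

MAC assembly (C6-C9), classical C1 initiation, and the C3w/C3wBb
intermediate are deliberately outside the model boundary.

Concentrations are in nM internally; time is in hours.  Model files may
declare serum levels in mg/ml or ug/ml together with molecular weights, and
the loader converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .reaction_core import (
    ConfigurationError,
    ControlFactor,
    ControlRule,
    ParameterSet,
    Reaction,
    Species,
)

__all__ = [
    "ModelDefinition",
    "build_default_model",
    "load_model",
    "save_model",
    "knockdown",
    "DEFAULT_SPECIES",
    "SERUM_MG_PER_ML",
    "MOLECULAR_WEIGHTS",
]

#: The 18 state variables, in state-vector order.
DEFAULT_SPECIES: tuple[str, ...] = (
    "C4", "C4a", "C4b",
    "C2", "C2a", "C2b",
    "C3", "C3a", "C3b",
    "C5", "C5a", "C5b",
    "CP_C3_convertase", "AP_C3_convertase",
    "CP_C5_convertase", "AP_C5_convertase",
    "factor_H", "C4BP",
)

#: Physiological serum concentrations (mg/ml) of the intact precursors and
#: fluid-phase regulators; fragments and complexes start at zero.
SERUM_MG_PER_ML: dict[str, float] = {
    "C4": 0.40,
    "C2": 0.025,
    "C3": 1.20,
    "C5": 0.075,
    "factor_H": 0.50,
    "C4BP": 0.25,
}

#: Molecular weights (g/mol) used to convert mass-based serum levels to nM.
MOLECULAR_WEIGHTS: dict[str, float] = {
    "C4": 205_000.0, "C4a": 8_700.0, "C4b": 196_000.0,
    "C2": 102_000.0, "C2a": 70_000.0, "C2b": 30_000.0,
    "C3": 187_000.0, "C3a": 9_000.0, "C3b": 177_000.0,
    "C5": 190_000.0, "C5a": 11_000.0, "C5b": 179_000.0,
    "factor_H": 155_000.0, "C4BP": 570_000.0,
}

#: Structural Hill orders of the three control transfer functions.  These are
#: fixed model structure, not free parameters: each control rule contributes
#: a single free gain constant to the 28-parameter table.
LECTIN_GATE_ORDER = 2.0
C4BP_CONTROL_ORDER = 1.0
FACTOR_H_CONTROL_ORDER = 1.0


@dataclass
class ModelDefinition:
    """A complete network: species, reactions, controls, ICs, parameters."""

    name: str
    species: list[Species]
    reactions: list[Reaction]
    controls: dict[str, ControlRule]
    initial_conditions: dict[str, float]
    parameters: ParameterSet
    initiator: str = "zymosan"
    external_inputs: dict[str, float] = field(default_factory=dict)
    molecular_weights: dict[str, float] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in sorted(self.species, key=lambda s: s.index))

    def species_index(self) -> dict[str, int]:
        return {s.id: s.index for s in self.species}

    def stoichiometric_matrix(self) -> np.ndarray:
        """M x R matrix of sigma_ij in species-index / reaction order."""
        idx = self.species_index()
        S = np.zeros((self.n_species, len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                S[idx[sid], j] = coeff
        return S

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """State vector of initial conditions; unlisted species default to 0."""
        ic = dict(self.initial_conditions)
        if overrides:
            ic.update(overrides)
        x0 = np.zeros(self.n_species)
        idx = self.species_index()
        for sid, value in ic.items():
            if sid not in idx:
                raise ConfigurationError(f"unknown species in initial conditions: {sid!r}")
            x0[idx[sid]] = value
        return x0

    def validate(self) -> list[str]:
        """Return every violated structural invariant (empty means valid)."""
        problems: list[str] = []
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            problems.append("duplicate species ids")
        indices = sorted(s.index for s in self.species)
        if indices != list(range(len(self.species))):
            problems.append("species indices are not a contiguous 0-based range")
        known = set(ids)
        declared = set(self.parameters.names)
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in known:
                    problems.append(
                        f"reaction {rxn.id!r} names undeclared species {sid!r}"
                    )
            for role, ref in rxn.parameter_refs.items():
                if ref not in declared:
                    problems.append(
                        f"reaction {rxn.id!r} references undeclared parameter {ref!r}"
                    )
            if rxn.enzyme and not rxn.enzyme.startswith("@") and rxn.enzyme not in known:
                problems.append(f"reaction {rxn.id!r} enzyme {rxn.enzyme!r} unknown")
        rxn_ids = {r.id for r in self.reactions}
        for target, rule in self.controls.items():
            if target not in rxn_ids:
                problems.append(f"control rule targets unknown reaction {target!r}")
            for f in rule.factors:
                if not f.actor.startswith("@") and f.actor not in known:
                    problems.append(f"control actor {f.actor!r} unknown")
                if isinstance(f.gain, str) and f.gain not in declared:
                    problems.append(f"control gain parameter {f.gain!r} undeclared")
        for sid, value in self.initial_conditions.items():
            if sid not in known:
                problems.append(f"initial condition for unknown species {sid!r}")
            elif value < 0:
                problems.append(f"negative initial condition for {sid!r} ({value})")
        problems.extend(self.parameters.validate())
        return problems


def _mass_to_nM(mg_per_ml: float, mw: float) -> float:
    """mg/ml -> nM given molecular weight in g/mol (mg/ml == g/L)."""
    return mg_per_ml / mw * 1e9


def _log_bounds(value: float, decades: float = 2.0) -> tuple[float, float]:
    return value * 10.0 ** (-decades), value * 10.0 ** decades


def build_default_model() -> ModelDefinition:
    """Construct the default 18-state, 28-parameter complement network.

    Parameter declaration order fixes the 1..28 index mapping used by the
    sensitivity and pairwise analyses; see the package methods note for the
    full correspondence table.
    """
    species = [
        Species(sid, i, "initiator" if sid in ("C5a", "C5b") else "constant")
        for i, sid in enumerate(DEFAULT_SPECIES)
    ]

    # (name, nominal value, bounds); rate constants in 1/h or nM/h,
    # saturation constants and control gains in nM (gate gain in mg/ml),
    # orders dimensionless.
    nominal: list[tuple[str, float, tuple[float, float]]] = [
        # lectin initiation: C4 cleavage (saturation, lumped MASP enzyme)
        ("k_C4_cleavage", 2000.0, _log_bounds(2000.0)),
        ("K_C4_cleavage", 1500.0, _log_bounds(1500.0)),
        ("eta_C4_cleavage", 1.0, (1.0, 4.0)),
        # lectin initiation: C2 cleavage
        ("k_C2_cleavage", 300.0, _log_bounds(300.0)),
        ("K_C2_cleavage", 200.0, _log_bounds(200.0)),
        ("eta_C2_cleavage", 1.0, (1.0, 4.0)),
        # CP C3 convertase assembly (C4b + C2a)
        ("k_CP_C3_convertase_formation", 1.0e-3, _log_bounds(1.0e-3)),
        # CP C3 convertase activity on C3
        ("k_cat_CP_C3_convertase", 20.0, _log_bounds(20.0)),
        ("K_CP_C3_convertase", 2000.0, _log_bounds(2000.0)),
        ("eta_CP_C3_convertase", 1.2, (1.0, 4.0)),
        # tickover (lumped spontaneous C3 hydrolysis)
        ("k_tickover", 3.0e-4, _log_bounds(3.0e-4)),
        # AP C3 convertase assembly from C3b (factor B/D in excess, lumped)
        ("k_AP_C3_convertase_formation", 0.05, _log_bounds(0.05)),
        # AP C3 convertase activity on C3
        ("k_cat_AP_C3_convertase", 8.0, _log_bounds(8.0)),
        ("K_AP_C3_convertase", 3000.0, _log_bounds(3000.0)),
        ("eta_AP_C3_convertase", 1.0, (1.0, 4.0)),
        # C5 convertase assembly (C3 convertase + C3b)
        ("k_CP_C5_convertase_formation", 2.0e-5, _log_bounds(2.0e-5)),
        ("k_AP_C5_convertase_formation", 2.0e-5, _log_bounds(2.0e-5)),
        # C5 cleavage by the CP C5 convertase
        ("k_cat_CP_C5_convertase", 0.5, _log_bounds(0.5)),
        ("K_CP_C5_convertase", 800.0, _log_bounds(800.0)),
        ("eta_CP_C5_convertase", 1.0, (1.0, 4.0)),
        # C5 cleavage by the AP C5 convertase
        ("k_cat_AP_C5_convertase", 0.5, _log_bounds(0.5)),
        ("K_AP_C5_convertase", 800.0, _log_bounds(800.0)),
        ("eta_AP_C5_convertase", 1.0, (1.0, 4.0)),
        # anaphylatoxin clearance
        ("k_C3a_degradation", 0.05, _log_bounds(0.05)),
        ("k_C5a_degradation", 0.005, _log_bounds(0.005)),
        # control gains: lectin trigger gate (mg/ml), C4BP and factor H (nM)
        ("K_lectin_gate", 0.01, _log_bounds(0.01)),
        ("K_C4BP_inhibition", 1000.0, _log_bounds(1000.0)),
        ("K_factorH_inhibition", 6000.0, _log_bounds(6000.0)),
    ]
    params = ParameterSet(
        names=tuple(n for n, _, _ in nominal),
        values=np.array([v for _, v, _ in nominal]),
        bounds=np.array([b for _, _, b in nominal]),
    )

    reactions = [
        Reaction(
            id="lectin_C4_cleavage",
            rate_law="saturation",
            stoichiometry={"C4": -1, "C4a": 1, "C4b": 1},
            parameter_refs={"k_max": "k_C4_cleavage", "K": "K_C4_cleavage",
                            "eta": "eta_C4_cleavage"},
            enzyme="@lectin_enzyme",
            substrate="C4",
        ),
        Reaction(
            id="lectin_C2_cleavage",
            rate_law="saturation",
            stoichiometry={"C2": -1, "C2a": 1, "C2b": 1},
            parameter_refs={"k_max": "k_C2_cleavage", "K": "K_C2_cleavage",
                            "eta": "eta_C2_cleavage"},
            enzyme="@lectin_enzyme",
            substrate="C2",
        ),
        Reaction(
            id="CP_C3_convertase_formation",
            rate_law="mass_action",
            stoichiometry={"C4b": -1, "C2a": -1, "CP_C3_convertase": 1},
            parameter_refs={"k_max": "k_CP_C3_convertase_formation"},
        ),
        Reaction(
            id="CP_C3_convertase_activity",
            rate_law="saturation",
            stoichiometry={"C3": -1, "C3a": 1, "C3b": 1},
            parameter_refs={"k_max": "k_cat_CP_C3_convertase",
                            "K": "K_CP_C3_convertase",
                            "eta": "eta_CP_C3_convertase"},
            enzyme="CP_C3_convertase",
            substrate="C3",
        ),
        Reaction(
            id="tickover",
            rate_law="first_order",
            stoichiometry={"C3": -1, "C3a": 1, "C3b": 1},
            parameter_refs={"k_max": "k_tickover"},
        ),
        Reaction(
            id="AP_C3_convertase_formation",
            rate_law="first_order",
            stoichiometry={"C3b": -1, "AP_C3_convertase": 1},
            parameter_refs={"k_max": "k_AP_C3_convertase_formation"},
        ),
        Reaction(
            id="AP_C3_convertase_activity",
            rate_law="saturation",
            stoichiometry={"C3": -1, "C3a": 1, "C3b": 1},
            parameter_refs={"k_max": "k_cat_AP_C3_convertase",
                            "K": "K_AP_C3_convertase",
                            "eta": "eta_AP_C3_convertase"},
            enzyme="AP_C3_convertase",
            substrate="C3",
        ),
        Reaction(
            id="CP_C5_convertase_formation",
            rate_law="mass_action",
            stoichiometry={"CP_C3_convertase": -1, "C3b": -1,
                           "CP_C5_convertase": 1},
            parameter_refs={"k_max": "k_CP_C5_convertase_formation"},
        ),
        Reaction(
            id="AP_C5_convertase_formation",
            rate_law="mass_action",
            stoichiometry={"AP_C3_convertase": -1, "C3b": -1,
                           "AP_C5_convertase": 1},
            parameter_refs={"k_max": "k_AP_C5_convertase_formation"},
        ),
        Reaction(
            id="CP_C5_convertase_activity",
            rate_law="saturation",
            stoichiometry={"C5": -1, "C5a": 1, "C5b": 1},
            parameter_refs={"k_max": "k_cat_CP_C5_convertase",
                            "K": "K_CP_C5_convertase",
                            "eta": "eta_CP_C5_convertase"},
            enzyme="CP_C5_convertase",
            substrate="C5",
        ),
        Reaction(
            id="AP_C5_convertase_activity",
            rate_law="saturation",
            stoichiometry={"C5": -1, "C5a": 1, "C5b": 1},
            parameter_refs={"k_max": "k_cat_AP_C5_convertase",
                            "K": "K_AP_C5_convertase",
                            "eta": "eta_AP_C5_convertase"},
            enzyme="AP_C5_convertase",
            substrate="C5",
        ),
        Reaction(
            id="C3a_degradation",
            rate_law="first_order",
            stoichiometry={"C3a": -1},
            parameter_refs={"k_max": "k_C3a_degradation"},
        ),
        Reaction(
            id="C5a_degradation",
            rate_law="first_order",
            stoichiometry={"C5a": -1},
            parameter_refs={"k_max": "k_C5a_degradation"},
        ),
    ]

    controls = {
        # lectin trigger: the gate closes (v -> 0) without initiator
        "lectin_C4_cleavage": ControlRule(
            target_reaction="lectin_C4_cleavage",
            integration="min",
            factors=(ControlFactor("@zymosan", "activating",
                                   "K_lectin_gate", LECTIN_GATE_ORDER),),
        ),
        "lectin_C2_cleavage": ControlRule(
            target_reaction="lectin_C2_cleavage",
            integration="min",
            factors=(ControlFactor("@zymosan", "activating",
                                   "K_lectin_gate", LECTIN_GATE_ORDER),),
        ),
        # C4BP inhibits the CP C3 convertase; factor H the AP C3 convertase
        "CP_C3_convertase_activity": ControlRule(
            target_reaction="CP_C3_convertase_activity",
            integration="min",
            factors=(ControlFactor("C4BP", "inhibiting",
                                   "K_C4BP_inhibition", C4BP_CONTROL_ORDER),),
        ),
        "AP_C3_convertase_activity": ControlRule(
            target_reaction="AP_C3_convertase_activity",
            integration="min",
            factors=(ControlFactor("factor_H", "inhibiting",
                                   "K_factorH_inhibition",
                                   FACTOR_H_CONTROL_ORDER),),
        ),
    }

    initial_conditions = {
        sid: _mass_to_nM(mg, MOLECULAR_WEIGHTS[sid])
        for sid, mg in SERUM_MG_PER_ML.items()
    }

    model = ModelDefinition(
        name="reduced_order_complement",
        species=species,
        reactions=reactions,
        controls=controls,
        initial_conditions=initial_conditions,
        parameters=params,
        initiator="zymosan",
        external_inputs={"lectin_enzyme": 1.0, "zymosan": 0.0},
        molecular_weights=dict(MOLECULAR_WEIGHTS),
    )
    problems = model.validate()
    if problems:  # pragma: no cover - construction bug guard
        raise ConfigurationError("; ".join(problems))
    return model


def knockdown(
    ic: Mapping[str, float], targets: Iterable[str], fraction: float
) -> dict[str, float]:
    """Reduce the initial condition of each target by ``fraction`` percent.

    Emulates an anti-complement intervention (e.g. a C3 inhibitor alone or
    combined with a C5 inhibitor) by scaling initial abundances by
    ``1 - fraction/100``.  Other entries are returned unchanged.
    """
    if not 0.0 <= fraction <= 100.0:
        raise ValueError(f"knockdown fraction must be in [0, 100], got {fraction}")
    out = dict(ic)
    for target in targets:
        if target not in out:
            raise ConfigurationError(f"unknown knockdown target {target!r}")
        out[target] = out[target] * (1.0 - fraction / 100.0)
    return out


# ---------------------------------------------------------------------------
# Model file round-trip (YAML, JSON-compatible structure)
# ---------------------------------------------------------------------------

_MASS_UNITS = {"nM": None, "mg/ml": 1.0, "ug/ml": 1e-3}


def save_model(model: ModelDefinition, path) -> None:
    """Write a model definition to a structured text file (YAML)."""
    doc = {
        "name": model.name,
        "initiator": model.initiator,
        "external_inputs": {k: float(v) for k, v in model.external_inputs.items()},
        "species": [
            {"id": s.id, "time_scale": s.time_scale_rule}
            for s in sorted(model.species, key=lambda s: s.index)
        ],
        "initial_conditions": {
            k: float(v) for k, v in model.initial_conditions.items()
        },
        "initial_condition_units": "nM",
        "molecular_weights": {
            k: float(v) for k, v in model.molecular_weights.items()
        },
        "reactions": [
            {
                "id": r.id,
                "rate_law": r.rate_law,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "parameters": dict(r.parameter_refs),
                **({"enzyme": r.enzyme} if r.enzyme else {}),
                **({"substrate": r.substrate} if r.substrate else {}),
            }
            for r in model.reactions
        ],
        "controls": [
            {
                "reaction": rule.target_reaction,
                "integration": rule.integration,
                "factors": [
                    {
                        "actor": f.actor,
                        "direction": f.direction,
                        "gain": f.gain,
                        "order": f.order,
                    }
                    for f in rule.factors
                ],
            }
            for rule in model.controls.values()
        ],
        "parameters": [
            {"name": n, "value": float(v), "lower": float(lo), "upper": float(hi)}
            for n, v, (lo, hi) in zip(
                model.parameters.names,
                model.parameters.values,
                model.parameters.bounds,
            )
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> ModelDefinition:
    """Read and validate a model file; raise listing every violation.

    Initial conditions may be given in nM (default), or in mg/ml / ug/ml
    with per-species molecular weights declared for conversion.  Species
    without an initial condition default to zero.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    species = [
        Species(s["id"], i, s.get("time_scale", "constant"))
        for i, s in enumerate(doc.get("species", []))
    ]
    params_doc = doc.get("parameters", [])
    params = ParameterSet(
        names=tuple(p["name"] for p in params_doc),
        values=np.array([p["value"] for p in params_doc], dtype=float),
        bounds=np.array(
            [[p.get("lower", p["value"]), p.get("upper", p["value"])]
             for p in params_doc],
            dtype=float,
        ),
    )
    reactions = [
        Reaction(
            id=r["id"],
            rate_law=r["rate_law"],
            stoichiometry=r["stoichiometry"],
            parameter_refs=r.get("parameters", {}),
            enzyme=r.get("enzyme"),
            substrate=r.get("substrate"),
        )
        for r in doc.get("reactions", [])
    ]
    controls = {}
    for c in doc.get("controls", []):
        controls[c["reaction"]] = ControlRule(
            target_reaction=c["reaction"],
            integration=c["integration"],
            factors=tuple(
                ControlFactor(
                    f["actor"], f["direction"], f["gain"], f.get("order", 1.0)
                )
                for f in c.get("factors", [])
            ),
        )

    mw = {k: float(v) for k, v in doc.get("molecular_weights", {}).items()}
    units = doc.get("initial_condition_units", "nM")
    if units not in _MASS_UNITS:
        raise ConfigurationError(f"unknown initial condition units {units!r}")
    ic = {}
    for sid, value in (doc.get("initial_conditions") or {}).items():
        if units == "nM":
            ic[sid] = float(value)
        else:
            if sid not in mw:
                raise ConfigurationError(
                    f"initial condition for {sid!r} given in {units} but no "
                    "molecular weight declared"
                )
            ic[sid] = _mass_to_nM(float(value) * _MASS_UNITS[units], mw[sid])

    model = ModelDefinition(
        name=doc.get("name", "model"),
        species=species,
        reactions=reactions,
        controls=controls,
        initial_conditions=ic,
        parameters=params,
        initiator=doc.get("initiator", "zymosan"),
        external_inputs={
            k: float(v) for k, v in (doc.get("external_inputs") or {}).items()
        },
        molecular_weights=mw,
    )
    problems = model.validate()
    if problems:
        raise ConfigurationError(
            "invalid model file: " + "; ".join(problems)
        )
    return model
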
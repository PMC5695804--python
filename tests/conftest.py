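import numpy as np
import pytest

from complement_rom import build_default_model
from complement_rom.reaction_core import (
    ControlFactor,
    ControlRule,
    ParameterSet,
    Reaction,
    Species,
)
from complement_rom.network import ModelDefinition


@pytest.fixture(scope="session")
def model():
    """The shipped default complement network."""
    return build_default_model()


@pytest.fixture(scope="session")
def nominal(model):
    return model.parameters


def make_decay_model(k: float = 0.3) -> ModelDefinition:
    """Minimal network: first-order C3 -> C3a + C3b (tickover only).

    C3(t) = C3(0) exp(-k t) in closed form, which makes this the oracle
    model for integration accuracy tests.
    """
    params = ParameterSet(
        names=("k_tickover",),
        values=np.array([k]),
        bounds=np.array([[k / 100, k * 100]]),
    )
    return ModelDefinition(
        name="tickover_only",
        species=[Species("C3", 0), Species("C3a", 1), Species("C3b", 2)],
        reactions=[
            Reaction(
                id="tickover",
                rate_law="first_order",
                stoichiometry={"C3": -1, "C3a": 1, "C3b": 1},
                parameter_refs={"k_max": "k_tickover"},
            )
        ],
        controls={},
        initial_conditions={"C3": 100.0},
        parameters=params,
        initiator="zymosan",
        external_inputs={"zymosan": 0.0},
    )


@pytest.fixture()
def decay_model():
    return make_decay_model()


def make_toy_controlled_model() -> ModelDefinition:
    """3-species A -> B conversion gated by an external activator.

    Small enough that S diag(v) r can be assembled by hand in tests.
    """
    params = ParameterSet(
        names=("k_conv", "K_gate"),
        values=np.array([2.0, 1.0]),
        bounds=np.array([[0.02, 200.0], [0.01, 100.0]]),
    )
    return ModelDefinition(
        name="toy",
        species=[Species("A", 0), Species("B", 1),
                 Species("P", 2, "initiator")],
        reactions=[
            Reaction(
                id="convert",
                rate_law="first_order",
                stoichiometry={"A": -1, "B": 1},
                parameter_refs={"k_max": "k_conv"},
            ),
            Reaction(
                id="produce",
                rate_law="first_order",
                stoichiometry={"A": -1, "P": 1},
                parameter_refs={"k_max": "k_conv"},
            ),
        ],
        controls={
            "convert": ControlRule(
                target_reaction="convert",
                integration="min",
                factors=(ControlFactor("@signal", "activating", "K_gate", 1.0),),
            )
        },
        initial_conditions={"A": 5.0},
        parameters=params,
        initiator="signal",
        external_inputs={"signal": 0.0},
    )


@pytest.fixture()
def toy_model():
    return make_toy_controlled_model()
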
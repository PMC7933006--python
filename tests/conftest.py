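import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trpflux.model import (
    ModelDefinition,
    ParameterSet,
    ReactionDef,
    SpeciesDef,
    build_default_model,
)
from trpflux.steady_state import solve_steady_state


def make_toy_model(vmax_out: float = 2.0, km_out: float = 1.0) -> ModelDefinition:
    """One-species balance: constant source flux k0 = 1 into S, Michaelis-
    Menten consumption.  Closed-form steady state S* = Km k0 / (Vmax - k0)
    when Vmax > k0."""
    species = [
        SpeciesDef("X_ext", "source pool", "extracellular", True, 1.0),
        SpeciesDef("S", "substrate", "intracellular", False, 0.0),
    ]
    reactions = [
        ReactionDef("R_src", None, [("X_ext", 1)], [("S", 1)], "irreversible_mm"),
        ReactionDef("R_out", None, [("S", 1)], [], "irreversible_mm"),
    ]
    params = ParameterSet(
        vmax={"R_src": 2.0, "R_out": vmax_out},
        km={"R_src": {"X_ext": 1.0}, "R_out": {"S": km_out}},
    )
    return ModelDefinition(species=species, reactions=reactions, baseline_params=params)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def baseline_steady(default_model):
    result = solve_steady_state(default_model)
    assert result.converged
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
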
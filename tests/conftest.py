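import numpy as np
import pytest

from solvtherm.state_model import (
    CYCLOHEXANE,
    GAS,
    WATER,
    Constants,
    CorrectionParams,
    SpeciesEnsemble,
    StateThermo,
)


@pytest.fixture
def const():
    return Constants()


@pytest.fixture
def identity_params():
    """Parameters that leave the excess chemical potential untouched."""
    return CorrectionParams("1-par", CYCLOHEXANE, c_V=0.0)


def make_state(
    g=0.0,
    compound="c",
    tautomer="t0",
    conformer="c0",
    phase=CYCLOHEXANE,
    mu_ex=0.0,
    V_m=100.0,
    q=0.0,
    **kw,
):
    """A state whose free energy under identity parameters is ``g``.

    With c_mu=1, c_V=0 the per-state exponent is E_sol + mu_ex, so E_sol is
    set to g - mu_ex.
    """
    return StateThermo(
        compound, tautomer, conformer, phase,
        E_sol=g - mu_ex, mu_ex=mu_ex, V_m=V_m, q=q, **kw,
    )


def make_ensemble(gs, compound="c", phase=CYCLOHEXANE, scope="single-tautomer", **kw):
    states = tuple(
        make_state(g, compound=compound, conformer=f"c{i}", phase=phase, **kw)
        for i, g in enumerate(gs)
    )
    return SpeciesEnsemble(compound, scope, phase, states)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
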
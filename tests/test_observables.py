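import math

import numpy as np
import pytest

from solvtherm.observables import (
    PkaModelParams,
    TautomerReaction,
    log_d,
    log_p,
    pka_from_gibbs,
    tautomer_dG_cycle,
    tautomer_dG_direct,
)
from solvtherm.state_model import (
    CYCLOHEXANE,
    GAS,
    WATER,
    Constants,
    CorrectionParams,
    IonizationInfo,
    SpeciesEnsemble,
    StateThermo,
)

from conftest import make_ensemble, make_state


@pytest.fixture
def water_identity():
    return CorrectionParams("1-par", WATER, c_V=0.0)


class TestLogP:
    def test_equal_phases_zero(self, const):
        assert log_p(-10.0, -10.0, const) == 0.0

    def test_rt_ln10_difference_is_one_unit(self, const):
        assert log_p(const.RT_ln10, 0.0, const) == pytest.approx(1.0)
        assert const.RT_ln10 == pytest.approx(1.3643, abs=5e-4)

    def test_antisymmetry(self, const, rng):
        gw, go = rng.normal(size=2) * 10
        assert log_p(gw, go, const) == pytest.approx(-log_p(go, gw, const))

    def test_hydrophilic_compound_negative(self, const):
        # much more stable in water than in the organic phase
        assert log_p(-50.0, -40.0, const) < 0


class TestLogD:
    def test_half_ionized_base(self):
        ion = IonizationInfo("c", "base", pKa=7.4)
        assert log_d(2.0, ion) == pytest.approx(2.0 - math.log10(2))

    def test_acid_one_unit_below_ph(self):
        ion = IonizationInfo("c", "acid", pKa=6.4)
        assert log_d(2.0, ion) == pytest.approx(2.0 - math.log10(1 + 10.0), abs=1e-4)
        assert log_d(2.0, ion) == pytest.approx(0.9586, abs=1e-4)

    def test_never_protonated_base_limits_to_logp(self):
        ion = IonizationInfo("c", "base", pKa=-5.0)
        assert log_d(1.5, ion) == pytest.approx(1.5, abs=1e-6)

    def test_none_site_passthrough(self):
        assert log_d(0.7, IonizationInfo("c", "none")) == 0.7

    def test_missing_pka_rejected(self):
        ion = IonizationInfo.__new__(IonizationInfo)  # bypass to craft invalid input
        object.__setattr__(ion, "compound_id", "c")
        object.__setattr__(ion, "site_type", "acid")
        object.__setattr__(ion, "pKa", None)
        with pytest.raises(ValueError, match="pKa"):
            log_d(1.0, ion)

    def test_logd_never_exceeds_logp(self, rng):
        for _ in range(50):
            logp = float(rng.normal() * 3)
            site = "acid" if rng.uniform() < 0.5 else "base"
            pka = float(rng.uniform(-20, 30))
            assert log_d(logp, IonizationInfo("c", site, pka)) <= logp + 1e-12

    def test_extreme_pka_no_overflow(self):
        ion = IonizationInfo("c", "base", pKa=500.0)
        out = log_d(1.0, ion)
        assert np.isfinite(out) and out == pytest.approx(1.0 - (500.0 - 7.4), abs=1e-6)


class TestPka:
    def test_zero_slope_returns_intercept(self):
        with pytest.warns(UserWarning):
            p = PkaModelParams(a=0.0, b=3.5)
        assert pka_from_gibbs(-10.0, 25.0, p) == 3.5

    def test_zero_case(self):
        p = PkaModelParams(a=0.7, b=0.0)
        assert pka_from_gibbs(-5.0, -5.0, p) == 0.0

    def test_unit_consistency(self, const):
        p = PkaModelParams(a=1.0 / const.RT_ln10, b=0.0)
        assert pka_from_gibbs(0.0, const.RT_ln10, p) == pytest.approx(1.0)

    def test_affine_in_slope(self):
        dG = 4.2
        p1 = PkaModelParams(a=0.5, b=1.0)
        p2 = PkaModelParams(a=1.0, b=1.0)
        pka1 = pka_from_gibbs(0.0, dG, p1)
        pka2 = pka_from_gibbs(0.0, dG, p2)
        assert (pka2 - p2.b) == pytest.approx(2 * (pka1 - p1.b))


def water_species(gs, compound, tautomer="t0"):
    states = tuple(
        make_state(g, compound=compound, tautomer=tautomer, conformer=f"c{i}", phase=WATER)
        for i, g in enumerate(gs)
    )
    return SpeciesEnsemble(compound, "single-tautomer", WATER, states)


class TestTautomerDirect:
    def test_identical_species_zero(self, water_identity, const):
        a = water_species([-10.0], "A")
        b = water_species([-10.0], "B")
        assert tautomer_dG_direct(a, b, water_identity, const).dG == pytest.approx(0.0)

    def test_sign_convention(self, water_identity, const):
        # b more stable than a by 4.8 kcal/mol -> dG(a->b) = -4.8
        a = water_species([-10.0], "1A")
        b = water_species([-14.8], "1B")
        rxn = tautomer_dG_direct(a, b, water_identity, const)
        assert rxn.dG == pytest.approx(-4.8)

    def test_antisymmetry(self, water_identity, const, rng):
        a = water_species(list(rng.normal(size=3) * 5), "A")
        b = water_species(list(rng.normal(size=2) * 5), "B")
        fwd = tautomer_dG_direct(a, b, water_identity, const).dG
        rev = tautomer_dG_direct(b, a, water_identity, const).dG
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_cycle_additivity(self, water_identity, const, rng):
        a, b, c = (water_species(list(rng.normal(size=2) * 5), n) for n in "ABC")
        ab = tautomer_dG_direct(a, b, water_identity, const).dG
        bc = tautomer_dG_direct(b, c, water_identity, const).dG
        ac = tautomer_dG_direct(a, c, water_identity, const).dG
        assert ac == pytest.approx(ab + bc, abs=1e-9)

    def test_phase_mismatch(self, water_identity, const):
        a = water_species([-1.0], "A")
        b = make_ensemble([-1.0], compound="B", phase=CYCLOHEXANE)
        with pytest.raises(ValueError, match="phase"):
            tautomer_dG_direct(a, b, water_identity, const)

    def test_reaction_requires_distinct_species(self):
        with pytest.raises(ValueError):
            TautomerReaction("x", "A", "A", 0.0)


def cycle_species(compound, e_gas, e_sol, mu, e_hl=None, thermal=0.0):
    gas = SpeciesEnsemble(
        compound, "single-tautomer", GAS,
        (StateThermo(compound, "t0", "c0", GAS, E_sol=e_gas, mu_ex=0.0, V_m=1.0,
                     E_gas=e_gas, G_thermal_gas=thermal,
                     E_gas_highlevel=e_hl if e_hl is not None else e_gas),),
    )
    sol = SpeciesEnsemble(
        compound, "single-tautomer", WATER,
        (StateThermo(compound, "t0", "c0", WATER, E_sol=e_sol, mu_ex=mu, V_m=1.0),),
    )
    return gas, sol


class TestTautomerCycle:
    def test_cycle_closure_reduces_to_direct(self, water_identity, const):
        ga, sa = cycle_species("A", e_gas=-3.0, e_sol=-7.0, mu=-2.0)
        gb, sb = cycle_species("B", e_gas=-5.0, e_sol=-10.0, mu=-1.5)
        cyc = tautomer_dG_cycle(ga, sa, gb, sb, water_identity, const).dG
        direct = tautomer_dG_direct(sa, sb, water_identity, const).dG
        assert cyc == pytest.approx(direct, abs=1e-9)

    def test_hand_summed_components(self, water_identity, const):
        # dE_gas(high-level) = -3, d(thermal) = +0.5, ddG_hyd = -1 -> -3.5
        ga, sa = cycle_species("A", e_gas=0.0, e_sol=-4.0, mu=0.0, e_hl=0.0, thermal=0.0)
        gb, sb = cycle_species("B", e_gas=0.0, e_sol=-5.0, mu=0.0, e_hl=-3.0, thermal=0.5)
        got = tautomer_dG_cycle(ga, sa, gb, sb, water_identity, const).dG
        assert got == pytest.approx(-3.5, abs=1e-10)

    def test_antisymmetry(self, water_identity, const):
        ga, sa = cycle_species("A", e_gas=-3.0, e_sol=-7.0, mu=-2.0, e_hl=-3.3, thermal=0.2)
        gb, sb = cycle_species("B", e_gas=-5.0, e_sol=-10.0, mu=-1.5, e_hl=-5.4, thermal=0.1)
        fwd = tautomer_dG_cycle(ga, sa, gb, sb, water_identity, const).dG
        rev = tautomer_dG_cycle(gb, sb, ga, sa, water_identity, const).dG
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_missing_high_level_field_names_state(self, water_identity, const):
        ga, sa = cycle_species("A", e_gas=-3.0, e_sol=-7.0, mu=-2.0)
        gas_missing = SpeciesEnsemble(
            "B", "single-tautomer", GAS,
            (StateThermo("B", "t0", "c0", GAS, E_sol=-5.0, mu_ex=0.0, V_m=1.0, E_gas=-5.0),),
        )
        _, sb = cycle_species("B", e_gas=-5.0, e_sol=-10.0, mu=-1.5)
        with pytest.raises(ValueError, match="E_gas_highlevel"):
            tautomer_dG_cycle(ga, sa, gas_missing, sb, water_identity, const)
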
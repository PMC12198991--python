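import math

import pytest
from hypothesis import given, settings, strategies as st

from thermogav.hess_gibbs import SpeciesThermo, round_printed
from thermogav.reaction_thermo import (
    Reaction,
    equilibrium_constant,
    reaction_enthalpy,
    reaction_enthalpy_uncertainty,
    reaction_entropy,
    reaction_gibbs,
    reaction_report,
)


def dita_reaction(isomer):
    return Reaction(
        {"TMA": -2, f"{isomer}-DABA": -1, f"{isomer}-DITA": 1, "H2O": 2},
        name=f"{isomer} condensation",
    )


class TestReactionEnthalpy:
    @pytest.mark.parametrize(
        "isomer,daba,dita,expected",
        [("3,4", -292.0, -1406.6, -82.85), ("3,5", -289.0, -1410.1, -89.35)],
    )
    def test_condensation_enthalpies_from_printed_inputs(
        self, isomer, daba, dita, expected
    ):
        thermo = {
            "TMA": SpeciesThermo("TMA", dfH=-757.7),
            f"{isomer}-DABA": SpeciesThermo("DABA", dfH=daba),
            f"{isomer}-DITA": SpeciesThermo("DITA", dfH=dita),
            "H2O": SpeciesThermo("H2O", dfH=-241.826),
        }
        drh = reaction_enthalpy(dita_reaction(isomer), thermo)
        assert round_printed(drh, 2) == expected

    def test_degenerate_reaction_is_thermoneutral(self):
        # products-only or reactants-only stoichiometries are rejected
        with pytest.raises(ValueError):
            Reaction({"A": 1, "B": 2})
        with pytest.raises(ValueError):
            Reaction({"A": -1, "B": 0})
        thermo = {
            "A": SpeciesThermo("A", dfH=-12.0, dfS=30.0),
            "B": SpeciesThermo("B", dfH=-12.0, dfS=30.0),
        }
        rxn = Reaction({"A": -1, "B": 1})
        assert reaction_enthalpy(rxn, thermo) == 0.0
        assert reaction_entropy(rxn, thermo) == 0.0

    def test_missing_species_and_missing_field(self):
        rxn = Reaction({"A": -1, "B": 1})
        with pytest.raises(KeyError):
            reaction_enthalpy(rxn, {"A": SpeciesThermo("A", dfH=1.0)})
        thermo = {
            "A": SpeciesThermo("A", dfH=1.0),
            "B": SpeciesThermo("B", dfS=5.0),
        }
        with pytest.raises(ValueError):
            reaction_enthalpy(rxn, thermo)

    def test_entropy_scales_with_stoichiometry(self):
        thermo = {
            "A": SpeciesThermo("A", dfS=-10.0),
            "B": SpeciesThermo("B", dfS=25.0),
        }
        r1 = Reaction({"A": -1, "B": 1})
        r2 = Reaction({"A": -2, "B": 2})
        assert reaction_entropy(r2, thermo) == pytest.approx(
            2 * reaction_entropy(r1, thermo)
        )
        assert reaction_entropy(r1, thermo) == pytest.approx(35.0)


class TestGibbsAndKeq:
    @pytest.mark.parametrize(
        "drH,drS,expected_G,expected_K",
        [(-82.86, -47.92, -68.57, 1.03e12), (-89.36, -44.72, -76.03, 2.09e13)],
    )
    def test_printed_reaction_chains(self, drH, drS, expected_G, expected_K):
        drG = reaction_gibbs(drH, drS)
        assert round_printed(drG, 2) == expected_G
        keq = equilibrium_constant(round_printed(drG, 2))
        assert keq == pytest.approx(expected_K, rel=0.02)

    def test_zero_gibbs_means_unit_keq(self):
        assert equilibrium_constant(0.0) == 1.0
        assert reaction_gibbs(-5.0, 0.0, 400.0) == -5.0

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-200, 200), st.floats(50, 2000))
    def test_reversal_inverts_keq_exactly(self, drG, T):
        k = equilibrium_constant(drG, T)
        k_rev = equilibrium_constant(-drG, T)
        assert k * k_rev == pytest.approx(1.0, rel=1e-9)

    def test_keq_monotone_decreasing_in_gibbs(self):
        ks = [equilibrium_constant(g) for g in (-10.0, 0.0, 10.0)]
        assert ks[0] > ks[1] > ks[2]

    def test_overflow_guard(self):
        with pytest.warns(UserWarning):
            assert equilibrium_constant(-1e5) == math.inf
        with pytest.warns(UserWarning):
            assert equilibrium_constant(1e5) == 0.0

    def test_species_gibbs_route_equals_reaction_gibbs(self):
        # algebraic identity: sum(nu*dfG) == drH - T*drS/1000 when
        # dfG_i = dfH_i - T*dfS_i/1000
        T = 350.0
        thermo = {
            "A": SpeciesThermo("A", dfH=-100.0, dfS=-50.0),
            "B": SpeciesThermo("B", dfH=-20.0, dfS=10.0),
            "C": SpeciesThermo("C", dfH=-150.0, dfS=-80.0),
        }
        rxn = Reaction({"A": -1, "B": -2, "C": 1}, temperature=T)
        via_species = sum(
            nu * (sp.dfH - T * sp.dfS / 1000.0)
            for nu, sp in ((v, thermo[k]) for k, v in rxn.stoichiometry.items())
        )
        drG = reaction_gibbs(
            reaction_enthalpy(rxn, thermo), reaction_entropy(rxn, thermo), T
        )
        assert via_species == pytest.approx(drG, rel=1e-12)


class TestReportAndUncertainty:
    def test_rss_uncertainty_over_stoichiometry(self):
        thermo = {
            "A": SpeciesThermo("A", dfH=0.0, u_dfH=1.8),
            "B": SpeciesThermo("B", dfH=0.0),
            "C": SpeciesThermo("C", dfH=0.0, u_dfH=0.040),
        }
        rxn = Reaction({"A": -1, "B": -2, "C": 2})
        u = reaction_enthalpy_uncertainty(rxn, thermo)
        assert u == pytest.approx(math.hypot(1.8, 2 * 0.040), rel=1e-12)

    def test_packaged_condensation_reports(self, species):
        from thermogav import packaged

        rep34 = reaction_report(packaged.reaction("3,4-DITA"), species)
        assert round_printed(rep34.drH, 2) == -82.85
        assert rep34.drS == -47.92
        assert round_printed(rep34.drG, 2) == -68.56
        assert rep34.keq == pytest.approx(1.03e12, rel=0.02)
        rep35 = reaction_report(packaged.reaction("3,5-DITA"), species)
        assert rep35.keq == pytest.approx(2.09e13, rel=0.02)

    def test_reversed_reaction_negates_everything(self, species):
        from thermogav import packaged

        rxn = packaged.reaction("3,4-DITA")
        fwd = reaction_report(rxn, species)
        rev = reaction_report(rxn.reversed(), species)
        assert rev.drH == pytest.approx(-fwd.drH)
        assert rev.drS == pytest.approx(-fwd.drS)
        assert rev.drG == pytest.approx(-fwd.drG)
        assert rev.keq * fwd.keq == pytest.approx(1.0, rel=1e-9)
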
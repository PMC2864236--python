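"""Model core: transformations, GPR evaluation, net conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxforge.fixtures import toy
from fluxforge.gpr import GeneRule, GeneRuleError
from fluxforge.model import (
    EnvironmentalConditions,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    apply_environmental_conditions,
    apply_knockouts,
    genes_to_reactions,
    net_conversion,
)
from fluxforge.simulation import fba


class TestGeneRule:
    @pytest.mark.parametrize(
        "expr,deleted,expected",
        [
            ("(g1 and g2) or g3", {"g1"}, True),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", set(), True),
            ("g1 and (g2 or g3)", {"g2"}, True),
            ("g1 and (g2 or g3)", {"g2", "g3"}, False),
            ("g1", {"g1"}, False),
        ],
    )
    def test_boolean_evaluation(self, expr, deleted, expected):
        rule = GeneRule(expr)
        assert rule.evaluate({g: False for g in deleted}) is expected

    def test_gene_collection(self):
        assert GeneRule("(g1 and g2) or g3").genes == {"g1", "g2", "g3"}

    @pytest.mark.parametrize("bad", ["", "and", "(g1", "g1 or", "g1 ) g2"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(GeneRuleError):
            GeneRule(bad)


class TestEnvironmentalConditions:
    def test_closed_uptake_kills_all_flux(self):
        m = apply_environmental_conditions(
            toy("TOY-LIN"), EnvironmentalConditions({"R1": (0, 0)})
        )
        assert fba(m, "R3").objective_value == pytest.approx(0.0)

    def test_limited_uptake_caps_the_chain(self):
        m = apply_environmental_conditions(
            toy("TOY-LIN"), EnvironmentalConditions({"R1": (0, 5)})
        )
        assert fba(m, "R3").objective_value == pytest.approx(5.0)

    def test_empty_override_is_identity(self):
        m = toy("TOY-LIN")
        assert apply_environmental_conditions(m, EnvironmentalConditions({})) == m

    def test_input_model_unmodified(self):
        m = toy("TOY-LIN")
        apply_environmental_conditions(m, EnvironmentalConditions({"R1": (0, 1)}))
        assert m.reactions["R1"].upper_bound == 10

    def test_non_drain_override_rejected(self):
        with pytest.raises(ModelError, match="non-drain"):
            apply_environmental_conditions(
                toy("TOY-LIN"), EnvironmentalConditions({"R2": (0, 1)})
            )

    def test_unknown_reaction_rejected(self):
        with pytest.raises(ModelError, match="NOPE"):
            apply_environmental_conditions(
                toy("TOY-LIN"), EnvironmentalConditions({"NOPE": (0, 1)})
            )


class TestKnockouts:
    def test_parallel_route_takes_over(self):
        m = apply_knockouts(toy("TOY-DIAMOND"), {"R2"})
        res = fba(m, "R4")
        assert res.objective_value == pytest.approx(10.0)
        assert res.fluxes["R3"] == pytest.approx(10.0)

    def test_broken_chain_is_dead(self):
        m = apply_knockouts(toy("TOY-LIN"), {"R2"})
        assert fba(m, "R3").objective_value == pytest.approx(0.0)

    def test_empty_knockout_is_identity(self):
        m = toy("TOY-LIN")
        assert apply_knockouts(m, set()) == m

    def test_unknown_id_rejected(self):
        with pytest.raises(ModelError):
            apply_knockouts(toy("TOY-LIN"), {"R99"})

    def test_commutes_with_environment_when_disjoint(self):
        m = toy("TOY-COUPLE")
        env = EnvironmentalConditions({"R1": (0, 4)})
        kos = {"R2"}
        a = apply_knockouts(apply_environmental_conditions(m, env), kos)
        b = apply_environmental_conditions(apply_knockouts(m, kos), env)
        assert a == b


class TestGenesToReactions:
    @pytest.fixture
    def gpr_model(self):
        m = toy("TOY-DIAMOND")
        m.genes = {"g1", "g2", "g3"}
        m.reactions["R2"].gene_rule = GeneRule("(g1 and g2) or g3")
        return m

    def test_isozyme_keeps_reaction(self, gpr_model):
        assert genes_to_reactions(gpr_model, {"g1"}) == set()

    def test_deleting_both_routes_disables(self, gpr_model):
        assert genes_to_reactions(gpr_model, {"g1", "g3"}) == {"R2"}

    def test_empty_deletion_is_identity(self, gpr_model):
        assert genes_to_reactions(gpr_model, set()) == set()

    def test_unknown_gene_rejected(self, gpr_model):
        with pytest.raises(ModelError):
            genes_to_reactions(gpr_model, {"gX"})

    @settings(deadline=None, max_examples=30)
    @given(
        a=st.sets(st.sampled_from(["g1", "g2", "g3"])),
        b=st.sets(st.sampled_from(["g1", "g2", "g3"])),
    )
    def test_monotone_in_deleted_genes(self, a, b):
        """Deleting a superset of genes disables a superset of reactions."""
        m = toy("TOY-DIAMOND")
        m.genes = {"g1", "g2", "g3"}
        m.reactions["R2"].gene_rule = GeneRule("(g1 and g2) or g3")
        m.reactions["R3"].gene_rule = GeneRule("g2 and g3")
        small, big = a, a | b
        assert genes_to_reactions(m, small) <= genes_to_reactions(m, big)


class TestNetConversion:
    def test_linear_chain(self):
        m = toy("TOY-LIN")
        nc = net_conversion(m, {"R1": 10, "R2": 10, "R3": 10})
        assert nc == {"A_ext": pytest.approx(-10), "B_ext": pytest.approx(10)}

    def test_zero_fluxes_give_empty_map(self):
        m = toy("TOY-LIN")
        assert net_conversion(m, {"R1": 0, "R2": 0, "R3": 0}) == {}

    def test_coupled_route(self):
        m = toy("TOY-COUPLE")
        nc = net_conversion(m, {"R1": 10, "R2": 0, "R3": 5, "R4": 5, "R5": 5})
        assert nc == {
            "A_ext": pytest.approx(-10),
            "BIOM_ext": pytest.approx(5),
            "P_ext": pytest.approx(5),
        }

    def test_missing_flux_rejected(self):
        with pytest.raises(ModelError):
            net_conversion(toy("TOY-LIN"), {"R1": 1})

    @pytest.mark.parametrize("name", ["TOY-LIN", "TOY-DIAMOND", "TOY-COUPLE"])
    def test_steady_state_balances_internals(self, name):
        """Any FBA solution leaves every internal metabolite balanced."""
        m = toy(name)
        res = fba(m)
        S, rows, cols = m.stoichiometric_matrix()
        v = np.array([res.fluxes[r] for r in cols])
        assert np.abs(S @ v).max() <= 1e-6


class TestModelStructure:
    def test_duplicate_reaction_ids_rejected(self):
        m = toy("TOY-LIN")
        with pytest.raises(ModelError, match="duplicate"):
            MetabolicModel(
                metabolites=list(m.metabolites.values()),
                reactions=[m.reactions["R1"].copy(), m.reactions["R1"].copy()],
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelError):
            Reaction("R", {"A": 1}, lower_bound=5, upper_bound=1)

    def test_one_sided_drain_gets_external_counterpart(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("EX_A", {"A": 1}, upper_bound=10)],
        )
        assert m.metabolites["A_ext"].external
        assert m.reactions["EX_A"].stoichiometry == {"A": 1, "A_ext": -1}
        assert m.reactions["EX_A"].is_drain

    def test_drain_flags_on_toys(self):
        m = toy("TOY-COUPLE")
        assert {r for r in m.reactions if m.reactions[r].is_drain} == {"R1", "R4", "R5"}
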
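"""FBA, MOMA and ROOM against analytic answers and an independent LP oracle."""

import numpy as np
import pytest

from fluxforge.fixtures import FixtureSpec, random_network, toy
from fluxforge.model import EnvironmentalConditions
from fluxforge.simulation import (
    ReferenceFluxes,
    RoomParameters,
    fba,
    moma,
    room,
    wild_type_reference,
)

from conftest import cobra_fba_oracle, small_random_specs

DIAMOND_REF = ReferenceFluxes({"R1": 10, "R2": 10, "R3": 0, "R4": 10})


class TestFba:
    def test_linear_chain_optimum(self):
        res = fba(toy("TOY-LIN"), "R3")
        assert res.objective_value == pytest.approx(10.0)
        assert [res.fluxes[r] for r in ("R1", "R2", "R3")] == pytest.approx([10, 10, 10])

    def test_minimization_hits_zero(self):
        assert fba(toy("TOY-LIN"), "R3", direction="min").objective_value == pytest.approx(0.0)

    def test_default_objective_is_biomass(self):
        res = fba(toy("TOY-COUPLE"))
        assert res.objective_reaction == "R4"
        assert res.objective_value == pytest.approx(10.0)
        assert res.fluxes["R5"] == pytest.approx(0.0, abs=1e-9)

    def test_mutant_never_beats_wild_type(self, toy_model):
        obj = toy_model.biomass_reaction or "R2"
        wt = fba(toy_model, obj).objective_value
        for rid in toy_model.reactions:
            mut = fba(toy_model, obj, knockouts={rid})
            assert mut.objective_value <= wt + 1e-9

    def test_matches_cobra_oracle_on_toys(self, toy_model):
        obj = toy_model.biomass_reaction or "R2"
        ours = fba(toy_model, obj)
        status, oracle = cobra_fba_oracle(toy_model, obj)
        assert status == "optimal"
        assert ours.objective_value == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("spec", small_random_specs(10, 12, seed0=300, reversible=0.3))
    def test_matches_cobra_oracle_on_random_networks(self, spec):
        m = random_network(spec)
        ours = fba(m)
        status, oracle = cobra_fba_oracle(m)
        assert status == "optimal"
        assert ours.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_shadow_price_of_limiting_metabolite(self):
        """Extra supply of A bypasses the R1 cap, so A's shadow price is 1."""
        res = fba(toy("TOY-LIN"), "R3")
        assert res.shadow_prices["A"] == pytest.approx(1.0)

    def test_relaxing_binding_bound_raises_optimum_accordingly(self):
        m = toy("TOY-LIN")
        base = fba(m, "R3").objective_value
        m.reactions["R1"].upper_bound += 1
        assert fba(m, "R3").objective_value == pytest.approx(base + 1)

    def test_infeasible_status_reported(self):
        m = toy("TOY-LIN")
        m.reactions["R1"].lower_bound = 5.0  # force uptake
        m.reactions["R2"].upper_bound = 0.0  # but block the chain
        m.reactions["R2"].lower_bound = 0.0
        res = fba(m, "R3")
        assert res.status == "infeasible"
        assert res.fluxes == {}


class TestMoma:
    def test_diamond_knockout_analytic_optimum(self):
        """min 2(10-t)^2 + t^2 + 100 over the one-parameter mutant family."""
        res = moma(toy("TOY-DIAMOND"), DIAMOND_REF, knockouts={"R2"})
        expect = {"R1": 20 / 3, "R2": 0.0, "R3": 20 / 3, "R4": 20 / 3}
        for rid, v in expect.items():
            assert res.fluxes[rid] == pytest.approx(v, abs=1e-6)
        assert res.metrics["distance_sq"] == pytest.approx(500 / 3, abs=1e-6)
        assert res.objective_value == pytest.approx(20 / 3, abs=1e-6)

    def test_no_knockout_returns_reference(self):
        res = moma(toy("TOY-DIAMOND"), DIAMOND_REF, knockouts=set())
        assert res.metrics["distance_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_dead_mutant_returns_nearest_feasible_point(self):
        ref = ReferenceFluxes({"R1": 10, "R2": 10, "R3": 10})
        res = moma(toy("TOY-LIN"), ref, knockouts={"R2"})
        assert all(abs(v) < 1e-6 for v in res.fluxes.values())
        assert res.metrics["distance_sq"] == pytest.approx(300.0, abs=1e-5)

    def test_no_sampled_feasible_point_is_closer(self):
        """The QP minimizer beats random feasible mutant flux vectors."""
        m = toy("TOY-DIAMOND")
        res = moma(m, DIAMOND_REF, knockouts={"R2"})
        w = np.array([DIAMOND_REF.fluxes[r] for r in m.reaction_ids])
        best = res.metrics["distance_sq"]
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = rng.uniform(0, 10)  # v = (t, 0, t, t) spans the mutant polytope
            v = np.array([t, 0.0, t, t])
            assert best <= np.sum((v - w) ** 2) + 1e-6


class TestRoom:
    def test_diamond_knockout_two_changes(self):
        """Rerouting through R3 changes only {R2, R3}; throttling changes 3."""
        res = room(toy("TOY-DIAMOND"), DIAMOND_REF, knockouts={"R2"})
        assert res.metrics["changes"] == 2
        assert res.fluxes["R4"] == pytest.approx(10.0, abs=1e-6)
        assert res.fluxes["R3"] == pytest.approx(10.0, abs=1e-6)

    def test_no_knockout_zero_changes(self):
        res = room(toy("TOY-DIAMOND"), DIAMOND_REF, knockouts=set())
        assert res.metrics["changes"] == 0

    def test_lp_relaxation_lower_bounds_the_milp(self):
        milp = room(toy("TOY-DIAMOND"), DIAMOND_REF, knockouts={"R2"})
        relaxed = room(
            toy("TOY-DIAMOND"), DIAMOND_REF, knockouts={"R2"},
            params=RoomParameters(relaxed=True),
        )
        assert relaxed.method == "ROOM-LP"
        assert relaxed.metrics["changes"] <= milp.metrics["changes"] + 1e-9

    def test_change_count_trivial_upper_bound(self):
        """Changes cannot exceed nonzero-reference fluxes plus knockouts."""
        m = toy("TOY-COUPLE")
        ref = wild_type_reference(m)
        res = room(m, ref, knockouts={"R2"})
        nonzero = sum(1 for v in ref.fluxes.values() if abs(v) > 1e-6)
        assert res.metrics["changes"] <= nonzero + 1


class TestReference:
    @pytest.mark.parametrize("name", ["TOY-LIN", "TOY-DIAMOND", "TOY-DEAD", "TOY-COUPLE"])
    def test_wild_type_reference_is_steady_state(self, name):
        toy_model = toy(name)
        ref = wild_type_reference(toy_model)
        S, rows, cols = toy_model.stoichiometric_matrix()
        v = np.array([ref.fluxes[r] for r in cols])
        assert np.abs(S @ v).max() <= 1e-6

    def test_reference_respects_environment(self):
        env = EnvironmentalConditions({"R1": (0, 3)})
        ref = wild_type_reference(toy("TOY-LIN"), env)
        assert ref.fluxes["R3"] == pytest.approx(3.0)
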
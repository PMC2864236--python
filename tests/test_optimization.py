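"""Objective scoring, EA/SA search, and the OptKnock bilevel MILP."""

import itertools

import pytest

from fluxforge.fixtures import toy
from fluxforge.gpr import GeneRule
from fluxforge.model import ModelError, SimulationResult
from fluxforge.optimization import (
    KnockoutSolution,
    MetaheuristicConfig,
    ObjectiveSpec,
    evaluate_objective,
    metaheuristic_optimize,
    optknock,
)
from fluxforge.simplification import find_essential
from fluxforge.simulation import fba
from fluxforge.variability import fva_tight_bounds

BPCY = ObjectiveSpec(kind="BPCY", product="R5", substrate="R1", biomass="R4")
YIELD = ObjectiveSpec(
    kind="YIELD", product="R5", substrate="R1", biomass="R4", min_biomass_fraction=0.3
)


def _sim(fluxes) -> SimulationResult:
    return SimulationResult(
        fluxes=fluxes, method="FBA", objective_reaction="R4",
        objective_value=fluxes.get("R4"), status="optimal",
    )


def exhaustive_best(model, spec, candidates, k):
    best = (None, -1.0)
    wt = fba(model).objective_value
    for combo in itertools.chain.from_iterable(
        itertools.combinations(candidates, i) for i in range(1, k + 1)
    ):
        sim = fba(model, knockouts=set(combo), with_shadow_prices=False)
        score = evaluate_objective(spec, sim, wt)
        if score > best[1]:
            best = (frozenset(combo), score)
    return best


class TestObjectives:
    def test_bpcy_formula(self):
        sim = _sim({"R5": 5, "R4": 5, "R1": 10})
        assert evaluate_objective(BPCY, sim) == pytest.approx(2.5)

    def test_yield_below_biomass_floor_scores_zero(self):
        sim = _sim({"R5": 9, "R4": 0.1, "R1": 10})
        assert evaluate_objective(YIELD, sim, wild_type_biomass=10) == 0.0

    def test_yield_above_floor(self):
        sim = _sim({"R5": 4, "R4": 6, "R1": 10})
        assert evaluate_objective(YIELD, sim, wild_type_biomass=10) == pytest.approx(0.4)

    def test_zero_substrate_scores_zero(self):
        sim = _sim({"R5": 5, "R4": 5, "R1": 0})
        assert evaluate_objective(BPCY, sim) == 0.0
        assert evaluate_objective(YIELD, sim, wild_type_biomass=10) == 0.0

    def test_failed_simulation_scores_zero(self):
        sim = SimulationResult(
            fluxes={}, method="FBA", objective_reaction="R4",
            objective_value=None, status="infeasible",
        )
        assert evaluate_objective(BPCY, sim) == 0.0


@pytest.fixture(scope="module")
def essentials():
    return find_essential(toy("TOY-COUPLE"))


class TestMetaheuristics:
    @pytest.mark.parametrize("strategy", ["EA", "SA"])
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_single_knockout_matches_exhaustive_search(self, strategy, seed, essentials):
        """Both searches find {R2}: forcing flux through the coupled route."""
        m = toy("TOY-COUPLE")
        cfg = MetaheuristicConfig(
            strategy=strategy, max_knockouts=1, population_size=10,
            evaluation_budget=50, seed=seed,
        )
        best = metaheuristic_optimize(m, BPCY, cfg, excluded=essentials)[0]
        cands = [r for r in m.reactions if r not in essentials.essential | {"R1", "R4", "R5"}]
        expect_set, expect_score = exhaustive_best(m, BPCY, cands, 1)
        assert best.deletions == expect_set == frozenset({"R2"})
        assert best.score == pytest.approx(expect_score)
        assert best.product_flux == pytest.approx(5.0)
        assert best.biomass_flux == pytest.approx(5.0)

    def test_fixed_seed_is_bit_reproducible(self, essentials):
        cfg = MetaheuristicConfig(strategy="EA", max_knockouts=2, population_size=8,
                                  evaluation_budget=40, seed=123)
        runs = [
            [(s.deletions, s.score) for s in
             metaheuristic_optimize(toy("TOY-COUPLE"), BPCY, cfg, excluded=essentials)]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_budget_equal_to_population_evaluates_initial_only(self, essentials):
        cfg = MetaheuristicConfig(strategy="EA", max_knockouts=1, population_size=5,
                                  evaluation_budget=5, seed=9)
        ranked = metaheuristic_optimize(toy("TOY-COUPLE"), BPCY, cfg, excluded=essentials)
        assert 0 < len(ranked) <= 5

    def test_variable_representation_respects_max_knockouts(self, essentials):
        cfg = MetaheuristicConfig(strategy="EA", representation="variable",
                                  max_knockouts=2, population_size=8,
                                  evaluation_budget=60, seed=4)
        for sol in metaheuristic_optimize(toy("TOY-COUPLE"), BPCY, cfg, excluded=essentials):
            assert 0 < len(sol.deletions) <= 2

    def test_reported_scores_reproducible_by_resimulation(self, essentials):
        m = toy("TOY-COUPLE")
        wt = fba(m).objective_value
        cfg = MetaheuristicConfig(strategy="SA", max_knockouts=2, evaluation_budget=40, seed=2)
        for sol in metaheuristic_optimize(m, BPCY, cfg, excluded=essentials):
            sim = fba(m, knockouts=set(sol.deletions), with_shadow_prices=False)
            assert evaluate_objective(BPCY, sim, wt) == pytest.approx(sol.score, abs=1e-9)

    def test_essential_targets_never_deleted(self, essentials):
        cfg = MetaheuristicConfig(strategy="EA", max_knockouts=2, population_size=8,
                                  evaluation_budget=60, seed=11)
        for sol in metaheuristic_optimize(toy("TOY-COUPLE"), BPCY, cfg, excluded=essentials):
            assert not (sol.deletions & essentials.essential)

    def test_gene_level_search(self):
        m = toy("TOY-COUPLE")
        m.genes = {"g1", "g2", "g3"}
        m.reactions["R2"].gene_rule = GeneRule("g1")
        m.reactions["R3"].gene_rule = GeneRule("g2 and g3")
        cfg = MetaheuristicConfig(strategy="EA", max_knockouts=1, population_size=3,
                                  evaluation_budget=20, seed=0, target_level="gene")
        best = metaheuristic_optimize(m, BPCY, cfg)[0]
        assert best.deletions == frozenset({"g1"})


class TestOptKnock:
    def test_single_knockout_global_optimum(self, essentials):
        sol = optknock(toy("TOY-COUPLE"), "R5", 1, excluded=essentials)
        assert sol.deletions == frozenset({"R2"})
        assert sol.product_flux == pytest.approx(5.0, abs=1e-6)
        assert sol.biomass_flux == pytest.approx(5.0, abs=1e-6)

    def test_zero_knockouts_gives_wild_type(self, essentials):
        sol = optknock(toy("TOY-COUPLE"), "R5", 0, excluded=essentials, min_biomass=0.0)
        assert sol.deletions == frozenset()
        assert sol.product_flux == pytest.approx(0.0, abs=1e-6)

    def test_candidates_exclude_essentials(self, essentials):
        assert "R1" in essentials.essential and "R4" in essentials.essential
        sol = optknock(toy("TOY-COUPLE"), "R5", 2, excluded=essentials)
        assert not (sol.deletions & essentials.essential)

    def test_matches_exhaustive_search_up_to_two_knockouts(self, essentials):
        m = toy("TOY-COUPLE")
        sol = optknock(m, "R5", 2, excluded=essentials)
        cands = [r for r in m.reactions if r not in essentials.essential | {"R5"}]
        spec = ObjectiveSpec(kind="YIELD", product="R5", substrate="R1", biomass="R4",
                             min_biomass_fraction=0.0)
        # exhaustive inner-FBA search over <= 2 deletions, scored by product
        best_prod = 0.0
        for k in (1, 2):
            for combo in itertools.combinations(cands, k):
                sim = fba(m, knockouts=set(combo), with_shadow_prices=False)
                if sim.ok and sim.objective_value >= 0.05 * 10:
                    best_prod = max(best_prod, sim.fluxes["R5"])
        assert sol.product_flux == pytest.approx(best_prod, abs=1e-6)

    def test_product_bounded_by_fva_under_same_knockouts(self, essentials):
        m = toy("TOY-COUPLE")
        sol = optknock(m, "R5", 1, excluded=essentials)
        from fluxforge.model import apply_knockouts

        tb = fva_tight_bounds(apply_knockouts(m, set(sol.deletions)))
        assert sol.product_flux <= tb["R5"][1] + 1e-6

    def test_missing_biomass_rejected(self):
        with pytest.raises(ModelError):
            optknock(toy("TOY-BRANCH"), "R2", 1)
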
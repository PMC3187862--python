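"""FBA optimization, ATP accounting, yields and flux variability."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import assert_steady_state
from ectoflux import (
    INF,
    MaintenanceLoad,
    Metabolite,
    Reaction,
    Scenario,
    ScenarioInfeasibleError,
    StoichiometricNetwork,
    apply_scenario,
    atp_balance,
    flux_variability,
    max_yield,
    solve_fba,
)
from ectoflux.synth import RandomNetSpec, generate_random_network
from oracles import brute_force_fva


@pytest.fixture()
def linear_chain():
    net = StoichiometricNetwork([Metabolite("a"), Metabolite("b")])
    net.add_reaction(Reaction("EX_A", {"a": Fraction(1)}, upper_bound=10))
    net.add_reaction(Reaction("R1", {"a": Fraction(-1), "b": Fraction(1)}, upper_bound=10))
    net.add_reaction(Reaction("EX_B", {"b": Fraction(-1)}, upper_bound=10))
    return net


class TestSolveFBA:
    def test_single_path_carries_the_fixed_uptake(self, linear_chain):
        sol = solve_fba(linear_chain, "EX_B", fixed_fluxes={"EX_A": 1.0})
        assert sol.optimal
        assert sol.objective_value == pytest.approx(1.0)
        assert_steady_state(linear_chain, sol)

    def test_contradictory_constraints_report_infeasible(self, linear_chain):
        sol = solve_fba(
            linear_chain,
            "EX_B",
            fixed_fluxes={"R1": 1.0},
            bounds_override={"EX_A": (0.0, 0.0)},
        )
        assert sol.status == "infeasible"

    def test_free_internal_cycle_reports_unbounded(self):
        net = StoichiometricNetwork([Metabolite("a"), Metabolite("b")])
        net.add_reaction(Reaction("F", {"a": Fraction(-1), "b": Fraction(1)}))
        net.add_reaction(Reaction("B", {"b": Fraction(-1), "a": Fraction(1)}))
        assert solve_fba(net, "F").status == "unbounded"

    def test_unknown_objective_raises(self, linear_chain):
        with pytest.raises(KeyError):
            solve_fba(linear_chain, "NOPE")

    def test_parsimonious_solution_has_no_gratuitous_cycles(self, model):
        applied = apply_scenario(model, "cycle")
        sol = solve_fba(applied, "EX_ECT", fixed_fluxes={"EX_GLC": 1.0})
        assert sol.optimal
        # the canonical representative does not spin the futile cycle
        assert sol.fluxes["DOEA"] == pytest.approx(0.0, abs=1e-8)
        assert_steady_state(applied, sol)


class TestAtpBalance:
    @pytest.mark.parametrize(
        "scenario,expected",
        [("oren", -2.0), ("gdh", 0.0), ("malic", +1.0)],
    )
    def test_pathway_variant_atp_per_ectoine(self, model, scenario, expected):
        assert atp_balance(model, scenario) == pytest.approx(expected, abs=1e-6)

    def test_variant_span_is_three_atp(self, model):
        assert atp_balance(model, "malic") - atp_balance(model, "oren") == pytest.approx(3.0)

    def test_blocked_scenario_cannot_reach_total_conversion(self, model):
        s = Scenario(name="noect", disabled=frozenset({"ECTC"}))
        with pytest.raises(ScenarioInfeasibleError, match="total conversion"):
            atp_balance(model, s)


class TestMaxYield:
    def test_neutral_pathway_gives_total_conversion_without_load(self, model):
        assert max_yield(model, "gdh", MaintenanceLoad(0.0)) == pytest.approx(1.0)

    def test_generating_pathway_carries_one_atp_per_glucose_of_load(self, model):
        assert max_yield(model, "malic", MaintenanceLoad(1.0)) == pytest.approx(1.0)

    def test_neutral_pathway_collapses_under_load(self, model):
        s = Scenario(
            name="gdh+nadhox",
            enabled=frozenset({"PPC", "GDH", "NADHOX"}),
            disabled=frozenset({"MAE", "MDH", "GS", "GOGAT", "DOEA", "DOEB", "DOEC", "DOED"}),
        )
        assert max_yield(model, s, 0.5) < 1.0

    @pytest.mark.parametrize("scenario", ["gdh", "malic", "oren"])
    def test_yield_never_exceeds_carbon_bound(self, model, scenario):
        for m in (0.0, 0.3, 1.0, 2.5):
            assert 0.0 <= max_yield(model, scenario, m) <= 1.0

    @pytest.mark.parametrize("scenario", ["gdh", "malic"])
    def test_yield_monotone_in_maintenance(self, model, scenario):
        grid = [0.0, 0.25, 0.5, 1.0, 1.5, 3.0]
        yields = [max_yield(model, scenario, m) for m in grid]
        assert all(a >= b for a, b in zip(yields, yields[1:]))

    def test_negative_maintenance_rejected(self, model):
        with pytest.raises(ValueError):
            max_yield(model, "gdh", -0.1)


class TestFluxVariability:
    def test_anaplerotic_node_is_degenerate_at_full_yield(self, model):
        result = flux_variability(
            model, "synthesis", objective="EX_ECT", fraction=1.0, maintenance=0.0
        )
        assert result.optimum == pytest.approx(1.0)
        lo, hi = result["PPC"]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)

    def test_silenced_reaction_has_zero_range(self, model):
        result = flux_variability(model, "synthesis")
        assert result["DOEA"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_envelope_contains_the_optimal_flux_vector(self, model):
        applied = apply_scenario(model, "synthesis")
        sol = solve_fba(
            applied,
            "EX_ECT",
            fixed_fluxes={"EX_GLC": 1.0},
            bounds_override={"ATPDRAIN": (0.0, INF)},
        )
        result = flux_variability(model, "synthesis", maintenance=0.0)
        for rid, flux in sol.fluxes.items():
            lo, hi = result[rid]
            assert lo - 1e-6 <= flux <= hi + 1e-6

    def test_base_infeasibility_is_an_error(self, model):
        with pytest.raises(ScenarioInfeasibleError):
            flux_variability(model, "gdh", maintenance=5.0)

    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_matches_bruteforce_lp_pairs_on_random_networks(self, seed):
        net = generate_random_network(RandomNetSpec(n_internal=5, n_reactions=8, seed=seed))
        capped = net.with_reaction_bounds(
            {
                r.id: (max(r.lower_bound, -10.0), min(r.upper_bound, 10.0))
                for r in net.reactions
            }
        )
        result = flux_variability(capped, None, objective="EX_OUT", fraction=0.5)
        _, expected = brute_force_fva(net, "EX_OUT", 0.5)
        for rid, (lo, hi) in expected.items():
            assert result[rid][0] == pytest.approx(lo, abs=1e-6)
            assert result[rid][1] == pytest.approx(hi, abs=1e-6)


class TestAgainstCobra:
    """Cross-check the LP layer against an independent FBA implementation."""

    def _to_cobra(self, net):
        cobra = pytest.importorskip("cobra")
        m = cobra.Model(id_or_model="check")
        mets = {
            mid: cobra.Metabolite(mid)
            for mid in net.internal_metabolite_ids
        }
        reactions = []
        for r in net.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound = -1000 if r.lower_bound == -INF else r.lower_bound
            cr.upper_bound = 1000 if r.upper_bound == INF else r.upper_bound
            reactions.append(cr)
        m.add_reactions(reactions)
        for r in net.reactions:
            m.reactions.get_by_id(r.id).add_metabolites(
                {
                    mets[mid]: float(c)
                    for mid, c in r.stoichiometry.items()
                    if mid in mets
                }
            )
        return m

    @pytest.mark.parametrize("scenario,expected", [("oren", -2.0), ("malic", 1.0)])
    def test_atp_drain_optimum_agrees(self, model, scenario, expected):
        applied = apply_scenario(model, scenario)
        cm = self._to_cobra(applied)
        cm.reactions.EX_GLC.bounds = (1, 1)
        cm.reactions.EX_ECT.bounds = (1, 1)
        cm.objective = "ATPDRAIN"
        value = cm.optimize().objective_value
        assert value == pytest.approx(expected, abs=1e-6)
        assert value == pytest.approx(atp_balance(model, scenario), abs=1e-6)
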
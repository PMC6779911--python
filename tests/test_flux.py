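"""Model validation, constraint application, FBA/loopless, shuttle behavior."""

import numpy as np
import pandas as pd
import pytest

from nitrosense import flux
from nitrosense.flux import (
    ModelValidationError,
    Reaction,
    apply_constraints,
    concentrations_to_rates,
    fba_optimize,
    internal_l1,
    loopless,
    mass_balance_residual,
    nitrogen_balance,
    packaged_model,
    relax_to_feasible,
    shuttle_report,
)


@pytest.fixture(scope="module")
def model():
    return packaged_model()


@pytest.fixture(scope="module")
def nitrate_solution(model):
    constrained = apply_constraints(model, scenario="nitrate")
    return constrained, loopless(constrained, fba_optimize(constrained))


@pytest.fixture(scope="module")
def urea_solution(model):
    constrained = apply_constraints(model, scenario="urea")
    return constrained, loopless(constrained, fba_optimize(constrained))


class TestLoadAndValidate:
    def test_fixture_loads_clean(self, model):
        model.validate()  # no exception
        assert model.objective == "bof_c"
        for rid in ("EX_no3_e", "EX_urea_e", "EX_o2_e", "AOX_m", "NR_c",
                    "NiR_h", "GSII_h", "GOGAT_h", "URE_m", "GSIII_m",
                    "GOGAT_m", "AST_h", "AST_m", "ALT_h", "ALT_m", "PYC_h",
                    "NH4t_hc", "NH4t_mc", "CPS_m", "OTC_m", "ASS_ASL_c",
                    "ASPt_hm", "ALAt_mh", "GLUt_hm", "GLNt_hm", "bof_c"):
            model.reaction(rid)

    def test_element_corruption_names_consuming_reactions(self, model):
        broken = model.copy()
        broken.metabolites["glu_h"]["N"] = 0
        with pytest.raises(ModelValidationError) as exc:
            broken.validate()
        msg = str(exc.value)
        for rid in ("GSII_h", "AST_h", "ORNS_h"):
            assert rid in msg

    def test_exchanges_exempt_from_balance(self, model):
        # exchange reactions are one-sided and would never balance
        for r in model.reactions:
            if r.type == "exchange":
                assert len(r.stoichiometry) == 1
        model.validate()


class TestUnitConversion:
    def test_conversion_arithmetic(self):
        series = pd.DataFrame(
            {"metabolite": ["pro_c"], "conc_0h": [0.0], "conc_1h": [1000.0]}
        )
        rates = concentrations_to_rates(series)
        assert rates["pro_c"] == pytest.approx(0.7)

    def test_zero_delta(self):
        series = pd.DataFrame(
            {"metabolite": ["pro_c"], "conc_0h": [5.0], "conc_1h": [5.0]}
        )
        assert concentrations_to_rates(series)["pro_c"] == 0.0

    def test_linear_in_protein_fraction(self):
        series = pd.DataFrame(
            {"metabolite": ["pro_c"], "conc_0h": [0.0], "conc_1h": [100.0]}
        )
        full = concentrations_to_rates(series, protein_fraction=0.7)
        half = concentrations_to_rates(series, protein_fraction=0.35)
        assert half["pro_c"] == pytest.approx(full["pro_c"] / 2)

    def test_missing_timepoint_errors(self):
        with pytest.raises(ValueError):
            concentrations_to_rates(
                pd.DataFrame({"metabolite": ["x"], "conc_0h": [1.0]})
            )


class TestConstraints:
    def test_scenario_closes_other_source(self, model):
        m = apply_constraints(model, scenario="nitrate")
        urea = m.reaction("EX_urea_e")
        assert (urea.lb, urea.ub) == (0.0, 0.0)
        m2 = apply_constraints(model, scenario="urea")
        no3 = m2.reaction("EX_no3_e")
        assert (no3.lb, no3.ub) == (0.0, 0.0)

    def test_sink_rate_forced(self, model):
        rates = pd.Series({"pro_c": 0.5})
        m = apply_constraints(model, rates, scenario="nitrate")
        sol = fba_optimize(m)
        assert sol["SINK_pro_c"] == pytest.approx(0.5, abs=1e-9)

    def test_unknown_sink_metabolite_errors(self, model):
        with pytest.raises(ValueError):
            apply_constraints(model, pd.Series({"nope_x": 1.0}), scenario="nitrate")

    def test_named_bounds_applied(self, model):
        m = apply_constraints(model, scenario="nitrate", o2_max=7.5,
                              maintenance=0.4, nh4_transport_cap=0.05)
        assert m.reaction("EX_o2_e").ub == 7.5
        assert m.reaction("AOX_m").lb == 0.4
        assert m.reaction("NH4t_hc").ub == 0.05
        assert m.reaction("NH4t_mc").lb == -0.05


class TestFBA:
    def test_three_reaction_chain_bottleneck(self):
        doc = {
            "id": "chain",
            "metabolites": [
                {"id": "a_e", "compartment": "e", "C": 1, "N": 0},
                {"id": "a_c", "compartment": "c", "C": 1, "N": 0},
            ],
            "reactions": [
                {"id": "EX_a_e", "stoichiometry": {"a_e": -1}, "lb": -5, "ub": 0,
                 "type": "exchange"},
                {"id": "T_a", "stoichiometry": {"a_e": -1, "a_c": 1},
                 "lb": 0, "ub": 1000},
                {"id": "bio", "stoichiometry": {"a_c": -1}, "lb": 0, "ub": 1000,
                 "type": "biomass"},
            ],
            "objective": "bio",
        }
        sol = fba_optimize(flux.load_model(doc))
        assert sol.objective_value == pytest.approx(5.0)

    def test_all_exchanges_closed_zero_growth(self, model):
        m = apply_constraints(model, scenario="nitrate", maintenance=0.0)
        for r in m.reactions:
            if r.type == "exchange":
                r.lb = r.ub = 0.0
        sol = fba_optimize(m)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_objective_matches_cobra(self, model):
        """Independent LP formulation of the same matrices via cobrapy."""
        import cobra

        m = apply_constraints(model, scenario="nitrate")
        cm = cobra.Model("check")
        mets = {mid: cobra.Metabolite(mid) for mid in m.metabolites}
        rxns = []
        for r in m.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lb, r.ub
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r in m.reactions:
            cm.reactions.get_by_id(r.id).add_metabolites(
                {mets[k]: v for k, v in r.stoichiometry.items()}
            )
        cm.objective = "bof_c"
        ref = cm.optimize()
        assert ref.status == "optimal"
        sol = fba_optimize(m)
        assert sol.objective_value == pytest.approx(ref.objective_value, rel=1e-6)


class TestLoopless:
    def test_futile_cycle_removed_objective_kept(self, model):
        m = apply_constraints(model, scenario="nitrate")
        # plant an isolated 2-reaction futile cycle in the chloroplast
        m.metabolites["cycA_h"] = {"id": "cycA_h", "compartment": "h", "C": 1, "N": 0}
        m.metabolites["cycB_h"] = {"id": "cycB_h", "compartment": "h", "C": 1, "N": 0}
        m.reactions.append(Reaction("CYC_f", {"cycA_h": -1, "cycB_h": 1}, 0, 1000))
        m.reactions.append(Reaction("CYC_r", {"cycB_h": -1, "cycA_h": 1}, 0, 1000))
        m.validate()
        sol = fba_optimize(m)
        # force the cycle to carry flux in the input solution
        v = sol.fluxes.copy()
        v["CYC_f"] += 10
        v["CYC_r"] += 10
        pumped = flux.FluxSolution(v, sol.objective_value, "optimal", m)
        assert mass_balance_residual(m, pumped) < 1e-9
        ll = loopless(m, pumped)
        assert ll["CYC_f"] == pytest.approx(0.0, abs=1e-9)
        assert ll["CYC_r"] == pytest.approx(0.0, abs=1e-9)
        assert ll.objective_value == pytest.approx(sol.objective_value, abs=1e-8)
        assert internal_l1(m, ll) <= internal_l1(m, pumped) + 1e-9

    def test_loopfree_solution_unchanged_l1(self, nitrate_solution):
        m, sol = nitrate_solution
        again = loopless(m, sol)
        assert internal_l1(m, again) == pytest.approx(internal_l1(m, sol), abs=1e-6)

    def test_matches_cobra_loopless_l1(self, model):
        """Independent loopless reference (cobrapy CycleFreeFlux) agrees on
        the internal L1 norm of the cleaned solution."""
        import cobra
        from cobra.flux_analysis.loopless import loopless_solution

        m = apply_constraints(model, scenario="nitrate")
        cm = cobra.Model("check")
        mets = {mid: cobra.Metabolite(mid) for mid in m.metabolites}
        rxns = []
        for r in m.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lb, r.ub
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r in m.reactions:
            cm.reactions.get_by_id(r.id).add_metabolites(
                {mets[k]: v for k, v in r.stoichiometry.items()}
            )
        cm.objective = "bof_c"
        ref_ll = loopless_solution(cm)
        sol = loopless(m, fba_optimize(m))
        assert sol.objective_value == pytest.approx(
            ref_ll.fluxes["bof_c"], rel=1e-6
        )


class TestRelaxation:
    def test_feasible_model_unchanged(self, model):
        m = apply_constraints(model, pd.Series({"pro_c": 0.1}), scenario="urea")
        relaxed, report = relax_to_feasible(m)
        assert report == []
        assert relaxed.reaction("SINK_pro_c").lb == pytest.approx(0.1)

    def test_infeasible_proline_sink_reduced_and_named(self, model):
        m = apply_constraints(model, pd.Series({"pro_c": 6.6}), scenario="urea")
        assert not flux.is_feasible(m)
        relaxed, report = relax_to_feasible(m)
        assert len(report) == 1
        assert report[0]["sink"] == "SINK_pro_c"
        assert report[0]["relaxed"] < 6.6
        assert flux.is_feasible(relaxed)

    def test_bisection_matches_grid_search(self, model):
        """The relaxed sink value agrees with a brute-force line search."""
        m = apply_constraints(model, pd.Series({"pro_c": 6.6}), scenario="urea")
        relaxed, report = relax_to_feasible(m)
        found = report[0]["relaxed"]
        # grid search oracle
        lo = 0.0
        for val in np.arange(0.0, 6.6, 1e-3):
            sink = m.copy()
            r = sink.reaction("SINK_pro_c")
            r.lb = r.ub = val
            if flux.is_feasible(sink):
                lo = val
            else:
                break
        assert found == pytest.approx(lo, abs=2e-3)


class TestInvariantsAndShuttles:
    def test_mass_and_nitrogen_balance(self, nitrate_solution, urea_solution):
        for m, sol in (nitrate_solution, urea_solution):
            assert mass_balance_residual(m, sol) <= 1e-6
            assert abs(nitrogen_balance(m, sol)) <= 1e-6

    def test_scenario_flips_shuttle_dominance(self, nitrate_solution, urea_solution):
        rep_n = shuttle_report(nitrate_solution[1])
        rep_u = shuttle_report(urea_solution[1])
        assert rep_n["dominance"]["aspartate"] >= 0.8
        assert rep_n["dominance"]["alanine"] <= 0.1
        assert rep_u["dominance"]["alanine"] >= 0.8
        assert rep_u["dominance"]["aspartate"] <= 0.1

    def test_assimilation_organelle_tracks_source(self, nitrate_solution, urea_solution):
        assert shuttle_report(nitrate_solution[1])["assimilation_organelle"] == "chloroplast"
        assert shuttle_report(urea_solution[1])["assimilation_organelle"] == "mitochondrion"

    def test_arginine_synthesized_arginase_silent(self, nitrate_solution):
        rep = shuttle_report(nitrate_solution[1])
        assert rep["arginine_synthesis_flux"] > 0
        assert abs(rep["arginase_flux"]) <= 1e-9

    def test_all_transporters_zero_means_zero_routes(self, model):
        m = apply_constraints(model, scenario="nitrate")
        zero = flux.FluxSolution(
            pd.Series(0.0, index=m.reaction_ids), 0.0, "optimal", m
        )
        rep = shuttle_report(zero)
        assert all(v == 0 for v in rep["routes_n_flux"].values())
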
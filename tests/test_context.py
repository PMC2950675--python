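"""Context-specific model construction: bounds, objective, GIMME, reduction."""

import numpy as np
import pytest

import helpers
from organflux.context import (
    EvidenceFlags,
    EvidenceTable,
    GimmeError,
    ObjectiveSpec,
    assemble_objective,
    constrain_by_activity,
    derive_exchange_bounds,
    reduce_model,
    run_gimme,
)
from organflux.fba import maximize_flux
from organflux.gpr import parse_gpr
from organflux.model import MetabolicModel, Metabolite, Reaction
from organflux.perturb import simulate_component
from organflux.synth import generate_toy_organ


def _exchange_toy():
    m = MetabolicModel(id="ex", compartments={"b"})
    for mid in ("x_b", "y_b", "z_b"):
        m.add_metabolite(Metabolite(id=mid, compartment="b"))
        m.add_boundary_reaction(mid, "exchange", -1000.0, 1000.0)
    return m


class TestDeriveExchangeBounds:
    def test_blood_and_tissue_freely_exchangeable(self):
        m = _exchange_toy()
        ev = EvidenceTable(
            flags={"x_b": EvidenceFlags(detected_blood=True, detected_tissue=True)}
        )
        bounds = derive_exchange_bounds(m, ev, sbfc=13.5)
        assert bounds["EX_x_b"][:2] == (-1000.0, 13.5)

    def test_urine_only_is_closed(self):
        m = _exchange_toy()
        ev = EvidenceTable(flags={"y_b": EvidenceFlags(detected_urine=True)})
        bounds = derive_exchange_bounds(m, ev, sbfc=13.5)
        assert bounds["EX_y_b"][:2] == (0.0, 0.0)

    def test_urine_and_tissue_is_efflux_only(self):
        m = _exchange_toy()
        ev = EvidenceTable(
            flags={"y_b": EvidenceFlags(detected_urine=True, detected_tissue=True)}
        )
        bounds = derive_exchange_bounds(m, ev, sbfc=13.5)
        assert bounds["EX_y_b"][:2] == (0.0, 13.5)

    def test_secretion_objective_precludes_uptake(self):
        m = _exchange_toy()
        ev = EvidenceTable(
            flags={
                "z_b": EvidenceFlags(
                    detected_blood=True,
                    detected_tissue=True,
                    curated_secretion_objective=True,
                )
            }
        )
        bounds = derive_exchange_bounds(m, ev, sbfc=13.5)
        assert bounds["EX_z_b"][:2] == (0.0, 13.5)

    def test_no_evidence_closed(self):
        m = _exchange_toy()
        bounds = derive_exchange_bounds(m, EvidenceTable(), sbfc=13.5)
        assert all(b[:2] == (0.0, 0.0) for b in bounds.values())

    def test_curated_forbidden_uptake_never_widened(self):
        m = _exchange_toy()
        ev = EvidenceTable(
            flags={
                "x_b": EvidenceFlags(
                    detected_blood=True,
                    detected_tissue=True,
                    curated_uptake_forbidden=True,
                )
            }
        )
        bounds = derive_exchange_bounds(m, ev, sbfc=13.5)
        assert bounds["EX_x_b"].lower >= 0.0


def _objective_toy():
    """Secretable P (synthesized from A) and absorbable G with a demand."""
    m = MetabolicModel(id="obj", compartments={"b", "c", "u"})
    for mid, comp in (
        ("a_b", "b"),
        ("a_c", "c"),
        ("p_c", "c"),
        ("p_u", "u"),
        ("g_b", "b"),
        ("g_c", "c"),
    ):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_boundary_reaction("a_b", "exchange", -1000.0, 13.5)
    m.add_reaction(Reaction("T_a", {"a_b": -1, "a_c": 1}, 0, 1000, kind="transport"))
    m.add_reaction(Reaction("R_p", {"a_c": -1, "p_c": 1}, 0, 1000))
    m.add_reaction(Reaction("T_p", {"p_c": -1, "p_u": 1}, 0, 1000, kind="transport"))
    m.add_boundary_reaction("p_u", "exchange", 0.0, 13.5)
    m.add_boundary_reaction("g_b", "exchange", -1000.0, 13.5)
    m.add_reaction(Reaction("T_g", {"g_b": -1, "g_c": 1}, 0, 1000, kind="transport"))
    return m


class TestAssembleObjective:
    def test_combined_reaction_and_component_boundaries(self):
        m = _objective_toy()
        spec = ObjectiveSpec(
            components=[("p_u", "secretion"), ("g_c", "reabsorption")],
            uptake_reactions={"g_c": "EX_g_b"},
        )
        asm = assemble_objective(m, spec)
        combined = asm.model.reaction(asm.combined_reaction_id)
        assert combined.stoichiometry == {"p_u": -1.0, "g_c": -1.0}
        assert asm.model.has_reaction("DM_g_c")
        assert {c.boundary_reaction_id for c in asm.components} == {"EX_p_u", "DM_g_c"}
        assert asm.incompatible == []

    def test_unproducible_component_reported_and_excluded(self):
        m = _objective_toy()
        m.add_metabolite(Metabolite(id="orphan_c", compartment="c"))
        spec = ObjectiveSpec(
            components=[("p_u", "secretion"), ("orphan_c", "secretion")]
        )
        asm = assemble_objective(m, spec)
        assert ("orphan_c", "secretion") in asm.incompatible
        assert "orphan_c" not in asm.model.reaction(asm.combined_reaction_id).stoichiometry

    def test_atp_maintenance_term_included(self):
        m = _objective_toy()
        for mid in ("atp_c", "h2o_c", "adp_c", "pi_c", "h_c"):
            m.add_metabolite(Metabolite(id=mid, compartment="c"))
        # regenerating cycle so maintenance can run: ADP + Pi -> ATP + H2O
        m.add_reaction(
            Reaction(
                "R_atp_regen",
                {"adp_c": -1, "pi_c": -1, "h_c": -1, "atp_c": 1, "h2o_c": 1},
                0,
                1000,
            )
        )
        spec = ObjectiveSpec(
            components=[("p_u", "secretion")], include_atp_maintenance=True
        )
        asm = assemble_objective(m, spec)
        stoich = asm.model.reaction(asm.combined_reaction_id).stoichiometry
        assert stoich["atp_c"] == -1.0 and stoich["adp_c"] == 1.0

    def test_empty_spec_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            ObjectiveSpec(components=[])


def _gimme_fixture(lo_score=100.0, hi_score=2000.0, threshold=1000.0):
    """Parallel high- and low-expression routes feeding one secreted product."""
    m = helpers.parallel_model(cap1=20.0, cap2=20.0, inlet=1000.0, outlet=10.0)
    m.reaction("P1a").gpr = parse_gpr("g_hi")
    m.reaction("P1b").gpr = parse_gpr("g_hi")
    m.reaction("P2a").gpr = parse_gpr("g_lo")
    m.reaction("P2b").gpr = parse_gpr("g_lo")
    scores = {
        "P1a": hi_score,
        "P1b": hi_score,
        "P2a": lo_score,
        "P2b": lo_score,
    }
    return m, scores, threshold


class TestRunGimme:
    def test_redundant_low_expression_route_inactivated(self):
        m, scores, thr = _gimme_fixture()
        res = run_gimme(m, scores, thr, objective_reaction="DM_b")
        assert res.activity["P2a"] == "inactive"
        assert res.activity["P2b"] == "inactive"
        assert res.activity["P1a"] == "active"
        # the hand-enumerable optimum: all demand flux on the high route
        assert res.inconsistency_score == pytest.approx(0.0, abs=1e-6)

    def test_only_route_kept_active_despite_low_score(self):
        m, scores, thr = _gimme_fixture()
        m.reaction("P1a").upper_bound = 0.0  # high route blocked
        res = run_gimme(m, scores, thr, objective_reaction="DM_b")
        assert res.activity["P2a"] == "active"
        # penalty is forced: 0.9 * 10 flux through two penalized steps
        expected = 2 * (thr - 100.0) * 0.9 * 10.0
        assert res.inconsistency_score == pytest.approx(expected, rel=1e-6)

    def test_objective_attainment_contract(self):
        m, scores, thr = _gimme_fixture()
        res = run_gimme(m, scores, thr, objective_reaction="DM_b", required_fraction=0.9)
        assert res.objective_max == pytest.approx(10.0, abs=1e-6)
        constrained = constrain_by_activity(m, res)
        attained = maximize_flux(constrained, "DM_b").objective_value
        assert attained >= 0.9 * res.objective_max - 1e-6

    def test_all_above_threshold_zero_inconsistency(self):
        m, scores, thr = _gimme_fixture(lo_score=1500.0)
        res = run_gimme(m, scores, thr, objective_reaction="DM_b")
        assert res.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert "inactive" not in res.activity.values()

    def test_unscored_reactions_unpenalized(self):
        m, scores, thr = _gimme_fixture()
        res = run_gimme(m, scores, thr, objective_reaction="DM_b")
        assert res.activity["EX_a"] == "unpenalized-active"
        assert res.activity["DM_b"] == "unpenalized-active"

    def test_infeasible_objective_errors(self):
        m, scores, thr = _gimme_fixture()
        m.reaction("DM_b").upper_bound = 0.0
        with pytest.raises(GimmeError, match="positive optimum"):
            run_gimme(m, scores, thr, objective_reaction="DM_b")

    def test_inconsistency_nonincreasing_as_threshold_drops(self):
        m, scores, _ = _gimme_fixture()
        m.reaction("P1a").upper_bound = 0.0  # force the penalized route
        incons = [
            run_gimme(m, scores, t, objective_reaction="DM_b").inconsistency_score
            for t in (2000.0, 1000.0, 500.0, 100.0)
        ]
        for hi, lo in zip(incons, incons[1:]):
            assert lo <= hi + 1e-9


class TestReduceModel:
    def test_dead_end_branch_excluded(self):
        m = _objective_toy()
        m.add_metabolite(Metabolite(id="dead_c", compartment="c"))
        m.add_reaction(Reaction("R_dead", {"a_c": -1, "dead_c": 1}, 0, 1000))
        spec = ObjectiveSpec(
            components=[("p_u", "secretion"), ("g_c", "reabsorption")],
            uptake_reactions={"g_c": "EX_g_b"},
        )
        asm = assemble_objective(m, spec)
        reduced = reduce_model(asm.model, asm.components)
        assert not reduced.has_reaction("R_dead")
        assert reduced.has_reaction("R_p")

    def test_single_path_model_reduces_to_itself(self):
        m = helpers.chain_model()
        from organflux.context import ObjectiveComponent

        comp = ObjectiveComponent(
            id="b_c_secretion",
            metabolite_id="b_c",
            direction="secretion",
            boundary_reaction_id="DM_b_c",
        )
        reduced = reduce_model(m, [comp])
        assert set(reduced.reaction_ids()) == set(m.reaction_ids())

    @pytest.mark.parametrize("seed", range(5))
    def test_component_optima_preserved(self, seed):
        model, spec, truth = generate_toy_organ(seed=seed, n_pathways=4, depth=3)
        asm = assemble_objective(model, spec)
        reduced = reduce_model(asm.model, asm.components)
        for comp in asm.components:
            full = simulate_component(asm.model, comp)
            red = simulate_component(reduced, comp)
            assert red == pytest.approx(full, abs=1e-6)
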
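"""Drug off-target and gene-deficiency phenotype simulation."""

import numpy as np
import pytest

import helpers
from organflux.context import ObjectiveComponent
from organflux.model import MetabolicModel, Metabolite, Reaction
from organflux.perturb import (
    Perturbation,
    SimulationConfig,
    TargetMap,
    find_cryptic_risk_factors,
    scan_drug_targets,
    scan_gene_deletions,
    sensitivity_sweep,
    simulate_component,
)
from organflux.synth import generate_toy_organ


def _components(truth):
    return {c.id: c for c in truth.components}


class TestSimulateComponent:
    def test_secretion_capped_by_synthesis(self):
        m = helpers.chain_model(caps=(1000.0, 1000.0, 7.0, 1000.0))
        comp = ObjectiveComponent(
            id="b_c_secretion",
            metabolite_id="b_c",
            direction="secretion",
            boundary_reaction_id="DM_b_c",
        )
        assert simulate_component(m, comp) == pytest.approx(7.0, abs=1e-6)

    def test_reabsorption_sums_direct_and_indirect(self, toy_organ):
        model, _spec, truth = toy_organ
        comp = _components(truth)["glc_c_reabsorption"]
        expected = (
            model.reaction("T_glc_direct").upper_bound
            + model.reaction("T_glc_indirect").upper_bound
        )
        assert simulate_component(model, comp) == pytest.approx(expected, abs=1e-6)

    def test_reabsorption_other_uptakes_capped_at_sbfc(self, toy_organ):
        model, _spec, truth = toy_organ
        comp = _components(truth)["glc_c_reabsorption"]
        # with sbfc = 0 the indirect route is still fed by the component's own
        # uptake (raised to Vmax), so the optimum is unchanged on this toy;
        # capping the component's own exchange instead would bind.
        val = simulate_component(model, comp, SimulationConfig(sbfc=0.0))
        assert val == pytest.approx(simulate_component(model, comp), abs=1e-6)

    def test_blocked_component_scores_zero(self):
        m = helpers.chain_model()
        m.reaction("R1").upper_bound = 0.0
        comp = ObjectiveComponent(
            id="b_c_secretion",
            metabolite_id="b_c",
            direction="secretion",
            boundary_reaction_id="DM_b_c",
        )
        assert simulate_component(m, comp) == pytest.approx(0.0, abs=1e-9)

    def test_missing_boundary_reaction_errors(self):
        m = helpers.chain_model()
        comp = ObjectiveComponent(
            id="ghost",
            metabolite_id="b_c",
            direction="secretion",
            boundary_reaction_id="DM_ghost",
        )
        with pytest.raises(KeyError, match="DM_ghost"):
            simulate_component(m, comp)


class TestGeneDeletionScan:
    def test_planted_total_loss_and_isozyme_silence(self, toy_organ):
        model, _spec, truth = toy_organ
        genes = sorted(model.genes())
        matrix = scan_gene_deletions(model, genes, truth.components)
        for gene, comp in truth.planted_total_loss:
            assert matrix.ratio(gene, comp) == pytest.approx(0.0, abs=1e-6)
        for gene in truth.planted_no_phenotype:
            for comp in matrix.components:
                assert matrix.ratio(gene, comp) == pytest.approx(1.0, abs=1e-6)

    def test_planted_partial_ratios_exact(self, toy_organ):
        model, _spec, truth = toy_organ
        genes = [g for g, _c, _r in truth.planted_partial]
        matrix = scan_gene_deletions(model, genes, truth.components)
        for gene, comp, expected in truth.planted_partial:
            assert matrix.ratio(gene, comp) == pytest.approx(expected, abs=1e-6)

    def test_gene_absent_from_gprs_is_row_of_ones(self, toy_organ):
        model, _spec, truth = toy_organ
        matrix = scan_gene_deletions(model, ["not_a_gene"], truth.components)
        assert all(
            matrix.ratio("not_a_gene", c) == 1.0 for c in matrix.components
        )

    def test_all_ratios_within_unit_interval(self, toy_organ):
        model, _spec, truth = toy_organ
        genes = sorted(model.genes())[:20]
        matrix = scan_gene_deletions(model, genes, truth.components)
        vals = matrix.values_pool()
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0 + 1e-6)


class TestDrugTargetScan:
    def test_single_route_target_kills_secretion(self, toy_organ):
        model, _spec, truth = toy_organ
        targets = TargetMap()
        targets.add("t_kill", genes=["secA"])
        matrix = scan_drug_targets(model, targets, truth.components)
        assert matrix.ratio("t_kill", "pgi2_u_secretion") == pytest.approx(0.0, abs=1e-6)

    def test_off_route_target_is_row_of_ones(self, toy_organ):
        model, _spec, truth = toy_organ
        targets = TargetMap()
        targets.add("t_decoy", genes=["dg0_0"])
        matrix = scan_drug_targets(model, targets, truth.components)
        assert all(
            matrix.ratio("t_decoy", c) == pytest.approx(1.0, abs=1e-6)
            for c in matrix.components
        )

    def test_all_row_bounded_by_elementwise_min(self, toy_organ):
        model, _spec, truth = toy_organ
        targets = TargetMap()
        targets.add("t1", genes=["secA"])
        targets.add("t2", genes=["dirT"])
        targets.add("t3", genes=["prim"])
        matrix = scan_drug_targets(model, targets, truth.components)
        singles = matrix.data.drop(index="ALL")
        for comp in matrix.components:
            assert matrix.ratio("ALL", comp) <= singles[comp].min() + 1e-6

    def test_unknown_target_gene_rejected(self, toy_organ):
        model, _spec, truth = toy_organ
        targets = TargetMap()
        targets.add("bad", genes=["ghost_gene"])
        with pytest.raises(ValueError, match="ghost_gene"):
            scan_drug_targets(model, targets, truth.components)


class TestCrypticRiskFactors:
    def test_planted_synergy_detected(self, toy_organ):
        model, _spec, truth = toy_organ
        genes = sorted(model.genes())
        untreated = scan_gene_deletions(model, genes, truth.components)
        treated = scan_gene_deletions(
            model, genes, truth.components, treatment=truth.drug_targets
        )
        found = find_cryptic_risk_factors(untreated, treated)
        expected = {(g, c) for g, _t, c in truth.planted_cryptic}
        assert expected <= set(found)
        # nothing else qualifies: every other found pair is not a planted disorder
        planted_disorders = {(g, c) for g, c in truth.planted_total_loss} | {
            (g, c) for g, c, _r in truth.planted_partial
        }
        assert not (set(found) & planted_disorders)

    def test_gene_deficient_alone_excluded(self, toy_organ):
        model, _spec, truth = toy_organ
        genes = ["secA"]  # total loss untreated -> not cryptic
        untreated = scan_gene_deletions(model, genes, truth.components)
        treated = scan_gene_deletions(
            model, genes, truth.components, treatment=truth.drug_targets
        )
        assert find_cryptic_risk_factors(untreated, treated) == []

    def test_mismatched_axes_error(self, toy_organ):
        model, _spec, truth = toy_organ
        a = scan_gene_deletions(model, ["secA"], truth.components)
        b = scan_gene_deletions(model, ["secB"], truth.components)
        with pytest.raises(ValueError, match="axes"):
            find_cryptic_risk_factors(a, b)


class TestSensitivity:
    def test_single_route_loss_insensitive_to_sbfc(self, toy_organ):
        # grid restricted to sbfc > 0: at 0 the reference model is itself dead
        # and the 0/0 convention reports "no additional disorder"
        model, _spec, truth = toy_organ
        perts = [Perturbation(id="secA", genes=frozenset({"secA"}))]
        comps = [c for c in truth.components if c.id == "pgi2_u_secretion"]
        curves = sensitivity_sweep(
            model, perts, comps, "sbfc", (1.0, 13.5, 200.0, 1000.0)
        )
        (curve,) = curves
        assert all(n == pytest.approx(0.0, abs=1e-9) for n in curve.nsc)

    def test_nsc_zero_at_base_and_bounded(self, toy_organ):
        model, _spec, truth = toy_organ
        perts = [
            Perturbation(id=g, genes=frozenset({g}))
            for g in ("dirT", "indA", "prim", "back")
        ]
        curves = sensitivity_sweep(
            model, perts, truth.components, "sbfc", (0.0, 13.5, 100.0, 1000.0)
        )
        for curve in curves:
            i_base = curve.grid.index(13.5)
            assert curve.nsc[i_base] == 0.0
            assert all(-1.0 - 1e-9 <= n <= 1.0 + 1e-9 for n in curve.nsc)

    def test_bypass_opening_at_high_sbfc_gives_positive_nsc(self):
        # secreted product with main route (cap 5) and bypass through a second
        # efflux-limited exchange; at base sbfc the bypass adds nothing beyond
        # the efflux cap, at sbfc=1000 it fully compensates the knockout.
        m = MetabolicModel(id="bypass", compartments={"b", "c", "u"})
        for mid, comp in (("a_b", "b"), ("a_c", "c"), ("p_c", "c"), ("p_u", "u")):
            m.add_metabolite(Metabolite(id=mid, compartment=comp))
        m.add_boundary_reaction("a_b", "exchange", -1000.0, 10.0)
        m.add_reaction(Reaction("T_a", {"a_b": -1, "a_c": 1}, 0, 1000, kind="transport"))
        m.add_reaction(Reaction("R_main", {"a_c": -1, "p_c": 1}, 0, 1000, gpr="g_main"))
        m.add_reaction(Reaction("R_alt", {"a_c": -1, "p_c": 1}, 0, 5.0, gpr="g_alt"))
        m.add_reaction(Reaction("T_p", {"p_c": -1, "p_u": 1}, 0, 1000, kind="transport"))
        m.add_boundary_reaction("p_u", "exchange", 0.0, 10.0)
        comp = ObjectiveComponent(
            id="p_u_secretion",
            metabolite_id="p_u",
            direction="secretion",
            boundary_reaction_id="EX_p_u",
        )
        perts = [Perturbation(id="g_main", genes=frozenset({"g_main"}))]
        curves = sensitivity_sweep(
            m, perts, [comp], "sbfc", (5.0, 10.0), SimulationConfig(sbfc=10.0)
        )
        (curve,) = curves
        # base: ratio 5/10; sbfc=5: ratio 5/5 = 1 -> NSC = +1
        assert curve.base_ratio == pytest.approx(0.5, abs=1e-6)
        nsc_at_5 = curve.nsc[curve.grid.index(5.0)]
        assert nsc_at_5 == pytest.approx(1.0, abs=1e-6)

    def test_base_value_must_be_on_grid(self, toy_organ):
        model, _spec, truth = toy_organ
        with pytest.raises(ValueError, match="grid point"):
            sensitivity_sweep(
                model,
                [Perturbation(id="secA", genes=frozenset({"secA"}))],
                truth.components,
                "sbfc",
                (0.0, 100.0),
            )

    def test_ratios_monotone_in_inhibition_fraction(self, toy_organ):
        model, _spec, truth = toy_organ
        hit = truth.drug_targets.reactions_hit(model, ["offtarget1"])
        perts = [Perturbation(id="offtarget1", reactions=frozenset(hit))]
        curves = sensitivity_sweep(
            model,
            perts,
            truth.components,
            "inhibition_fraction",
            (0.0, 0.25, 0.5, 0.75, 1.0),
        )
        for curve in curves:
            for lo, hi in zip(curve.ratios, curve.ratios[1:]):
                assert lo <= hi + 1e-6
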
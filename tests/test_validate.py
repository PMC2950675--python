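"""ROC/AROC machinery, permutation null, cross-validation, set overlaps."""

import numpy as np
import pandas as pd
import pytest

from organflux.perturb import PerturbationMatrix
from organflux.validate import (
    BenchmarkTable,
    activity_set_overlap,
    crossval_recall,
    overlap_enrichment,
    permutation_null,
    roc_analysis,
)


def _matrix(values: dict, components=("C1",)) -> PerturbationMatrix:
    rows = sorted({g for g, _ in values})
    data = pd.DataFrame(
        [[values.get((g, c), 1.0) for c in components] for g in rows],
        index=rows,
        columns=list(components),
    )
    return PerturbationMatrix(data=data)


def _benchmark(pos, neg, component="C1"):
    records = [(g, component, "positive") for g in pos] + [
        (g, component, "negative") for g in neg
    ]
    return BenchmarkTable.from_records(records)


def mann_whitney_auc(pos_ratios, neg_ratios):
    """Rank-based oracle: P(pos < neg) + 0.5 P(tie), averaged over all pairs."""
    total = 0.0
    for p in pos_ratios:
        for n in neg_ratios:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_ratios) * len(neg_ratios))


class TestRocAnalysis:
    def test_perfect_separation(self):
        m = _matrix({("g1", "C1"): 0.2, ("g2", "C1"): 0.4, ("g3", "C1"): 1.0, ("g4", "C1"): 1.0})
        roc = roc_analysis(m, _benchmark(["g1", "g2"], ["g3", "g4"]))
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_classifier(self):
        m = _matrix({("g1", "C1"): 1.0, ("g2", "C1"): 1.0, ("g3", "C1"): 1.0})
        roc = roc_analysis(m, _benchmark(["g1"], ["g2", "g3"]))
        assert roc.auc == pytest.approx(0.5)

    def test_hand_computed_trapezoid(self):
        m = _matrix(
            {("g1", "C1"): 0.2, ("g2", "C1"): 1.0, ("g3", "C1"): 0.5, ("g4", "C1"): 1.0}
        )
        roc = roc_analysis(m, _benchmark(["g1", "g2"], ["g3", "g4"]))
        # sweep by hand over thresholds {0, 0.2, 0.5, 1} plus the closing point
        assert roc.auc == pytest.approx(0.625)

    def test_missing_class_errors(self):
        m = _matrix({("g1", "C1"): 0.2})
        with pytest.raises(ValueError, match="negative"):
            roc_analysis(m, _benchmark(["g1"], []))
        with pytest.raises(ValueError, match="positive"):
            roc_analysis(m, _benchmark([], ["g1"]))

    def test_tpr_fpr_nondecreasing(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = {(g, "C1"): float(rng.uniform(0, 1)) for g in genes}
        m = _matrix(values)
        roc = roc_analysis(m, _benchmark(genes[:12], genes[12:]))
        assert all(a <= b + 1e-12 for a, b in zip(roc.tpr, roc.tpr[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(roc.fpr, roc.fpr[1:]))

    def test_matches_mann_whitney_oracle_on_distinct_ratios(self, rng):
        for _ in range(25):
            genes = [f"g{i}" for i in range(20)]
            ratios = rng.permutation(np.linspace(0.01, 0.99, 20))
            values = {(g, "C1"): float(r) for g, r in zip(genes, ratios)}
            pos, neg = genes[:8], genes[8:]
            roc = roc_analysis(_matrix(values), _benchmark(pos, neg))
            oracle = mann_whitney_auc(
                [values[(g, "C1")] for g in pos], [values[(g, "C1")] for g in neg]
            )
            assert roc.auc == pytest.approx(oracle, abs=1e-9)


class TestPermutationNull:
    def _setup(self, rng, n=24):
        genes = [f"g{i}" for i in range(n)]
        values = {}
        pos, neg = [], []
        for i, g in enumerate(genes):
            if i < n // 3:
                values[(g, "C1")] = float(rng.uniform(0.0, 0.4))
                pos.append(g)
            else:
                values[(g, "C1")] = 1.0
                neg.append(g)
        return _matrix(values), _benchmark(pos, neg)

    def test_mean_auc_near_half_at_100_trials(self, rng):
        m, b = self._setup(rng)
        res = permutation_null(m, b, n_trials=100, seed=11)
        assert 0.4 <= res.mean_auc <= 0.6

    def test_mean_auc_tightens_at_1000_trials(self, rng):
        m, b = self._setup(rng)
        res = permutation_null(m, b, n_trials=1000, seed=13)
        assert abs(res.mean_auc - 0.5) <= 0.03

    def test_separable_benchmark_significant(self, rng):
        m, b = self._setup(rng)
        res = permutation_null(m, b, n_trials=100, seed=17)
        assert res.observed_auc == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_fixed_seed_reproducible(self, rng):
        m, b = self._setup(rng)
        r1 = permutation_null(m, b, n_trials=50, seed=23)
        r2 = permutation_null(m, b, n_trials=50, seed=23)
        assert r1.aucs == r2.aucs

    def test_too_few_trials_error(self, rng):
        m, b = self._setup(rng)
        with pytest.raises(ValueError, match="2 trials"):
            permutation_null(m, b, n_trials=1, seed=1)


class TestOverlapEnrichment:
    def test_exact_combinatorial_value(self):
        # C(4,4) * C(16,1) / C(20,5) = 16/15504
        assert overlap_enrichment(20, 4, 5, 4) == pytest.approx(16 / 15504, rel=1e-12)

    def test_disjoint_sets_p_one(self):
        assert overlap_enrichment(20, 4, 5, 0) == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        ps = [overlap_enrichment(40, 8, 10, k) for k in range(0, 9)]
        assert ps == sorted(ps, reverse=True)


class TestCrossval:
    def test_held_out_objective_genes_recovered(self, toy_organ):
        from organflux.context import assemble_objective
        from organflux.synth import generate_expression

        model, spec, truth = toy_organ
        asm = assemble_objective(model, spec)
        rep1, rep2, pmap, _ = generate_expression(
            model, 31, truth.expressed_gene_set, dropout_prob=0.0
        )
        from organflux.expression import build_profile

        profile = build_profile(asm.model, rep1, rep2, pmap)
        cv = crossval_recall(
            asm.model,
            profile.gene_values,
            objective_reaction=asm.combined_reaction_id,
        )
        assert len(cv.folds) == 5
        # the most highly expressed fold is dominated by planted objective-route
        # genes, which GIMME must keep to attain the objective
        assert cv.folds[0].recall >= 0.75
        assert cv.folds[0].p_adjusted < 0.05
        for f in cv.folds:
            assert 0.0 <= f.recall <= 1.0
            assert 0.0 <= f.p_value <= 1.0

    def test_too_few_genes_error(self, toy_organ):
        model, spec, truth = toy_organ
        from organflux.context import assemble_objective

        asm = assemble_objective(model, spec)
        with pytest.raises(ValueError, match="measured network genes"):
            crossval_recall(
                asm.model,
                {"secA": 5.0},
                objective_reaction=asm.combined_reaction_id,
            )


class TestActivityOverlap:
    def test_identical_sets(self):
        out = activity_set_overlap({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert out["all_three"] == 2
        assert sum(v for k, v in out.items() if k != "all_three") == 0

    def test_pairwise_disjoint(self):
        out = activity_set_overlap({"a"}, {"b"}, {"c"})
        assert (out["predicted_only"], out["expressed_only"], out["detected_only"]) == (1, 1, 1)
        assert out["all_three"] == 0

    def test_pairwise_overlaps(self):
        out = activity_set_overlap({"a", "b"}, {"b", "c"}, {"c", "a"})
        assert out["predicted_expressed"] == 1  # b
        assert out["expressed_detected"] == 1  # c
        assert out["predicted_detected"] == 1  # a
        assert out["all_three"] == 0
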
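"""Clinical benchmarking of perturbation predictions.

The benchmark is a table of (gene, component) pairs labelled positive
(a clinically observed disorder of that organ function under that gene
deficiency) or negative (clinically confirmed absent). Predictions are
the simulated flux-capacity ratios: sweeping the disorder-call
threshold over [0, 1] yields an ROC curve whose area (AROC, trapezoidal
rule) summarizes sensitivity and specificity; significance is assessed
against a permutation null in which the ratio values are shuffled
across cells, using a one-sample left-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .perturb import PerturbationMatrix

__all__ = [
    "BenchmarkTable",
    "RocResult",
    "PermutationResult",
    "CrossvalResult",
    "roc_analysis",
    "permutation_null",
    "overlap_enrichment",
    "crossval_recall",
    "activity_set_overlap",
]


@dataclass
class BenchmarkTable:
    """Clinically observed positive/negative (gene, component) phenotype pairs."""

    entries: pd.DataFrame  # columns: gene, component, outcome

    def __post_init__(self) -> None:
        required = {"gene", "component", "outcome"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"benchmark requires columns {sorted(required)}")
        bad = set(self.entries["outcome"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown outcome labels {sorted(bad)}")
        if self.entries.duplicated(["gene", "component"]).any():
            raise ValueError("duplicate (gene, component) pairs in benchmark")

    def pairs(self, outcome: str) -> List[Tuple[str, str]]:
        sub = self.entries[self.entries["outcome"] == outcome]
        return list(zip(sub["gene"], sub["component"]))

    @classmethod
    def from_records(cls, records: Sequence[Tuple[str, str, str]]) -> "BenchmarkTable":
        return cls(pd.DataFrame(records, columns=["gene", "component", "outcome"]))

    @classmethod
    def from_tsv(cls, path) -> "BenchmarkTable":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={"gene_id": "gene", "component_id": "component"})
        return cls(df[["gene", "component", "outcome"]])

    def to_tsv(self, path) -> None:
        self.entries.rename(
            columns={"gene": "gene_id", "component": "component_id"}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class RocResult:
    """ROC curve from sweeping the disorder ratio threshold over [0, 1].

    ``thresholds`` are the distinct observed ratios plus the endpoints
    0 and 1; classification at threshold t calls a disorder iff
    ratio < t (strict), so t = 0 calls nothing. The curve is closed
    with the call-everything point (1, 1) before integrating. Both
    mean-TPR variants (with and without the endpoint thresholds) are
    reported since the sweep's endpoints are a convention.
    """

    thresholds: List[float]
    tpr: List[float]
    fpr: List[float]
    auc: float
    mean_tpr: float
    mean_tpr_interior: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "auc": self.auc,
            "mean_tpr": self.mean_tpr,
            "mean_tpr_interior": self.mean_tpr_interior,
        }


def _ratio_lookup(ratios) -> Callable[[str, str], float]:
    if isinstance(ratios, PerturbationMatrix):
        return ratios.ratio
    if isinstance(ratios, Mapping):
        return lambda g, c: ratios[(g, c)]
    raise TypeError("ratios must be a PerturbationMatrix or a mapping of (gene, component)")


def _roc_from_labels(pos_ratios: np.ndarray, neg_ratios: np.ndarray) -> RocResult:
    thresholds = sorted(set(pos_ratios) | set(neg_ratios) | {0.0, 1.0})
    tpr, fpr = [], []
    for t in thresholds:
        tpr.append(float(np.mean(pos_ratios < t)))
        fpr.append(float(np.mean(neg_ratios < t)))
    # close the curve at the call-everything corner
    curve_fpr = fpr + [1.0]
    curve_tpr = tpr + [1.0]
    auc = float(np.trapezoid(curve_tpr, curve_fpr))
    mean_tpr = float(np.mean(tpr))
    interior = tpr[1:-1] if len(tpr) > 2 else tpr
    return RocResult(
        thresholds=[float(t) for t in thresholds],
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        mean_tpr=mean_tpr,
        mean_tpr_interior=float(np.mean(interior)),
    )


def roc_analysis(ratios, benchmark: BenchmarkTable) -> RocResult:
    """ROC/AROC of simulated ratios against the clinical benchmark.

    Every benchmark pair must have a computed ratio. Raises when the
    benchmark lacks positives or negatives — the curve is undefined
    then.
    """
    lookup = _ratio_lookup(ratios)
    pos = benchmark.pairs("positive")
    neg = benchmark.pairs("negative")
    if not pos:
        raise ValueError("benchmark has no positive entries")
    if not neg:
        raise ValueError("benchmark has no negative entries")
    pos_ratios = np.array([lookup(g, c) for g, c in pos], dtype=float)
    neg_ratios = np.array([lookup(g, c) for g, c in neg], dtype=float)
    return _roc_from_labels(pos_ratios, neg_ratios)


@dataclass
class PermutationResult:
    observed_auc: float
    mean_auc: float
    aucs: List[float]
    p_value: float
    observed_mean_tpr: float
    mean_tpr_null: float
    tpr_p_value: float
    seed: Optional[int] = None


def permutation_null(
    ratios: PerturbationMatrix,
    benchmark: BenchmarkTable,
    n_trials: int = 100,
    seed: Optional[int] = None,
    per_gene: bool = False,
) -> PermutationResult:
    """Permutation null for the AROC: shuffle ratios, re-run the ROC.

    Each trial permutes the computed ratio values across all matrix
    cells (``per_gene=True`` instead shuffles within each gene's row)
    and recomputes the AROC. Significance of the observed AROC (and of
    the mean true positive rate) is a one-sample left-tailed t-test of
    the null values against the observed one.
    """
    if n_trials < 2:
        raise ValueError("permutation null requires at least 2 trials")
    rng = np.random.default_rng(seed)
    observed = roc_analysis(ratios, benchmark)

    values = ratios.data.to_numpy(copy=True)
    shape = values.shape
    aucs, mean_tprs = [], []
    index = {g: i for i, g in enumerate(ratios.perturbations)}
    cols = {c: j for j, c in enumerate(ratios.components)}
    pos = benchmark.pairs("positive")
    neg = benchmark.pairs("negative")
    for _ in range(n_trials):
        if per_gene:
            shuffled = np.vstack([rng.permutation(row) for row in values])
        else:
            shuffled = rng.permutation(values.ravel()).reshape(shape)
        pos_r = np.array([shuffled[index[g], cols[c]] for g, c in pos])
        neg_r = np.array([shuffled[index[g], cols[c]] for g, c in neg])
        trial = _roc_from_labels(pos_r, neg_r)
        aucs.append(trial.auc)
        mean_tprs.append(trial.mean_tpr)

    t_auc = stats.ttest_1samp(aucs, popmean=observed.auc, alternative="less")
    t_tpr = stats.ttest_1samp(mean_tprs, popmean=observed.mean_tpr, alternative="less")
    return PermutationResult(
        observed_auc=observed.auc,
        mean_auc=float(np.mean(aucs)),
        aucs=aucs,
        p_value=float(t_auc.pvalue),
        observed_mean_tpr=observed.mean_tpr,
        mean_tpr_null=float(np.mean(mean_tprs)),
        tpr_p_value=float(t_tpr.pvalue),
        seed=seed,
    )


# --------------------------------------------------------------------------
# cross-validation of the model-building approach
# --------------------------------------------------------------------------


def overlap_enrichment(
    population: int, held_out: int, predicted: int, overlap: int
) -> float:
    """Hypergeometric upper-tail probability of the observed overlap.

    Drawing ``predicted`` genes from a population containing
    ``held_out`` successes, the probability of an overlap at least as
    large as observed.
    """
    return float(stats.hypergeom.sf(overlap - 1, population, held_out, predicted))


@dataclass
class FoldResult:
    fold: int
    held_out: List[str]
    predicted_active: List[str]
    recall: float
    p_value: float
    p_adjusted: float


@dataclass
class CrossvalResult:
    folds: List[FoldResult]

    @property
    def mean_recall(self) -> float:
        return float(np.mean([f.recall for f in self.folds]))

    @property
    def min_p_adjusted(self) -> float:
        return float(min(f.p_adjusted for f in self.folds))


def crossval_recall(
    model,
    gene_values: Mapping[str, float],
    objective_reaction: str,
    required_fraction: float = 0.90,
    p_target: float = 0.05,
    fraction: float = 0.20,
    folds: int = 5,
) -> CrossvalResult:
    """Cross-validated recall of held-out expressed genes by the context model.

    Network genes with expression data are ranked by value; the ranked
    list is split into ``folds`` contiguous blocks of ``fraction``
    each, so the first fold holds out the most highly expressed block.
    Per fold the held-out genes' data is removed, the significance
    threshold and GIMME activity classification are recomputed, and
    recall is the share of held-out genes recovered among the genes of
    active reactions. Enrichment significance is hypergeometric with
    Bonferroni adjustment across folds.
    """
    from .context import run_gimme
    from .expression import reaction_scores as score_reactions
    from .expression import significance_threshold

    network_genes = model.genes()
    measured = sorted(
        (g for g in network_genes if g in gene_values),
        key=lambda g: (-gene_values[g], g),
    )
    n = len(measured)
    block = max(1, int(round(fraction * n)))
    if n < folds:
        raise ValueError(f"need at least {folds} measured network genes, got {n}")

    results: List[FoldResult] = []
    for k in range(folds):
        held = measured[k * block : (k + 1) * block]
        if not held:
            raise ValueError(f"fold {k}: empty held-out set (too few genes)")
        retained = {g: v for g, v in gene_values.items() if g not in set(held)}
        threshold = significance_threshold(retained.values(), p=p_target)
        scores = score_reactions(model, retained)
        gimme = run_gimme(
            model,
            scores,
            threshold,
            objective_reaction=objective_reaction,
            required_fraction=required_fraction,
        )
        predicted: set[str] = set()
        for rid in gimme.active_reactions():
            predicted |= model.reaction(rid).gpr.genes()
        predicted &= network_genes
        overlap = len(predicted & set(held))
        recall = overlap / len(held)
        p = overlap_enrichment(len(network_genes), len(held), len(predicted), overlap)
        results.append(
            FoldResult(
                fold=k,
                held_out=list(held),
                predicted_active=sorted(predicted),
                recall=recall,
                p_value=p,
                p_adjusted=min(1.0, p * folds),
            )
        )
    return CrossvalResult(folds=results)


def activity_set_overlap(
    predicted_active: set, expressed: set, detected_proteins: set
) -> Dict[str, int]:
    """All seven disjoint regions of the three-way set diagram."""
    a, b, c = set(predicted_active), set(expressed), set(detected_proteins)
    return {
        "predicted_only": len(a - b - c),
        "expressed_only": len(b - a - c),
        "detected_only": len(c - a - b),
        "predicted_expressed": len((a & b) - c),
        "predicted_detected": len((a & c) - b),
        "expressed_detected": len((b & c) - a),
        "all_three": len(a & b & c),
    }
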
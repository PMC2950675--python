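"""Two-replicate probe-intensity processing.

The pipeline mirrors classic two-array normalization: a global scaling
factor equalizes total intensity between replicates, a lowess fit in
MA space removes intensity-dependent bias, replicates are averaged,
probesets collapse to genes by the maximum rule, genes collapse to
reactions through the GPR rules (min over complexes, max over
isozymes), and a Gaussian fit of the gene values yields the
significance threshold used downstream to penalize lowly expressed
reactions.

Probe tables are mappings from probeset id to background-subtracted
intensity; internally everything is a :class:`pandas.Series`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .gpr import evaluate_gpr_expression
from .model import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "global_normalize",
    "smooth_replicates",
    "average_replicates",
    "gene_values_from_probesets",
    "reaction_scores",
    "significance_threshold",
    "build_profile",
    "read_probe_table",
    "read_probe_map",
]

log = logging.getLogger(__name__)

#: default lowess span (fraction of points per local fit)
DEFAULT_SPAN = 0.3


@dataclass
class ExpressionProfile:
    """Gene- and reaction-level expression scores plus the significance threshold."""

    gene_values: Dict[str, float]
    reaction_scores: Dict[str, Optional[float]]
    threshold: float
    threshold_p: float = 0.05

    def expressed_genes(self) -> set[str]:
        return {g for g, v in self.gene_values.items() if v >= self.threshold}

    def to_table(self) -> pd.DataFrame:
        genes = sorted(self.gene_values)
        return pd.DataFrame(
            {
                "gene": genes,
                "value": [self.gene_values[g] for g in genes],
                "above_threshold": [
                    self.gene_values[g] >= self.threshold for g in genes
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _as_series(table: Mapping[str, float]) -> pd.Series:
    s = pd.Series(table, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("probe intensities must be finite")
    return s


def global_normalize(
    rep1: Mapping[str, float], rep2: Mapping[str, float]
) -> pd.Series:
    """Rescale replicate 2 so its total intensity matches replicate 1.

    The factor is sum(rep1) / sum(rep2); afterwards the totals agree
    exactly.
    """
    s1, s2 = _as_series(rep1), _as_series(rep2)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("probe tables must be non-empty")
    t1, t2 = float(s1.sum()), float(s2.sum())
    if t1 <= 0 or t2 <= 0:
        raise ValueError("probe tables must have positive total intensity")
    return s2 * (t1 / t2)


def smooth_replicates(
    rep1: Mapping[str, float],
    rep2: Mapping[str, float],
    span: float = DEFAULT_SPAN,
) -> tuple[pd.Series, pd.Series]:
    """Remove intensity-dependent bias between replicates by lowess in MA space.

    For the probesets shared by both replicates (with positive
    intensity), the log-ratio M = log2(rep1/rep2) is regressed on the
    log-average A = (log2 rep1 + log2 rep2)/2 and the fitted trend is
    subtracted symmetrically from both replicates, leaving A
    unchanged. Probesets present in only one table (or with
    non-positive intensity, which has no log) pass through unchanged.
    """
    s1, s2 = _as_series(rep1), _as_series(rep2)
    shared = s1.index.intersection(s2.index)
    usable = shared[(s1[shared] > 0) & (s2[shared] > 0)]
    if len(shared) < 10:
        raise ValueError(
            f"lowess smoothing requires >=10 shared probesets, got {len(shared)}"
        )
    if len(usable) < len(shared):
        log.warning(
            "smooth_replicates: %d shared probesets skipped (non-positive intensity)",
            len(shared) - len(usable),
        )
    x1 = np.log2(s1[usable].to_numpy())
    x2 = np.log2(s2[usable].to_numpy())
    m = x1 - x2
    a = 0.5 * (x1 + x2)
    trend = lowess(m, a, frac=span, it=1, return_sorted=False)
    m_corrected = m - trend
    out1, out2 = s1.copy(), s2.copy()
    out1[usable] = np.exp2(a + m_corrected / 2.0)
    out2[usable] = np.exp2(a - m_corrected / 2.0)
    return out1, out2


def average_replicates(
    rep1: Mapping[str, float], rep2: Mapping[str, float]
) -> pd.Series:
    """Equal-weight replicate merge: per-probeset mean, singletons pass through."""
    s1, s2 = _as_series(rep1), _as_series(rep2)
    only1 = s1.index.difference(s2.index)
    only2 = s2.index.difference(s1.index)
    if len(only1) or len(only2):
        log.warning(
            "average_replicates: %d probesets present in one replicate only",
            len(only1) + len(only2),
        )
    merged = pd.concat([s1, s2], axis=1).mean(axis=1, skipna=True)
    return merged


def gene_values_from_probesets(
    table: Mapping[str, float], probe_map: Mapping[str, str]
) -> Dict[str, float]:
    """Collapse probesets to genes by the maximum rule.

    ``probe_map`` maps probeset id to gene id (many-to-one and possibly
    incomplete). A gene's value is the maximum over its mapped
    probesets; genes with no measured probeset are absent from the
    result (downstream they are "no data", unpenalized).
    """
    s = _as_series(table)
    out: Dict[str, float] = {}
    for probe, value in s.items():
        gene = probe_map.get(probe)
        if gene is None:
            continue
        if gene not in out or value > out[gene]:
            out[gene] = float(value)
    return out


def reaction_scores(
    model: MetabolicModel, gene_values: Mapping[str, float]
) -> Dict[str, Optional[float]]:
    """Per-reaction expression score from GPR evaluation (min/and, max/or).

    Reactions with an EMPTY rule, or whose genes all lack data, score
    ``None``.
    """
    return {
        rxn.id: evaluate_gpr_expression(rxn.gpr, gene_values)
        for rxn in model.reactions
    }


def significance_threshold(values, p: float = 0.05) -> float:
    """Expression value separating significant from background expression.

    Fits a single Gaussian to the values by moments and assigns each
    value the upper-tail probability 1 - Phi((x - mu)/sigma). The
    returned threshold is the smallest observed value whose tail
    probability does not exceed ``p`` — i.e. the observed value with
    p-value closest to, but not exceeding, the target.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 30:
        raise ValueError(f"need >=30 values to fit the Gaussian, got {arr.size}")
    mu = float(arr.mean())
    sigma = float(arr.std())
    if sigma == 0 or not math.isfinite(sigma):
        raise ValueError("values have zero spread; cannot fit a Gaussian")
    tail_p = stats.norm.sf(arr, loc=mu, scale=sigma)
    eligible = arr[tail_p <= p]
    if eligible.size == 0:
        # no observed value reaches the tail; fall back to the largest value
        return float(arr.max())
    return float(eligible.min())


def build_profile(
    model: MetabolicModel,
    rep1: Mapping[str, float],
    rep2: Mapping[str, float],
    probe_map: Mapping[str, str],
    p: float = 0.05,
    span: float = DEFAULT_SPAN,
) -> ExpressionProfile:
    """Run the full probe-to-reaction pipeline and fit the threshold."""
    rep2n = global_normalize(rep1, rep2)
    rep1s, rep2s = smooth_replicates(rep1, rep2n, span=span)
    merged = average_replicates(rep1s, rep2s)
    gene_values = gene_values_from_probesets(merged, probe_map)
    scores = reaction_scores(model, gene_values)
    threshold = significance_threshold(gene_values.values(), p=p)
    return ExpressionProfile(
        gene_values=gene_values,
        reaction_scores=scores,
        threshold=threshold,
        threshold_p=p,
    )


def read_probe_table(path) -> pd.Series:
    """TSV with columns probeset_id, intensity."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(
        df["intensity"].to_numpy(dtype=float), index=df["probeset_id"].astype(str)
    )


def read_probe_map(path) -> Dict[str, str]:
    """TSV with columns probeset_id, gene_id."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["probeset_id"].astype(str), df["gene_id"].astype(str)))
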
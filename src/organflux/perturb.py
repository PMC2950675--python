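"""Drug off-target and gene-deficiency simulation.

Phenotypes are expressed as flux-capacity ratios: for a perturbation
(gene deletion, drug-target inhibition, or both) and an objective
component, the ratio of the perturbed maximum component flux to the
matched unperturbed maximum, in [0, 1]. A ratio below one marks a
disorder phenotype; a gene whose deletion is silent untreated but
drops the ratio below one under drug treatment is a cryptic genetic
risk factor.

Simulation conventions follow the organ-model construction: secretion
components maximize their efflux under standing bounds; reabsorption
components unbound their own uptake and cap every other allowed uptake
at the system boundary flux constraint (sbfc), so direct and indirect
reabsorption routes can run concurrently in one optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .context import ObjectiveComponent
from .fba import LinearSystem, apply_inhibition, maximize_flux
from .gpr import evaluate_gpr_knockout
from .model import VMAX, MetabolicModel

__all__ = [
    "SimulationConfig",
    "TargetMap",
    "PerturbationMatrix",
    "SensitivityCurve",
    "simulate_component",
    "scan_gene_deletions",
    "scan_drug_targets",
    "find_cryptic_risk_factors",
    "sensitivity_sweep",
]

log = logging.getLogger(__name__)

RATIO_TOL = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable simulation parameters.

    * ``sbfc`` — system boundary flux constraint, the common cap on
      non-optimized uptakes during reabsorption simulation (and on
      allowed effluxes at model build time); base value 13.5 flux units.
    * ``inhibition_fraction`` — remaining fraction of capacity for
      drug-inhibited reactions; 0 is full inhibition.
    * ``disorder_threshold`` — ratio below which a phenotype is called
      a disorder (default 1: any loss of capacity).
    * ``vmax`` — maximum flux magnitude.
    """

    sbfc: float = 13.5
    inhibition_fraction: float = 0.0
    disorder_threshold: float = 1.0
    vmax: float = VMAX

    def __post_init__(self) -> None:
        if not 0.0 <= self.sbfc <= self.vmax:
            raise ValueError(f"sbfc must lie in [0, {self.vmax}]")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        if not 0.0 <= self.disorder_threshold <= 1.0 + RATIO_TOL:
            raise ValueError("disorder_threshold must lie in [0, 1]")


@dataclass
class TargetMap:
    """Drug-target map: target id -> genes and/or reactions it inactivates."""

    targets: Dict[str, Dict[str, set]] = field(default_factory=dict)

    def add(self, target_id: str, genes: Iterable[str] = (), reactions: Iterable[str] = ()) -> None:
        entry = self.targets.setdefault(target_id, {"genes": set(), "reactions": set()})
        entry["genes"] |= set(genes)
        entry["reactions"] |= set(reactions)

    def target_ids(self) -> List[str]:
        return sorted(self.targets)

    def validate(self, model: MetabolicModel) -> None:
        model_genes = model.genes()
        for tid, entry in self.targets.items():
            for g in entry["genes"]:
                if g not in model_genes:
                    raise ValueError(f"target {tid}: gene {g!r} not in any model GPR")
            for r in entry["reactions"]:
                if not model.has_reaction(r):
                    raise ValueError(f"target {tid}: reaction {r!r} not in model")

    def reactions_hit(self, model: MetabolicModel, target_ids: Iterable[str]) -> set[str]:
        """Reactions inactivated by the listed targets.

        Explicitly mapped reactions plus every reaction whose GPR fails
        once the targets' genes are removed.
        """
        genes: set[str] = set()
        rids: set[str] = set()
        for tid in target_ids:
            entry = self.targets[tid]
            genes |= entry["genes"]
            rids |= entry["reactions"]
        if genes:
            for rxn in model.reactions:
                if not rxn.gpr.is_empty and not evaluate_gpr_knockout(rxn.gpr, genes):
                    rids.add(rxn.id)
        return rids

    @classmethod
    def from_tsv(cls, path) -> "TargetMap":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        tm = cls()
        for _, row in df.iterrows():
            genes = [row["gene_id"]] if row.get("gene_id") else []
            rxns = [row["reaction_id"]] if row.get("reaction_id") else []
            tm.add(str(row["target_id"]), genes, rxns)
        return tm

    def to_tsv(self, path) -> None:
        rows = []
        for tid in self.target_ids():
            entry = self.targets[tid]
            for g in sorted(entry["genes"]):
                rows.append({"target_id": tid, "gene_id": g, "reaction_id": ""})
            for r in sorted(entry["reactions"]):
                rows.append({"target_id": tid, "gene_id": "", "reaction_id": r})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PerturbationMatrix:
    """(perturbation x component) grid of flux-capacity ratios in [0, 1].

    ``context`` records the treatment background ("untreated" or
    "drug-treated") and ``denominators`` the matched unperturbed
    optimum per component.
    """

    data: pd.DataFrame
    context: str = "untreated"
    denominators: Dict[str, float] = field(default_factory=dict)

    @property
    def perturbations(self) -> List[str]:
        return list(self.data.index)

    @property
    def components(self) -> List[str]:
        return list(self.data.columns)

    def ratio(self, perturbation: str, component: str) -> float:
        return float(self.data.loc[perturbation, component])

    def values_pool(self) -> np.ndarray:
        return self.data.to_numpy().ravel()

    def disorder_calls(self, threshold: float = 1.0, tol: float = RATIO_TOL) -> List[Tuple[str, str]]:
        """(perturbation, component) pairs whose ratio falls below the threshold."""
        out = []
        for p in self.data.index:
            for c in self.data.columns:
                if self.data.loc[p, c] < threshold - tol:
                    out.append((p, c))
        return out

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: perturbation, component, context, ratio."""
        long = self.data.reset_index(names="perturbation").melt(
            id_vars="perturbation", var_name="component", value_name="ratio"
        )
        long["context"] = self.context
        return long[["perturbation", "component", "context", "ratio"]]

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _clip_ratio(perturbed: float, reference: float) -> float:
    """Perturbed-to-reference capacity ratio; 0/0 counts as no additional disorder."""
    if reference <= RATIO_TOL:
        return 1.0
    r = perturbed / reference
    if r > 1.0 + RATIO_TOL:
        log.warning("ratio %g exceeds 1 beyond tolerance; clipping", r)
    return min(max(r, 0.0), 1.0) + 0.0  # + 0.0 normalizes -0.0


def simulate_component(
    model: MetabolicModel,
    component: ObjectiveComponent,
    config: SimulationConfig = SimulationConfig(),
) -> float:
    """Maximum flux of one objective component under the simulation protocol.

    Secretion: maximize the component's efflux with standing bounds.
    Reabsorption: raise the component's own uptake bound to Vmax, cap
    every other allowed uptake at ``config.sbfc``, then maximize the
    component's demand sink. Infeasible models score 0 (a dead model
    secretes nothing).
    """
    if not model.has_reaction(component.boundary_reaction_id):
        raise KeyError(
            f"component {component.id}: boundary reaction "
            f"{component.boundary_reaction_id!r} missing from model"
        )
    work = model
    if component.direction == "reabsorption":
        work = model.copy()
        for rxn in work.reactions:
            if rxn.kind == "exchange" and rxn.lower_bound < 0:
                rxn.lower_bound = -config.sbfc
        if component.uptake_reaction_id and work.has_reaction(component.uptake_reaction_id):
            up = work.reaction(component.uptake_reaction_id)
            up.lower_bound = -config.vmax
    state = maximize_flux(work, component.boundary_reaction_id)
    if not state.optimal or state.objective_value is None:
        return 0.0
    return max(state.objective_value, 0.0) + 0.0


def _baseline(
    model: MetabolicModel,
    components: Sequence[ObjectiveComponent],
    config: SimulationConfig,
) -> Dict[str, float]:
    return {c.id: simulate_component(model, c, config) for c in components}


def scan_gene_deletions(
    model: MetabolicModel,
    genes: Iterable[str],
    components: Sequence[ObjectiveComponent],
    config: SimulationConfig = SimulationConfig(),
    treatment: Optional[TargetMap] = None,
    treatment_targets: Optional[Iterable[str]] = None,
) -> PerturbationMatrix:
    """Single-gene deletion scan against each objective component.

    With a ``treatment`` target map, the drug inhibitions are applied
    to both the perturbed and the reference model (the matched
    drug-treated context); ratios then measure the gene's effect *on
    top of* the treatment.
    """
    from .fba import apply_gene_knockout

    context_model = model
    context = "untreated"
    if treatment is not None:
        tids = list(treatment_targets) if treatment_targets is not None else treatment.target_ids()
        hit = treatment.reactions_hit(model, tids)
        context_model = apply_inhibition(model, hit, config.inhibition_fraction)
        context = "drug-treated"
    base = _baseline(context_model, components, config)

    rows = {}
    for gene in genes:
        km = apply_gene_knockout(context_model, {gene})
        rows[gene] = {
            c.id: _clip_ratio(simulate_component(km, c, config), base[c.id])
            for c in components
        }
    data = pd.DataFrame.from_dict(rows, orient="index", columns=[c.id for c in components])
    return PerturbationMatrix(data=data, context=context, denominators=base)


def scan_drug_targets(
    model: MetabolicModel,
    targets: TargetMap,
    components: Sequence[ObjectiveComponent],
    config: SimulationConfig = SimulationConfig(),
) -> PerturbationMatrix:
    """Per-target inhibition scan plus the cumulative ALL-targets row.

    Each target's reactions are scaled to ``config.inhibition_fraction``
    of their capacity (0 = full inhibition); ratios are against the
    untreated normal model.
    """
    targets.validate(model)
    base = _baseline(model, components, config)
    rows = {}
    tids = targets.target_ids()
    for tid in tids:
        hit = targets.reactions_hit(model, [tid])
        pm = apply_inhibition(model, hit, config.inhibition_fraction)
        rows[tid] = {
            c.id: _clip_ratio(simulate_component(pm, c, config), base[c.id])
            for c in components
        }
    hit_all = targets.reactions_hit(model, tids)
    pm = apply_inhibition(model, hit_all, config.inhibition_fraction)
    rows["ALL"] = {
        c.id: _clip_ratio(simulate_component(pm, c, config), base[c.id])
        for c in components
    }
    data = pd.DataFrame.from_dict(rows, orient="index", columns=[c.id for c in components])
    return PerturbationMatrix(data=data, context="untreated", denominators=base)


def find_cryptic_risk_factors(
    untreated: PerturbationMatrix,
    treated: PerturbationMatrix,
    tol: float = RATIO_TOL,
) -> List[Tuple[str, str]]:
    """Gene-component pairs silent untreated but deficient under treatment.

    Returns pairs whose untreated ratio is one (within ``tol``) while
    the drug-treated ratio falls below one: deficiencies that manifest
    only in combination with the drug.
    """
    if untreated.perturbations != treated.perturbations or (
        untreated.components != treated.components
    ):
        raise ValueError("matrices must share identical perturbation/component axes")
    out = []
    for p in untreated.perturbations:
        for c in untreated.components:
            if untreated.ratio(p, c) >= 1.0 - tol and treated.ratio(p, c) < 1.0 - tol:
                out.append((p, c))
    return out


# --------------------------------------------------------------------------
# parameter sensitivity
# --------------------------------------------------------------------------


@dataclass
class SensitivityCurve:
    """Normalized sensitivity of one (perturbation, component) ratio.

    ``nsc[i] = (ratio[i] - ratio_base) / max(ratio_base, 1 - ratio_base)``,
    the deviation from the base-case ratio over the largest deviation
    the [0, 1] outcome range allows; bounded in [-1, 1] and zero at the
    base grid point.
    """

    perturbation: str
    component: str
    parameter: str
    grid: List[float]
    ratios: List[float]
    base_value: float

    @property
    def base_ratio(self) -> float:
        i = min(range(len(self.grid)), key=lambda k: abs(self.grid[k] - self.base_value))
        return self.ratios[i]

    @property
    def nsc(self) -> List[float]:
        rb = self.base_ratio
        denom = max(rb, 1.0 - rb)
        if denom <= 0:
            return [0.0 for _ in self.ratios]
        return [(r - rb) / denom for r in self.ratios]


def _apply_sbfc(model: MetabolicModel, sbfc: float) -> MetabolicModel:
    """Re-cap every allowed efflux at a new system boundary flux constraint."""
    out = model.copy()
    for rxn in out.reactions:
        if rxn.kind == "exchange" and rxn.upper_bound > 0:
            rxn.upper_bound = sbfc
            rxn.lower_bound = min(rxn.lower_bound, sbfc)
    return out


@dataclass(frozen=True)
class Perturbation:
    """A named perturbation: genes deleted and/or reactions inhibited."""

    id: str
    genes: frozenset = frozenset()
    reactions: frozenset = frozenset()


DEFAULT_SBFC_GRID = (0.0, 13.5, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)
DEFAULT_FRACTION_GRID = tuple(round(0.1 * i, 1) for i in range(11))


def sensitivity_sweep(
    model: MetabolicModel,
    perturbations: Sequence[Perturbation],
    components: Sequence[ObjectiveComponent],
    parameter: str,
    grid: Sequence[float],
    base_config: SimulationConfig = SimulationConfig(),
) -> List[SensitivityCurve]:
    """Recompute phenotype ratios across a parameter grid.

    ``parameter`` is ``"sbfc"`` or ``"inhibition_fraction"``; the base
    configuration's value for it must be a grid point (the base case
    anchors the normalized sensitivity coefficient at zero).
    """
    from .fba import apply_gene_knockout

    if parameter not in ("sbfc", "inhibition_fraction"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    base_value = getattr(base_config, parameter)
    grid = list(grid)
    if not any(abs(g - base_value) < 1e-12 for g in grid):
        raise ValueError(
            f"base {parameter} value {base_value} must be a grid point"
        )

    ratios: Dict[Tuple[str, str], List[float]] = {
        (p.id, c.id): [] for p in perturbations for c in components
    }
    for value in grid:
        if parameter == "sbfc":
            cfg = replace(base_config, sbfc=value)
            ref_model = _apply_sbfc(model, value)
        else:
            cfg = replace(base_config, inhibition_fraction=value)
            ref_model = model
        base = _baseline(ref_model, components, cfg)
        for p in perturbations:
            pm = ref_model
            if p.reactions:
                pm = apply_inhibition(pm, p.reactions, cfg.inhibition_fraction)
            if p.genes:
                pm = apply_gene_knockout(pm, p.genes)
            for c in components:
                r = _clip_ratio(simulate_component(pm, c, cfg), base[c.id])
                ratios[(p.id, c.id)].append(r)

    return [
        SensitivityCurve(
            perturbation=p.id,
            component=c.id,
            parameter=parameter,
            grid=list(grid),
            ratios=ratios[(p.id, c.id)],
            base_value=base_value,
        )
        for p in perturbations
        for c in components
    ]
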
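"""Context-specific model construction.

Four stages turn a base network plus organ evidence into a functional
organ model:

1. :func:`derive_exchange_bounds` — metabolite-detection evidence
   (blood / urine / tissue flags plus curated overrides) decides which
   boundary exchanges may carry uptake and/or efflux; all allowed
   effluxes share one cap, the system boundary flux constraint (sbfc).
2. :func:`assemble_objective` — the curated secretion/reabsorption
   components (optionally plus ATP maintenance) are combined into a
   single objective reaction, with per-component boundary reactions so
   individual functions can be simulated one at a time; components the
   unconstrained network cannot support are reported and excluded.
3. :func:`run_gimme` — the GIMME linear program finds a flux state
   that attains at least a required fraction of the objective optimum
   while minimizing flux through reactions expressed below the
   significance threshold, and classifies each reaction's activity.
4. :func:`reduce_model` — flux variability under per-component anchors
   isolates the connected sub-network of reactions that can possibly
   support any objective component, preserving every component's
   optimum exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .fba import FLUX_TOL, TOL_BAL, FBAError, LinearSystem, flux_variability, maximize_flux
from .model import VMAX, MetabolicModel, Metabolite, ModelError, Reaction

__all__ = [
    "EvidenceFlags",
    "EvidenceTable",
    "ObjectiveComponent",
    "ObjectiveSpec",
    "ObjectiveAssembly",
    "GimmeResult",
    "GimmeError",
    "derive_exchange_bounds",
    "apply_exchange_bounds",
    "assemble_objective",
    "run_gimme",
    "constrain_by_activity",
    "reduce_model",
    "DEFAULT_SBFC",
]

log = logging.getLogger(__name__)

#: default system boundary flux constraint (flux units)
DEFAULT_SBFC = 13.5

ATP_MAINTENANCE = {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0}


@dataclass(frozen=True)
class EvidenceFlags:
    detected_blood: bool = False
    detected_urine: bool = False
    detected_tissue: bool = False
    curated_free_exchange: bool = False
    curated_secretion_objective: bool = False
    curated_uptake_forbidden: bool = False


@dataclass
class EvidenceTable:
    """Metabolite-detection evidence keyed by exchange-metabolite id."""

    flags: Dict[str, EvidenceFlags] = field(default_factory=dict)

    def get(self, met_id: str) -> EvidenceFlags:
        return self.flags.get(met_id, EvidenceFlags())

    @classmethod
    def from_tsv(cls, path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t")
        cols = [
            "detected_blood",
            "detected_urine",
            "detected_tissue",
            "curated_free_exchange",
            "curated_secretion_objective",
            "curated_uptake_forbidden",
        ]
        flags = {}
        for _, row in df.iterrows():
            flags[str(row["metabolite_id"])] = EvidenceFlags(
                **{c: bool(row[c]) if c in df.columns else False for c in cols}
            )
        return cls(flags=flags)

    def to_tsv(self, path) -> None:
        rows = []
        for met, f in sorted(self.flags.items()):
            rows.append(
                {
                    "metabolite_id": met,
                    "detected_blood": int(f.detected_blood),
                    "detected_urine": int(f.detected_urine),
                    "detected_tissue": int(f.detected_tissue),
                    "curated_free_exchange": int(f.curated_free_exchange),
                    "curated_secretion_objective": int(f.curated_secretion_objective),
                    "curated_uptake_forbidden": int(f.curated_uptake_forbidden),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class ExchangeBound(NamedTuple):
    lower: float
    upper: float
    rule: str


def derive_exchange_bounds(
    model: MetabolicModel,
    evidence: EvidenceTable,
    sbfc: float = DEFAULT_SBFC,
) -> Dict[str, ExchangeBound]:
    """Evidence-driven bounds for every exchange reaction.

    Rules, in order of application:

    * detected in blood and tissue, or curated freely exchangeable —
      uptake allowed (lb = -Vmax) and efflux allowed;
    * detected in urine and tissue only — efflux only;
    * no supporting evidence — closed, [0, 0];
    * secretion-objective metabolites (and curated uptake-forbidden
      ones) never take up, regardless of other evidence — the model
      must synthesize what it secretes;
    * every allowed efflux is capped at the system boundary flux
      constraint ``sbfc`` so all candidate pathways can operate
      concurrently.

    Evidence rows naming metabolites without an exchange are warned
    about and skipped.
    """
    if not 0.0 <= sbfc <= VMAX:
        raise ValueError(f"sbfc must lie in [0, {VMAX}], got {sbfc}")
    exchange_mets = {
        next(iter(r.stoichiometry)): r.id for r in model.exchanges()
    }
    for met in evidence.flags:
        if met not in exchange_mets:
            log.warning("evidence for %s ignored: no exchange reaction", met)

    bounds: Dict[str, ExchangeBound] = {}
    for met_id, rid in exchange_mets.items():
        f = evidence.get(met_id)
        if f.curated_free_exchange or (f.detected_blood and f.detected_tissue):
            lb, ub = -VMAX, sbfc
            rule = "curated_free_exchange" if f.curated_free_exchange else "blood_and_tissue"
        elif f.detected_urine and f.detected_tissue:
            lb, ub = 0.0, sbfc
            rule = "urine_and_tissue"
        else:
            lb, ub = 0.0, 0.0
            rule = "no_evidence"
        if f.curated_secretion_objective or f.curated_uptake_forbidden:
            lb = max(lb, 0.0)
            ub = max(ub, sbfc) if f.curated_secretion_objective else ub
            rule += "+uptake_forbidden"
        bounds[rid] = ExchangeBound(lb, ub, rule)
    return bounds


def apply_exchange_bounds(
    model: MetabolicModel, bounds: Mapping[str, ExchangeBound]
) -> MetabolicModel:
    out = model.copy()
    for rid, b in bounds.items():
        rxn = out.reaction(rid)
        rxn.lower_bound = b.lower
        rxn.upper_bound = b.upper
    return out


# --------------------------------------------------------------------------
# objective assembly
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectiveComponent:
    """One organ function: secretion or reabsorption of a metabolite.

    ``boundary_reaction_id`` is the reaction maximized when this
    function is simulated alone (an efflux exchange for secretion, a
    demand sink for reabsorption); ``uptake_reaction_id`` is the blood
    exchange whose uptake is unbounded during reabsorption simulation.
    """

    id: str
    metabolite_id: str
    direction: str  # "secretion" | "reabsorption"
    boundary_reaction_id: str
    uptake_reaction_id: Optional[str] = None
    weight: float = 1.0


@dataclass
class ObjectiveSpec:
    """Curated list of secretion/reabsorption functions plus ATP maintenance."""

    components: List[Tuple[str, str]]  # (metabolite id, direction)
    include_atp_maintenance: bool = False
    weights: Dict[str, float] = field(default_factory=dict)
    atp_metabolites: Dict[str, str] = field(default_factory=dict)
    #: reabsorption metabolite -> blood exchange reaction whose uptake is
    #: unbounded during that component's simulation (default EX_<met>)
    uptake_reactions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("objective spec requires at least one component")
        for met, direction in self.components:
            if direction not in ("secretion", "reabsorption"):
                raise ValueError(f"component {met}: bad direction {direction!r}")
            if self.weights.get(met, 1.0) <= 0:
                raise ValueError(f"component {met}: weight must be positive")


@dataclass
class ObjectiveAssembly:
    """Result of wiring an objective spec into a model."""

    model: MetabolicModel
    combined_reaction_id: str
    components: List[ObjectiveComponent]
    incompatible: List[Tuple[str, str]]  # (metabolite, direction) with zero flux


def _unconstrained_copy(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for rxn in out.reactions:
        rxn.upper_bound = VMAX
        if rxn.kind == "exchange":
            rxn.lower_bound = -VMAX
        elif rxn.reversible:
            rxn.lower_bound = -VMAX
        else:
            rxn.lower_bound = 0.0
    return out


def assemble_objective(
    model: MetabolicModel, spec: ObjectiveSpec
) -> ObjectiveAssembly:
    """Add per-component boundary reactions and one combined objective reaction.

    Every component is first tested for compatibility: its boundary
    flux is maximized in the fully unconstrained network, and
    components that cannot carry positive flux are reported as
    incompatible and left out of the combined reaction. The combined
    reaction consumes each compatible component's metabolite with its
    weight (default one), plus an ATP hydrolysis maintenance term when
    requested.
    """
    out = model.copy()
    components: List[ObjectiveComponent] = []
    for met_id, direction in spec.components:
        if not out.has_metabolite(met_id):
            raise ModelError(f"objective component {met_id!r}: metabolite not in model")
        if direction == "secretion":
            rid = f"EX_{met_id}"
            if not out.has_reaction(rid):
                rid = f"DM_{met_id}"
                if not out.has_reaction(rid):
                    out.add_boundary_reaction(met_id, "demand", 0.0, VMAX)
            uptake = None
        else:
            rid = f"DM_{met_id}"
            if not out.has_reaction(rid):
                out.add_boundary_reaction(met_id, "demand", 0.0, VMAX)
            uptake = spec.uptake_reactions.get(met_id)
            if uptake is None:
                ex = f"EX_{met_id}"
                if out.has_reaction(ex):
                    uptake = ex
            elif not out.has_reaction(uptake):
                raise ModelError(
                    f"component {met_id}: uptake reaction {uptake!r} not in model"
                )
        components.append(
            ObjectiveComponent(
                id=f"{met_id}_{direction}",
                metabolite_id=met_id,
                direction=direction,
                boundary_reaction_id=rid,
                uptake_reaction_id=uptake,
                weight=spec.weights.get(met_id, 1.0),
            )
        )

    # compatibility: positive flux attainable in the fully unconstrained network
    probe = _unconstrained_copy(out)
    system = LinearSystem(probe)
    compatible: List[ObjectiveComponent] = []
    incompatible: List[Tuple[str, str]] = []
    for comp in components:
        state = maximize_flux(probe, comp.boundary_reaction_id, system=system)
        if state.optimal and state.objective_value > TOL_BAL:
            compatible.append(comp)
        else:
            incompatible.append((comp.metabolite_id, comp.direction))
            log.warning(
                "objective component %s (%s) incompatible with the network; excluded",
                comp.metabolite_id,
                comp.direction,
            )

    stoich: Dict[str, float] = {}
    for comp in compatible:
        stoich[comp.metabolite_id] = stoich.get(comp.metabolite_id, 0.0) - comp.weight
    if spec.include_atp_maintenance:
        name_map = spec.atp_metabolites or {k: f"{k}_c" for k in ATP_MAINTENANCE}
        for key, coef in ATP_MAINTENANCE.items():
            met = name_map[key]
            if not out.has_metabolite(met):
                raise ModelError(f"ATP maintenance metabolite {met!r} not in model")
            stoich[met] = stoich.get(met, 0.0) + coef
    if not stoich:
        raise ModelError("no objective component is compatible with the network")
    combined = Reaction(
        id="combined_objective",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=VMAX,
        kind="objective",
        subsystem="objective",
    )
    out.add_reaction(combined)
    return ObjectiveAssembly(
        model=out,
        combined_reaction_id=combined.id,
        components=compatible,
        incompatible=incompatible,
    )


# --------------------------------------------------------------------------
# GIMME
# --------------------------------------------------------------------------


class GimmeError(FBAError):
    pass


@dataclass
class GimmeResult:
    """Activity classification from the GIMME linear program.

    ``activity`` maps every reaction to ``"active"``, ``"inactive"``
    or ``"unpenalized-active"`` (no expression evidence, kept without
    penalty). ``inconsistency_score`` is the minimized total penalized
    flux.
    """

    activity: Dict[str, str]
    inconsistency_score: float
    required_fraction: float
    objective_max: float
    threshold: float
    weights: Dict[str, float] = field(default_factory=dict)

    def inactive_reactions(self) -> set[str]:
        return {r for r, a in self.activity.items() if a == "inactive"}

    def active_reactions(self) -> set[str]:
        return {r for r, a in self.activity.items() if a != "inactive"}

    def to_table(self, scores: Optional[Mapping[str, Optional[float]]] = None) -> pd.DataFrame:
        rows = []
        for rid in sorted(self.activity):
            rows.append(
                {
                    "reaction": rid,
                    "score": None if scores is None else scores.get(rid),
                    "weight": self.weights.get(rid, 0.0),
                    "class": self.activity[rid],
                }
            )
        return pd.DataFrame(rows)


class _SplitLP:
    """Reversible-split LP over a model: v_j = f_j - r_j with f, r >= 0."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = model.reaction_ids()
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        cols = []
        self.var_of: Dict[str, list[int]] = {}
        var_lb, var_ub, signs = [], [], []
        col_blocks = []
        k = 0
        for j, rid in enumerate(self.rxn_ids):
            col = S.getcol(j)
            if lb[j] < 0:
                # forward half
                col_blocks.append(col)
                var_lb.append(0.0)
                var_ub.append(max(ub[j], 0.0))
                signs.append(1.0)
                # reverse half
                col_blocks.append(-col)
                var_lb.append(0.0)
                var_ub.append(-lb[j])
                signs.append(-1.0)
                self.var_of[rid] = [k, k + 1]
                k += 2
            else:
                col_blocks.append(col)
                var_lb.append(lb[j])
                var_ub.append(ub[j])
                signs.append(1.0)
                self.var_of[rid] = [k]
                k += 1
        self.A_eq = sparse.hstack(col_blocks, format="csr")
        self.lb = np.array(var_lb)
        self.ub = np.array(var_ub)
        self.signs = np.array(signs)
        self.n = k

    def net_flux_row(self, rid: str) -> np.ndarray:
        """Row vector expressing the net flux of a reaction."""
        row = np.zeros(self.n)
        idx = self.var_of[rid]
        row[idx[0]] = 1.0
        if len(idx) == 2:
            row[idx[1]] = -1.0
        return row

    def solve(self, c, A_ub=None, b_ub=None):
        return linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.A_eq,
            b_eq=np.zeros(self.A_eq.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
        )


def run_gimme(
    model: MetabolicModel,
    reaction_scores: Mapping[str, Optional[float]],
    threshold: float,
    objective_reaction: str,
    required_fraction: float = 0.90,
) -> GimmeResult:
    """GIMME: minimal below-threshold flux subject to objective attainment.

    Solves ``min sum_i w_i |v_i|`` with ``w_i = max(0, threshold -
    score_i)`` (unscored reactions are unpenalized), subject to
    S v = 0, the bounds, and ``v_obj >= required_fraction * v_obj_max``.
    Absolute values are handled by splitting reversible reactions into
    nonnegative halves.

    Classification probes alternative optima per penalized reaction:
    within an inconsistency budget of the minimum plus 1e-6, a
    below-threshold reaction that cannot carry any flux is
    ``inactive``; every other reaction is kept (``active``, or
    ``unpenalized-active`` when it has no expression evidence).
    """
    if not 0.0 < required_fraction <= 1.0:
        raise ValueError(f"required_fraction must lie in (0, 1], got {required_fraction}")
    base = maximize_flux(model, objective_reaction)
    if not base.optimal or base.objective_value is None or base.objective_value <= TOL_BAL:
        raise GimmeError(
            f"objective {objective_reaction} has no positive optimum; GIMME needs one"
        )
    fmax = base.objective_value
    required = required_fraction * fmax

    lp = _SplitLP(model)
    weights: Dict[str, float] = {}
    c = np.zeros(lp.n)
    for rid in lp.rxn_ids:
        score = reaction_scores.get(rid)
        w = 0.0 if score is None else max(0.0, threshold - score)
        if w > 0:
            weights[rid] = w
            for k in lp.var_of[rid]:
                c[k] += w

    obj_row = lp.net_flux_row(objective_reaction)
    A_ub = sparse.csr_matrix(-obj_row)
    b_ub = np.array([-required])
    res = lp.solve(c, A_ub=A_ub, b_ub=b_ub)
    if res.status != 0:
        raise GimmeError(
            f"GIMME LP infeasible: objective constraint v >= {required:g} cannot be met"
        )
    inconsistency = float(res.fun)

    # probe alternative optima per penalized reaction
    budget_row = sparse.csr_matrix(c)
    A_probe = sparse.vstack([A_ub, budget_row], format="csr")
    b_probe = np.array([-required, inconsistency + 1e-6])
    activity: Dict[str, str] = {}
    for rid in lp.rxn_ids:
        score = reaction_scores.get(rid)
        if rid not in weights:
            activity[rid] = "unpenalized-active" if score is None else "active"
            continue
        row = lp.net_flux_row(rid)
        hi = lp.solve(-row, A_ub=A_probe, b_ub=b_probe)
        vmax_r = -hi.fun if hi.status == 0 else 0.0
        if vmax_r > 1e-6:
            activity[rid] = "active"
            continue
        lo = lp.solve(row, A_ub=A_probe, b_ub=b_probe)
        vmin_r = lo.fun if lo.status == 0 else 0.0
        activity[rid] = "active" if vmin_r < -1e-6 else "inactive"

    return GimmeResult(
        activity=activity,
        inconsistency_score=inconsistency,
        required_fraction=required_fraction,
        objective_max=fmax,
        threshold=threshold,
        weights=weights,
    )


def constrain_by_activity(model: MetabolicModel, result: GimmeResult) -> MetabolicModel:
    """Copy of ``model`` with GIMME-inactive reactions closed to zero flux."""
    out = model.copy()
    for rid in result.inactive_reactions():
        rxn = out.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


# --------------------------------------------------------------------------
# reduction
# --------------------------------------------------------------------------


def reduce_model(
    model: MetabolicModel,
    components: Sequence[ObjectiveComponent],
    eps: float = 1e-6,
) -> MetabolicModel:
    """Connected functional sub-model supporting the objective components.

    For each component, its boundary flux is anchored at ``>= eps``
    and flux variability identifies every reaction that can carry flux
    while the component operates. The reduced model is the union of
    those reactions (plus their metabolites) across components, and
    preserves each component's optimum exactly: it contains all
    pathways that could possibly support the objectives.

    Components whose anchor is infeasible are logged and skipped.
    Disconnected islands in the reaction-metabolite graph trigger a
    warning but are retained.
    """
    system = LinearSystem(model)
    all_ids = model.reaction_ids()
    keep: set[str] = set()
    for comp in components:
        try:
            fva = flux_variability(
                model, all_ids, anchor=(comp.boundary_reaction_id, eps), system=system
            )
        except FBAError:
            log.warning(
                "component %s infeasible at anchor %g; skipped in reduction",
                comp.id,
                eps,
            )
            continue
        keep.add(comp.boundary_reaction_id)
        for rid, (lo, hi) in fva.items():
            if max(abs(lo), abs(hi)) > FLUX_TOL:
                keep.add(rid)

    reduced = MetabolicModel(id=f"{model.id}_reduced", compartments=set())
    kept_mets: set[str] = set()
    for rid in all_ids:
        if rid in keep:
            kept_mets |= set(model.reaction(rid).stoichiometry)
    for met in model.metabolites:
        if met.id in kept_mets:
            reduced.add_metabolite(met)
    for rid in all_ids:
        if rid in keep:
            reduced.add_reaction(model.reaction(rid).copy())

    _check_connected(reduced)
    return reduced


def _check_connected(model: MetabolicModel) -> None:
    g = nx.Graph()
    for rxn in model.reactions:
        g.add_node(("r", rxn.id))
        for met in rxn.stoichiometry:
            g.add_edge(("r", rxn.id), ("m", met))
    if g.number_of_nodes() and not nx.is_connected(g):
        n = nx.number_connected_components(g)
        log.warning("reduced model is not a single connected component (%d islands)", n)
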
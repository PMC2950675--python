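"""Flux balance analysis core.

All linear programs share one contract: minimize ``c @ v`` subject to
the steady-state mass balance ``S v = 0``, optional inequality rows,
and per-reaction flux bounds. The backend is scipy's HiGHS solver.

Only objective values are contractually deterministic; when the
optimum is degenerate the returned flux vector is one of the optimal
vertices and must not be relied on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .fba_types import FluxRange, FluxState  # noqa: F401  (re-export)
from .model import MetabolicModel

__all__ = [
    "FluxState",
    "FluxRange",
    "FBAError",
    "InfeasibleAnchorError",
    "LinearSystem",
    "maximize_flux",
    "flux_variability",
    "apply_gene_knockout",
    "apply_inhibition",
    "TOL_BAL",
    "FLUX_TOL",
]

#: mass-balance / bound tolerance
TOL_BAL = 1e-6
#: a flux is considered nonzero if its magnitude exceeds this
FLUX_TOL = 1e-9


class FBAError(RuntimeError):
    pass


class InfeasibleAnchorError(FBAError):
    """The required anchor flux cannot be attained."""


@dataclass
class LinearSystem:
    """Reusable LP description of a model: S v = 0 plus bounds.

    Building S dominates the cost of repeated small solves, so the
    system is constructed once per model and bounds are overridden per
    solve.
    """

    model: MetabolicModel
    S: sparse.csr_matrix = field(init=False)
    rxn_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.S = self.model.stoichiometric_matrix()
        self.rxn_ids = self.model.reaction_ids()
        self._index = {rid: j for j, rid in enumerate(self.rxn_ids)}
        lb, ub = self.model.bounds_arrays()
        self.lb = lb
        self.ub = ub

    def index(self, rxn_id: str) -> int:
        try:
            return self._index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def solve(
        self,
        c: np.ndarray,
        lb: Optional[np.ndarray] = None,
        ub: Optional[np.ndarray] = None,
        A_ub: Optional[sparse.spmatrix] = None,
        b_ub: Optional[np.ndarray] = None,
    ):
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        return res


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _state_from_result(res, rxn_ids: Sequence[str], sense: float) -> FluxState:
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxState(status=status, objective_value=None, fluxes={})
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxState(status="optimal", objective_value=sense * res.fun, fluxes=fluxes)


def maximize_flux(
    model: MetabolicModel,
    objective_reaction_id: str,
    system: Optional[LinearSystem] = None,
) -> FluxState:
    """Maximize the flux of one reaction under S v = 0 and the bounds.

    Returns a :class:`FluxState`; an infeasible model yields status
    ``"infeasible"`` with objective ``None``.
    """
    sys_ = system or LinearSystem(model)
    j = sys_.index(objective_reaction_id)
    c = np.zeros(len(sys_.rxn_ids))
    c[j] = -1.0
    res = sys_.solve(c)
    return _state_from_result(res, sys_.rxn_ids, sense=-1.0)


def flux_variability(
    model: MetabolicModel,
    reaction_ids: Iterable[str],
    anchor: Tuple[str, float],
    system: Optional[LinearSystem] = None,
) -> FluxRange:
    """Per-reaction min/max flux with a required anchor flux.

    ``anchor`` = (reaction id, minimum required flux); the anchor
    reaction's lower bound is raised to that value before the sweep.
    """
    sys_ = system or LinearSystem(model)
    anchor_id, anchor_flux = anchor
    ja = sys_.index(anchor_id)
    lb = sys_.lb.copy()
    if anchor_flux > sys_.ub[ja] + TOL_BAL:
        raise InfeasibleAnchorError(
            f"anchor {anchor_id}: required flux {anchor_flux} exceeds its upper bound"
        )
    lb[ja] = max(lb[ja], anchor_flux)

    # feasibility probe
    c0 = np.zeros(len(sys_.rxn_ids))
    if sys_.solve(c0, lb=lb).status != 0:
        raise InfeasibleAnchorError(
            f"anchor {anchor_id}: flux >= {anchor_flux} is infeasible"
        )

    ranges: Dict[str, Tuple[float, float]] = {}
    c = np.zeros(len(sys_.rxn_ids))
    for rid in reaction_ids:
        j = sys_.index(rid)
        c[j] = 1.0
        lo_res = sys_.solve(c, lb=lb)
        c[j] = -1.0
        hi_res = sys_.solve(c, lb=lb)
        c[j] = 0.0
        if lo_res.status != 0 or hi_res.status != 0:
            raise FBAError(f"flux variability failed for reaction {rid}")
        ranges[rid] = (lo_res.fun, -hi_res.fun)
    return FluxRange(ranges=ranges)


def apply_gene_knockout(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Copy of ``model`` with all reactions disabled whose GPR fails.

    A reaction fails when its boolean rule evaluates false with the
    given genes deleted; failed reactions get bounds [0, 0]. Unknown
    genes are harmless no-ops and EMPTY-GPR reactions always survive.
    """
    deleted = set(genes)
    out = model.copy()
    if not deleted:
        return out
    from .gpr import evaluate_gpr_knockout

    for rxn in out.reactions:
        if rxn.gpr.is_empty:
            continue
        if not evaluate_gpr_knockout(rxn.gpr, deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def apply_inhibition(
    model: MetabolicModel, reaction_ids: Iterable[str], remaining_fraction: float
) -> MetabolicModel:
    """Copy of ``model`` with listed reactions scaled to a fraction of capacity.

    Bounds become ``[f * lb, f * ub]``; ``f = 0`` is full inhibition
    (the default drug-effect model), ``f = 1`` is the identity.
    """
    if not 0.0 <= remaining_fraction <= 1.0:
        raise ValueError(
            f"remaining_fraction must lie in [0, 1], got {remaining_fraction}"
        )
    out = model.copy()
    for rid in reaction_ids:
        rxn = out.reaction(rid)  # KeyError on unknown ids
        rxn.lower_bound *= remaining_fraction
        rxn.upper_bound *= remaining_fraction
    return out
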
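"""Compartmentalized stoichiometric metabolic networks.

A :class:`MetabolicModel` is a list of metabolites (each living in a
compartment), a list of bounded reactions with signed stoichiometry and
a GPR rule, and the compartment set. The implied stoichiometric matrix
S (one row per metabolite, one column per reaction) feeds the linear
programming core.

Flux units are dimensionless, capped at ``VMAX`` = 1000 in magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import EMPTY_GPR, GPRTree, parse_gpr

__all__ = [
    "VMAX",
    "REACTION_KINDS",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelError",
]

#: default maximum flux magnitude (flux units)
VMAX = 1000.0

REACTION_KINDS = ("enzymatic", "transport", "exchange", "demand", "objective")

BOUNDARY_KINDS = ("exchange", "demand")


class ModelError(ValueError):
    """Structural problem in a model definition."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A bounded reaction with signed stoichiometry and a GPR rule.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed, positive = produced). Treat the dict as
    immutable once the reaction is inside a model; bounds are the only
    fields mutated by constraint application.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = VMAX
    gpr: GPRTree = EMPTY_GPR
    subsystem: str = ""
    kind: str = "enzymatic"

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        self.validate()

    def validate(self, vmax: float = VMAX) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not (
            math.isfinite(self.lower_bound) and math.isfinite(self.upper_bound)
        ):
            raise ModelError(f"reaction {self.id}: non-finite bounds")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if max(abs(self.lower_bound), abs(self.upper_bound)) > vmax + 1e-9:
            raise ModelError(
                f"reaction {self.id}: bounds exceed the maximum flux magnitude {vmax}"
            )
        if self.kind in BOUNDARY_KINDS and len(self.stoichiometry) != 1:
            raise ModelError(
                f"reaction {self.id}: {self.kind} reactions must touch exactly "
                f"one metabolite, got {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def formula(self) -> str:
        """Human-readable ``a + 2 b --> c`` style equation string."""

        def side(items: Iterable[tuple[str, float]]) -> str:
            parts = []
            for met, coef in items:
                coef = abs(coef)
                parts.append(met if coef == 1 else f"{coef:g} {met}")
            return " + ".join(parts)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<==>" if self.reversible else "-->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class MetabolicModel:
    """A compartmentalized stoichiometric network."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._met_index: Dict[str, int] = {}
        self._rxn_index: Dict[str, int] = {}
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # ---------------------------------------------------------------- access
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return out

    def boundary_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind in BOUNDARY_KINDS]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    # ------------------------------------------------------------- mutation
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1
        self.compartments.add(met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelError(
                    f"reaction {rxn.id}: references undeclared metabolite {met_id!r}"
                )
        rxn.validate()
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def add_boundary_reaction(
        self,
        met_id: str,
        kind: str,
        lower: float = 0.0,
        upper: float = VMAX,
    ) -> Reaction:
        """Add an exchange (``EX_<met>``) or demand (``DM_<met>``) reaction.

        Both are written as a single-metabolite drain (coefficient -1),
        so positive flux removes the metabolite from the system and
        negative flux (exchanges only) is uptake.
        """
        if kind not in BOUNDARY_KINDS:
            raise ModelError(f"boundary kind must be exchange or demand, got {kind!r}")
        self.metabolite(met_id)  # existence check
        prefix = "EX_" if kind == "exchange" else "DM_"
        rxn = Reaction(
            id=f"{prefix}{met_id}",
            stoichiometry={met_id: -1.0},
            lower_bound=lower,
            upper_bound=upper,
            kind=kind,
        )
        self.add_reaction(rxn)
        return rxn

    # ------------------------------------------------------------ integrity
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            raise ModelError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ModelError("duplicate reaction ids")
        declared = set(ids)
        for m in self.metabolites:
            self.compartments.add(m.compartment)
        for r in self.reactions:
            r.validate()
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ModelError(
                    f"reaction {r.id}: references undeclared metabolites {sorted(missing)}"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            compartments=set(self.compartments),
        )

    # -------------------------------------------------------------- algebra
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with one row per metabolite, one column per reaction."""
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    # ------------------------------------------------------------- tabular
    def to_table(self) -> pd.DataFrame:
        """One reaction per row: id, formula, bounds, gpr, subsystem, kind."""
        return pd.DataFrame(
            {
                "reaction_id": [r.id for r in self.reactions],
                "formula": [r.formula() for r in self.reactions],
                "lower_bound": [r.lower_bound for r in self.reactions],
                "upper_bound": [r.upper_bound for r in self.reactions],
                "gpr": [r.gpr.to_string() for r in self.reactions],
                "subsystem": [r.subsystem for r in self.reactions],
                "kind": [r.kind for r in self.reactions],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def infer_reaction_kind(rxn_id: str, stoichiometry: Mapping[str, float]) -> str:
    """Guess a reaction kind from id conventions and stoichiometry shape."""
    if len(stoichiometry) == 1:
        if rxn_id.startswith("DM_"):
            return "demand"
        return "exchange"
    if rxn_id.startswith(("T_", "TR_")):
        return "transport"
    return "enzymatic"


def empty_model(model_id: str, compartments: Optional[Iterable[str]] = None) -> MetabolicModel:
    return MetabolicModel(id=model_id, compartments=set(compartments or ()))
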
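"""Result containers for the linear-programming core."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

__all__ = ["FluxState", "FluxRange"]


@dataclass
class FluxState:
    """Outcome of one flux optimization.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    when optimal, ``fluxes`` satisfies S v = 0 and the bounds within
    the balance tolerance.
    """

    status: str
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction (min, max) attainable flux under stated constraints."""

    ranges: Dict[str, Tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()

    def can_carry_flux(self, rxn_id: str, tol: float = 1e-9) -> bool:
        lo, hi = self.ranges[rxn_id]
        return max(abs(lo), abs(hi)) > tol
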
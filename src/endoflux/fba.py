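"""Linear-program core: maximum growth of one metabolism and the viability
predicate.

The flux balance program for a metabolism in isolation is

    maximize  x[biomass]
    s.t.      a <= S x <= b        (compound derivative bounds)
              l <= x <= u         (reaction flux bounds)

solved here with HiGHS through scipy.  The binary viability call uses the
collections' conventional biological threshold of 0.001 on the growth rate,
which is deliberately far above the solver's numerical tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import Environment, MetabolicModel

#: Growth-rate threshold below which a metabolism is considered nonviable.
VIABILITY_TOLERANCE = 1e-3

#: Numerical feasibility/optimality tolerance of the LP backend; never
#: conflated with the biological viability threshold above.
SOLVER_TOLERANCE = 1e-9


class LPStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    FAILED = "failed"


@dataclass
class FluxSolution:
    """Outcome of one LP solve."""

    status: LPStatus
    objective: float
    fluxes: Optional[np.ndarray] = None
    message: str = ""

    @property
    def growth(self) -> float:
        """Objective as a growth rate; non-optimal statuses count as zero."""
        return self.objective if self.status is LPStatus.OPTIMAL else 0.0


@dataclass
class ViabilityReport:
    growth: float
    viable: bool
    tolerance: float = VIABILITY_TOLERANCE
    solver_failed: bool = False


def solve_lp(
    A: sparse.sparray,
    row_lower: np.ndarray,
    row_upper: np.ndarray,
    col_lower: np.ndarray,
    col_upper: np.ndarray,
    objective: np.ndarray,
) -> FluxSolution:
    """Maximize ``objective . x`` subject to two-sided row and box constraints.

    This is the solver abstraction contract: any backend accepting
    ``(A, row bounds, column bounds, objective)`` and returning a
    :class:`FluxSolution` is pluggable.  The default backend is HiGHS via
    :func:`scipy.optimize.milp` (with no integrality, i.e. a pure LP).
    """
    objective = np.asarray(objective, dtype=float)
    try:
        res = milp(
            c=-objective,
            constraints=LinearConstraint(A, row_lower, row_upper),
            bounds=Bounds(np.asarray(col_lower, float), np.asarray(col_upper, float)),
        )
    except Exception as exc:  # pragma: no cover - backend failure path
        return FluxSolution(LPStatus.FAILED, 0.0, None, message=str(exc))
    if res.status == 0:
        # +0.0 normalizes IEEE negative zero in reported optima
        return FluxSolution(LPStatus.OPTIMAL, float(-res.fun) + 0.0, np.asarray(res.x))
    if res.status == 2:
        return FluxSolution(LPStatus.INFEASIBLE, 0.0, None, message=res.message)
    if res.status == 3:
        free = [
            int(i)
            for i in np.nonzero(np.isinf(col_lower) | np.isinf(col_upper))[0]
        ]
        return FluxSolution(
            LPStatus.UNBOUNDED,
            float("inf"),
            None,
            message=f"unbounded; columns with infinite bounds: {free}",
        )
    return FluxSolution(LPStatus.FAILED, 0.0, None, message=res.message)


def _column_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([r.lower_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lo, hi


def maximize_growth(
    model: MetabolicModel, env: Optional[Environment] = None
) -> FluxSolution:
    """Maximum biomass flux of ``model`` in ``env`` (default: its own
    environment)."""
    row_lo, row_hi = model.row_bounds(env)
    col_lo, col_hi = _column_bounds(model)
    c = np.zeros(len(model.reactions))
    c[model.biomass_index] = 1.0
    return solve_lp(model.S, row_lo, row_hi, col_lo, col_hi, c)


def is_viable(
    model: MetabolicModel,
    env: Optional[Environment] = None,
    tolerance: float = VIABILITY_TOLERANCE,
) -> ViabilityReport:
    """Binary viability: growth at or above ``tolerance``.

    An infeasible LP counts as growth zero (nonviable); a solver failure is
    reported as nonviable with the failure flagged, never silently.
    """
    sol = maximize_growth(model, env)
    growth = sol.growth
    return ViabilityReport(
        growth=growth,
        viable=growth >= tolerance,
        tolerance=tolerance,
        solver_failed=sol.status is LPStatus.FAILED,
    )
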
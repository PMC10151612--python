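"""Competition between a host-endosymbiont pair and its ancestral
metabolisms: survival under single-compound environmental degradation,
pairwise growth-rate comparison, and the shared-environment community LP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .core import Compound, Environment, MetabolicModel, ModelError
from .endosymbiosis import EndosymbiosisModel, pair_is_viable
from .fba import (
    FluxSolution,
    LPStatus,
    VIABILITY_TOLERANCE,
    is_viable,
    solve_lp,
)

#: Relative tolerance for calling two growth rates equal.
GROWTH_EQUAL_RTOL = 1e-6

#: Two optima of one entity are "unique enough" when their spread is within
#: this fraction of the larger one.
UNIQUENESS_FRACTION = 0.10


class Scenario(str, Enum):
    """Joint survival outcome of (pair, ancestral host, ancestral endo)
    under one perturbation.  The eight classes partition the 2^3 boolean
    space: two unanimous outcomes and six mixed ones."""

    ALL_VIABLE = "all_viable"
    ALL_NONVIABLE = "all_nonviable"
    ONLY_PAIR_SURVIVES = "only_pair_survives"
    ONLY_HOST_SURVIVES = "only_host_survives"
    ONLY_ENDO_SURVIVES = "only_endo_survives"
    ONLY_PAIR_DIES = "only_pair_dies"
    ONLY_HOST_DIES = "only_host_dies"
    ONLY_ENDO_DIES = "only_endo_dies"


_SCENARIO_TABLE: Dict[Tuple[bool, bool, bool], Scenario] = {
    (True, True, True): Scenario.ALL_VIABLE,
    (False, False, False): Scenario.ALL_NONVIABLE,
    (True, False, False): Scenario.ONLY_PAIR_SURVIVES,
    (False, True, False): Scenario.ONLY_HOST_SURVIVES,
    (False, False, True): Scenario.ONLY_ENDO_SURVIVES,
    (False, True, True): Scenario.ONLY_PAIR_DIES,
    (True, False, True): Scenario.ONLY_HOST_DIES,
    (True, True, False): Scenario.ONLY_ENDO_DIES,
}


def classify_scenario(pair_viable: bool, host_viable: bool, endo_viable: bool) -> Scenario:
    """Total, exhaustive map from the viability triple to its scenario class."""
    return _SCENARIO_TABLE[(bool(pair_viable), bool(host_viable), bool(endo_viable))]


@dataclass
class PerturbationRecord:
    removed_compound: str
    pair_viable: bool
    host_viable: bool
    endo_viable: bool

    @property
    def scenario(self) -> Scenario:
        return classify_scenario(self.pair_viable, self.host_viable, self.endo_viable)


@dataclass
class RobustnessScore:
    metabolism_id: str
    survived: int
    total: int

    @property
    def proportion(self) -> float:
        return self.survived / self.total if self.total else 1.0


@dataclass
class RelativeFitness:
    """Growth advantage of a focal metabolism over a reference, both grown
    in the same environment: ``(focal - reference) / reference``."""

    focal: float
    reference: float
    advantage: Optional[float] = None
    classification: Optional[str] = None  # faster / slower / equal
    defined: bool = True


@dataclass
class CommunityGrowthResult:
    z: float
    entity_max: Dict[str, float]
    entity_min: Dict[str, float]
    unique: bool
    feasible: bool = True
    witnesses: Dict[str, np.ndarray] = field(default_factory=dict)
    objective: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Environmental perturbations
# ---------------------------------------------------------------------------


def enumerate_perturbations(env: Environment) -> List[str]:
    """Compounds whose removal is a distinct perturbation: every compound
    with nonzero uptake availability (``env_lower < 0``), each once."""
    return sorted(b for b, (a, _) in env.bounds.items() if a < 0.0)


def perturb(env: Environment, compound: str) -> Environment:
    """Remove one compound from the medium: its uptake bound goes to zero,
    secretion capacity is untouched.  Idempotent."""
    if compound not in env:
        raise ModelError(f"compound {compound!r} not present in the environment")
    bounds = dict(env.bounds)
    a, b = bounds[compound]
    bounds[compound] = (0.0, b)
    return Environment(bounds)


def survival_screen(
    pair: EndosymbiosisModel,
    host: MetabolicModel,
    endo: MetabolicModel,
    env: Optional[Environment] = None,
    tolerance: float = VIABILITY_TOLERANCE,
) -> Tuple[List[PerturbationRecord], Dict[str, RobustnessScore]]:
    """Single-compound knockout screen over the (joint) environment.

    For every removable compound the pair and both ancestors are re-tested
    for viability in the degraded environment; robustness is the proportion
    of perturbations each metabolism survives.  All three metabolisms must be
    viable in the unperturbed environment.
    """
    env = env if env is not None else pair.joint_env
    if not (
        pair_is_viable(pair, env, tolerance)
        and is_viable(host, env, tolerance).viable
        and is_viable(endo, env, tolerance).viable
    ):
        raise ModelError("survival_screen requires all three metabolisms viable "
                         "in the unperturbed environment")
    records: List[PerturbationRecord] = []
    for compound in enumerate_perturbations(env):
        degraded = perturb(env, compound)
        records.append(
            PerturbationRecord(
                removed_compound=compound,
                pair_viable=pair_is_viable(pair, degraded, tolerance),
                host_viable=is_viable(host, degraded, tolerance).viable,
                endo_viable=is_viable(endo, degraded, tolerance).viable,
            )
        )
    total = len(records)
    scores = {
        "pair": RobustnessScore("pair", sum(r.pair_viable for r in records), total),
        "host": RobustnessScore("host", sum(r.host_viable for r in records), total),
        "endo": RobustnessScore("endo", sum(r.endo_viable for r in records), total),
    }
    return records, scores


# ---------------------------------------------------------------------------
# Growth-rate competition
# ---------------------------------------------------------------------------


def pairwise_relative_fitness(
    pair_growth: float,
    ancestor_growth: float,
    tolerance: float = VIABILITY_TOLERANCE,
    rtol: float = GROWTH_EQUAL_RTOL,
) -> RelativeFitness:
    """Relative fitness of the pair against one ancestor, both computed in
    the same (joint) environment."""
    if ancestor_growth < tolerance:
        return RelativeFitness(
            focal=pair_growth, reference=ancestor_growth, defined=False
        )
    advantage = (pair_growth - ancestor_growth) / ancestor_growth
    if abs(advantage) <= rtol:
        cls = "equal"
    elif advantage > 0:
        cls = "faster"
    else:
        cls = "slower"
    return RelativeFitness(
        focal=pair_growth,
        reference=ancestor_growth,
        advantage=advantage,
        classification=cls,
    )


class _CommunityLP:
    """Shared-environment LP over three entities: ancestral host, ancestral
    endosymbiont, and the host-endosymbiont pair.

    Each entity keeps a private copy of every internal (c/p) row; the
    extracellular rows are pooled, so the summed consumption of all three
    entities is bounded by the shared environment.  The pair block retains
    its internal structure including the equal-growth coupling.
    """

    def __init__(
        self,
        host: MetabolicModel,
        endo: MetabolicModel,
        pair: EndosymbiosisModel,
        shared_env: Environment,
    ):
        if not (host.compounds == endo.compounds == pair.host.compounds):
            raise ModelError("community entities must share a harmonized namespace")
        ns = host.compounds
        self.shared_env = shared_env
        e_idx = [i for i, c in enumerate(ns) if c.compartment == "e"]
        int_idx = [i for i, c in enumerate(ns) if c.compartment in ("c", "p")]
        self._e_pos = {ns_i: g for g, ns_i in enumerate(e_idx)}
        n_e, n_int = len(e_idx), len(int_idx)
        int_pos = {ns_i: g for g, ns_i in enumerate(int_idx)}

        n_pair_cols = pair.A.shape[1]
        self.n_cols = len(host.reactions) + len(endo.reactions) + n_pair_cols
        self.col_offsets = {
            "host": 0,
            "endo": len(host.reactions),
            "pair": len(host.reactions) + len(endo.reactions),
        }
        # global rows: shared e | host internal | endo internal | pair internal
        # (+ pair endo-private, orphans, equal-growth)
        pair_internal_rows = pair.A.shape[0] - len(ns)
        self.n_rows = n_e + 2 * n_int + n_int + pair_internal_rows
        off_host = n_e
        off_endo = n_e + n_int
        off_pair = n_e + 2 * n_int

        rows, cols, vals = [], [], []

        def add_solo(model: MetabolicModel, col0: int, int_off: int) -> None:
            S = sparse.coo_array(model.S)
            for r, c_, v in zip(S.row, S.col, S.data):
                g = self._e_pos[r] if r in self._e_pos else int_off + int_pos[r]
                rows.append(g)
                cols.append(col0 + c_)
                vals.append(v)

        add_solo(host, self.col_offsets["host"], off_host)
        add_solo(endo, self.col_offsets["endo"], off_endo)

        P = sparse.coo_array(pair.A)
        for r, c_, v in zip(P.row, P.col, P.data):
            if r < len(ns):
                g = self._e_pos[r] if r in self._e_pos else off_pair + int_pos[r]
            else:
                g = off_pair + n_int + (r - len(ns))
            rows.append(g)
            cols.append(self.col_offsets["pair"] + c_)
            vals.append(v)

        self.A = sparse.csc_array(
            (vals, (rows, cols)), shape=(self.n_rows, self.n_cols)
        )

        self.row_lo = np.zeros(self.n_rows)
        self.row_hi = np.zeros(self.n_rows)
        for ns_i, g in self._e_pos.items():
            self.row_lo[g], self.row_hi[g] = shared_env.get(ns[ns_i].base_id)

        h_lo = np.array([r.lower_bound for r in host.reactions])
        h_hi = np.array([r.upper_bound for r in host.reactions])
        e_lo = np.array([r.lower_bound for r in endo.reactions])
        e_hi = np.array([r.upper_bound for r in endo.reactions])
        p_lo, p_hi = pair.column_bounds()
        self.col_lo = np.concatenate([h_lo, e_lo, p_lo])
        self.col_hi = np.concatenate([h_hi, e_hi, p_hi])

        self.biomass_cols = {
            "host": self.col_offsets["host"] + host.biomass_index,
            "endo": self.col_offsets["endo"] + endo.biomass_index,
            "pair": self.col_offsets["pair"] + pair.host_biomass_col,
        }

    def solve(
        self, objective: np.ndarray, fixed_total: Optional[float] = None
    ) -> FluxSolution:
        A, row_lo, row_hi = self.A, self.row_lo, self.row_hi
        if fixed_total is not None:
            extra = sparse.lil_array((1, self.n_cols))
            for col in self.biomass_cols.values():
                extra[0, col] = 1.0
            A = sparse.vstack([A, sparse.csc_array(extra)])
            row_lo = np.append(row_lo, fixed_total)
            row_hi = np.append(row_hi, fixed_total)
        return solve_lp(A, row_lo, row_hi, self.col_lo, self.col_hi, objective)


def community_growth(
    host: MetabolicModel,
    endo: MetabolicModel,
    pair: EndosymbiosisModel,
    shared_env: Optional[Environment] = None,
) -> CommunityGrowthResult:
    """Two-step community growth computation.

    Step 1 maximizes the total flux through the three biomass reactions over
    the shared environment, giving ``z``.  Step 2 maximizes and minimizes
    each entity's biomass flux one at a time under the added constraint that
    the community total stays at ``z``; an entity's growth rate is *unique*
    when its spread ``(max - min)`` is within 10% of its maximum (entities
    pinned at zero count as unique).
    """
    shared_env = shared_env if shared_env is not None else pair.joint_env
    lp = _CommunityLP(host, endo, pair, shared_env)
    total_obj = np.zeros(lp.n_cols)
    for col in lp.biomass_cols.values():
        total_obj[col] = 1.0
    step1 = lp.solve(total_obj)
    if step1.status is not LPStatus.OPTIMAL:
        return CommunityGrowthResult(
            z=0.0,
            entity_max={k: 0.0 for k in lp.biomass_cols},
            entity_min={k: 0.0 for k in lp.biomass_cols},
            unique=True,
            feasible=False,
        )
    z = step1.objective
    entity_max: Dict[str, float] = {}
    entity_min: Dict[str, float] = {}
    witnesses: Dict[str, np.ndarray] = {}
    unique = True
    for name, col in lp.biomass_cols.items():
        obj = np.zeros(lp.n_cols)
        obj[col] = 1.0
        hi = lp.solve(obj, fixed_total=z)
        lo = lp.solve(-obj, fixed_total=z)
        vmax = hi.objective if hi.status is LPStatus.OPTIMAL else 0.0
        vmin = -lo.objective if lo.status is LPStatus.OPTIMAL else 0.0
        entity_max[name] = vmax
        entity_min[name] = vmin
        if hi.fluxes is not None:
            witnesses[name] = hi.fluxes
        if vmax > 0 and (vmax - vmin) / vmax > UNIQUENESS_FRACTION:
            unique = False
    return CommunityGrowthResult(
        z=z,
        entity_max=entity_max,
        entity_min=entity_min,
        unique=unique,
        witnesses=witnesses,
        objective=total_obj,
    )
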
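"""Nested host-endosymbiont flux systems.

An endosymbiont lives inside its host's cytoplasm: its extracellular
compartment *is* the host cytoplasm.  The pair is a single linear program
over host fluxes ``x`` and endosymbiont fluxes ``y``:

    maximize  x[biomass_H]
    s.t.      a_H + a_E <= S_H x + S_EtoH y <= b_H + b_E   (e-rows: joint env)
              (host internal rows at steady state, absorbing S_EtoH y)
              S_E y = 0                                     (endo internal)
              l_H <= x <= u_H,  l_E <= y <= u_E
              x[biomass_H] = y[biomass_E]                   (equal growth)

The equal-growth constraint makes the pair reproduce as a unit; the reported
growth rate is the shared biomass flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .core import (
    Compound,
    DEFAULT_BOUND,
    EndoPartition,
    Environment,
    MetabolicModel,
    ModelError,
    merge_environments,
    partition_for_endosymbiont,
)
from .fba import (
    FluxSolution,
    VIABILITY_TOLERANCE,
    solve_lp,
)


class PairClass(str, Enum):
    NEITHER = "neither"
    ONLY_ONE = "only_one"
    BOTH = "both"


@dataclass
class ConfigurationOutcome:
    """Viability of the two directed configurations of an unordered pair."""

    pair_ab_viable: bool  # A hosts B
    pair_ba_viable: bool  # B hosts A
    growth_ab: float = 0.0
    growth_ba: float = 0.0

    @property
    def pair_class(self) -> PairClass:
        n = int(self.pair_ab_viable) + int(self.pair_ba_viable)
        return (PairClass.NEITHER, PairClass.ONLY_ONE, PairClass.BOTH)[n]


@dataclass
class ExtraColumn:
    """An auxiliary reaction column appended to a pair system (repair)."""

    id: str
    entries: List[Tuple[int, float]]  # (global row index, coefficient)
    lower_bound: float
    upper_bound: float
    kind: str  # "transport" or "endo_access"
    base_id: str


@dataclass
class EndosymbiosisModel:
    """Assembled host-endosymbiont LP system.

    Global row layout: namespace rows (host side; e-rows carry the joint
    environment, internal rows steady state), then endosymbiont-internal
    rows, then orphan rows (endosymbiont e-compounds with no cytoplasmic
    counterpart, held at steady state), then the equal-growth row.
    """

    host: MetabolicModel
    endo: MetabolicModel
    partition: EndoPartition
    joint_env: Environment
    extra_columns: List[ExtraColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._A: Optional[sparse.csc_array] = None

    # -- layout ---------------------------------------------------------

    @property
    def n_ns(self) -> int:
        return len(self.host.compounds)

    @property
    def n_internal(self) -> int:
        return len(self.partition.internal_compounds)

    @property
    def n_orphans(self) -> int:
        return len(self.partition.orphan_base_ids)

    @property
    def n_rows(self) -> int:
        return self.n_ns + self.n_internal + self.n_orphans + 1

    @property
    def n_host_rxns(self) -> int:
        return len(self.host.reactions)

    @property
    def n_endo_rxns(self) -> int:
        return len(self.endo.reactions)

    @property
    def host_biomass_col(self) -> int:
        return self.host.biomass_index

    @property
    def endo_biomass_col(self) -> int:
        return self.n_host_rxns + self.endo.biomass_index

    @property
    def equal_growth_row(self) -> int:
        return self.n_rows - 1

    def ns_row(self, compound: Compound) -> int:
        return self.host.row_of(compound)

    def orphan_row(self, base_id: str) -> int:
        return self.n_ns + self.n_internal + self.partition.orphan_base_ids.index(base_id)

    # -- assembly -------------------------------------------------------

    @property
    def A(self) -> sparse.csc_array:
        if self._A is None:
            n_ns, n_int, n_orp = self.n_ns, self.n_internal, self.n_orphans
            host_block = sparse.vstack(
                [
                    self.host.S,
                    sparse.csc_array((n_int + n_orp, self.n_host_rxns)),
                ]
            )
            endo_block = sparse.vstack(
                [self.partition.S_EtoH, self.partition.S_E, self.partition.S_orphan]
            )
            A = sparse.hstack([host_block, endo_block], format="lil")
            # equal-growth row
            eq = sparse.lil_array((1, A.shape[1]))
            eq[0, self.host_biomass_col] = 1.0
            eq[0, self.endo_biomass_col] = -1.0
            A = sparse.vstack([A, eq], format="lil")
            if self.extra_columns:
                extra = sparse.lil_array((A.shape[0], len(self.extra_columns)))
                for j, col in enumerate(self.extra_columns):
                    for row, coef in col.entries:
                        extra[row, j] = coef
                A = sparse.hstack([A, extra], format="lil")
            self._A = sparse.csc_array(A)
        return self._A

    def row_bounds(
        self, env: Optional[Environment] = None, equal_growth: bool = True
    ) -> Tuple[np.ndarray, np.ndarray]:
        env = env if env is not None else self.joint_env
        lo = np.zeros(self.n_rows)
        hi = np.zeros(self.n_rows)
        for i, c in enumerate(self.host.compounds):
            if c.compartment == "e":
                lo[i], hi[i] = env.get(c.base_id)
        if not equal_growth:
            lo[self.equal_growth_row] = -np.inf
            hi[self.equal_growth_row] = np.inf
        return lo, hi

    def column_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [r.lower_bound for r in self.host.reactions]
            + [r.lower_bound for r in self.endo.reactions]
            + [c.lower_bound for c in self.extra_columns],
            dtype=float,
        )
        hi = np.array(
            [r.upper_bound for r in self.host.reactions]
            + [r.upper_bound for r in self.endo.reactions]
            + [c.upper_bound for c in self.extra_columns],
            dtype=float,
        )
        return lo, hi

    # -- solving --------------------------------------------------------

    def solve(
        self,
        env: Optional[Environment] = None,
        column_lower: Optional[np.ndarray] = None,
        column_upper: Optional[np.ndarray] = None,
        equal_growth: bool = True,
        force_endo_zero: bool = False,
    ) -> FluxSolution:
        """Maximize the host biomass flux of the assembled system.

        ``force_endo_zero`` pins all endosymbiont fluxes at zero (used with
        ``equal_growth=False`` to recover the host's solo optimum as a
        consistency check).
        """
        row_lo, row_hi = self.row_bounds(env, equal_growth=equal_growth)
        col_lo, col_hi = self.column_bounds()
        if column_lower is not None:
            col_lo = column_lower
        if column_upper is not None:
            col_hi = column_upper
        if force_endo_zero:
            col_lo = col_lo.copy()
            col_hi = col_hi.copy()
            sl = slice(self.n_host_rxns, self.n_host_rxns + self.n_endo_rxns)
            col_lo[sl] = 0.0
            col_hi[sl] = 0.0
        c = np.zeros(self.A.shape[1])
        c[self.host_biomass_col] = 1.0
        return solve_lp(self.A, row_lo, row_hi, col_lo, col_hi, c)

    # -- augmentation (used by the repair module) -----------------------

    def with_extra_columns(self, columns: Sequence[ExtraColumn]) -> "EndosymbiosisModel":
        return EndosymbiosisModel(
            host=self.host,
            endo=self.endo,
            partition=self.partition,
            joint_env=self.joint_env,
            extra_columns=list(self.extra_columns) + list(columns),
        )

    # -- export ---------------------------------------------------------

    def to_lp_text(self, env: Optional[Environment] = None) -> str:
        """Render the pair system in CPLEX LP text format for external solvers."""
        A = sparse.csr_array(self.A)
        row_lo, row_hi = self.row_bounds(env)
        col_lo, col_hi = self.column_bounds()
        names = (
            [f"x_{i}" for i in range(self.n_host_rxns)]
            + [f"y_{i}" for i in range(self.n_endo_rxns)]
            + [f"t_{i}" for i in range(len(self.extra_columns))]
        )
        lines = ["Maximize", f" obj: {names[self.host_biomass_col]}", "Subject To"]
        for i in range(A.shape[0]):
            start, end = A.indptr[i], A.indptr[i + 1]
            if start == end:
                continue
            terms = " + ".join(
                f"{A.data[k]:g} {names[A.indices[k]]}" for k in range(start, end)
            ).replace("+ -", "- ")
            if row_lo[i] == row_hi[i]:
                lines.append(f" r{i}: {terms} = {row_lo[i]:g}")
            else:
                if np.isfinite(row_lo[i]):
                    lines.append(f" r{i}_lo: {terms} >= {row_lo[i]:g}")
                if np.isfinite(row_hi[i]):
                    lines.append(f" r{i}_hi: {terms} <= {row_hi[i]:g}")
        lines.append("Bounds")
        for j, name in enumerate(names):
            lines.append(f" {col_lo[j]:g} <= {name} <= {col_hi[j]:g}")
        lines.append("End")
        return "\n".join(lines) + "\n"


def build_pair(host: MetabolicModel, endo: MetabolicModel) -> EndosymbiosisModel:
    """Assemble the nested LP system for ``endo`` living inside ``host``.

    Both models must come from one collection and share a harmonized
    namespace; the joint environment is the elementwise sum of the two
    ancestral environments, in which each ancestor can grow independently.
    """
    if host.collection_tag != endo.collection_tag:
        raise ModelError(
            f"cannot pair models from different collections: "
            f"{host.collection_tag!r} vs {endo.collection_tag!r}"
        )
    if host.compounds != endo.compounds:
        raise ModelError(
            "host and endosymbiont must be harmonized onto one namespace "
            "before pairing"
        )
    partition = partition_for_endosymbiont(endo)
    joint_env = merge_environments(host.environment, endo.environment)
    return EndosymbiosisModel(host=host, endo=endo, partition=partition, joint_env=joint_env)


def maximize_pair_growth(
    pair: EndosymbiosisModel, env: Optional[Environment] = None
) -> FluxSolution:
    """Shared growth rate of the pair (host and endosymbiont biomass fluxes
    are constrained equal)."""
    return pair.solve(env=env)


def pair_is_viable(
    pair: EndosymbiosisModel,
    env: Optional[Environment] = None,
    tolerance: float = VIABILITY_TOLERANCE,
) -> bool:
    return maximize_pair_growth(pair, env).growth >= tolerance


def assess_configurations(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    tolerance: float = VIABILITY_TOLERANCE,
) -> ConfigurationOutcome:
    """Evaluate both directed configurations of an unordered species pair."""
    sol_ab = maximize_pair_growth(build_pair(model_a, model_b))
    sol_ba = maximize_pair_growth(build_pair(model_b, model_a))
    return ConfigurationOutcome(
        pair_ab_viable=sol_ab.growth >= tolerance,
        pair_ba_viable=sol_ba.growth >= tolerance,
        growth_ab=sol_ab.growth,
        growth_ba=sol_ba.growth,
    )
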
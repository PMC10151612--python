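"""Diagnosing nonviable host-endosymbiont pairs and computing minimal
transport repairs.

Two non-exclusive causes make a pair nonviable in an environment where both
ancestors grow: (1) the host cannot move a compound the endosymbiont needs
(or must dispose of) between its extracellular and cytoplasm compartments —
fixable by adding host transport reactions; (2) the endosymbiont needs a
reaction whose compound never enters any cell — fixable only by granting the
endosymbiont direct access to the external environment, which the nested
compartment structure forbids in reality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set

import numpy as np

from .core import Compound, DEFAULT_BOUND, Environment, ModelError
from .endosymbiosis import (
    EndosymbiosisModel,
    ExtraColumn,
    maximize_pair_growth,
    pair_is_viable,
)
from .fba import VIABILITY_TOLERANCE


@dataclass
class RepairResult:
    """Diagnosis and (when applicable) minimal repair of a nonviable pair."""

    cause_transport: bool
    cause_access: bool
    candidate_compounds: Set[str] = field(default_factory=set)
    minimal_set: Set[str] = field(default_factory=set)
    single_specific: Optional[bool] = None
    fixable: bool = True  # by the combination of both mechanisms

    def to_json(self, host_id: str, endo_id: str, seed: Optional[int] = None) -> str:
        return json.dumps(
            {
                "host_id": host_id,
                "endo_id": endo_id,
                "seed": seed,
                "cause_transport": self.cause_transport,
                "cause_access": self.cause_access,
                "candidate_compounds": sorted(self.candidate_compounds),
                "minimal_set": sorted(self.minimal_set),
                "single_specific": self.single_specific,
                "fixable": self.fixable,
            }
        )


def candidate_transport_compounds(pair: EndosymbiosisModel) -> Set[str]:
    """Compounds whose host transport could possibly rescue the pair.

    A base_id qualifies when (1) it is available in the joint environment in
    nonzero amount, (2) it exists in both environmental and cellular
    compartments somewhere in the union of host and endosymbiont compounds,
    and (3) the endosymbiont has at least one reaction involving it.
    """
    env = pair.joint_env
    available = {
        base_id for base_id, (a, b) in env.bounds.items() if a < 0.0 or b > 0.0
    }
    compartments: Dict[str, Set[str]] = {}
    for c in pair.host.compounds:
        compartments.setdefault(c.base_id, set()).add(c.compartment)
    used_by_endo: Set[str] = set()
    for rxn in pair.endo.reactions:
        for compound in rxn.stoichiometry:
            used_by_endo.add(compound.base_id)
    return {
        base_id
        for base_id in available
        if "e" in compartments.get(base_id, set())
        and "c" in compartments.get(base_id, set())
        and base_id in used_by_endo
    }


def _transport_column(pair: EndosymbiosisModel, base_id: str, bound: float) -> ExtraColumn:
    row_e = pair.ns_row(Compound(base_id, "e"))
    row_c = pair.ns_row(Compound(base_id, "c"))
    return ExtraColumn(
        id=f"T_univ_{base_id}",
        entries=[(row_e, -1.0), (row_c, 1.0)],
        lower_bound=-bound,
        upper_bound=bound,
        kind="transport",
        base_id=base_id,
    )


def add_universal_transport(
    pair: EndosymbiosisModel,
    compounds: Sequence[str],
    bound: float = DEFAULT_BOUND,
) -> EndosymbiosisModel:
    """Return a copy of ``pair`` with reversible host ``[e] <-> [c]``
    transport reactions for the given compounds (original untouched).

    The added routes bypass any periplasm and carry symmetric bounds
    ``+/-bound``.  Compounds must come from the candidate set.
    """
    candidates = candidate_transport_compounds(pair)
    outside = set(compounds) - candidates
    if outside:
        raise ModelError(
            f"compounds outside the candidate transport set: {sorted(outside)}"
        )
    cols = [_transport_column(pair, b, bound) for b in sorted(set(compounds))]
    return pair.with_extra_columns(cols)


def _endo_access_columns(
    pair: EndosymbiosisModel, bound: float = DEFAULT_BOUND
) -> List[ExtraColumn]:
    """Direct environment-to-endosymbiont conduits for every environmental
    compound with nonzero amount.

    Each column withdraws a compound from its external e-row and delivers it
    to the row where the endosymbiont's copy of that compound lives (the
    mapped host cytoplasm row, or the orphan row), so supply remains limited
    by the joint environment.
    """
    cols: List[ExtraColumn] = []
    orphans = set(pair.partition.orphan_base_ids)
    for base_id, (a, b) in sorted(pair.joint_env.bounds.items()):
        if a == 0.0 and b == 0.0:
            continue
        e_compound = Compound(base_id, "e")
        if not pair.host.has_compound(e_compound):
            continue
        if base_id in orphans:
            target = pair.orphan_row(base_id)
        elif pair.host.has_compound(Compound(base_id, "c")):
            target = pair.ns_row(Compound(base_id, "c"))
        else:
            continue
        cols.append(
            ExtraColumn(
                id=f"ACC_{base_id}",
                entries=[(pair.ns_row(e_compound), -1.0), (target, 1.0)],
                lower_bound=-bound,
                upper_bound=bound,
                kind="endo_access",
                base_id=base_id,
            )
        )
    return cols


def diagnose_nonviability(
    pair: EndosymbiosisModel, tolerance: float = VIABILITY_TOLERANCE
) -> RepairResult:
    """Attribute a pair's nonviability to missing transport and/or missing
    environment access, in that fixed order.

    ``cause_transport`` is true when universal host transport of all
    candidate compounds restores viability.  If not, ``cause_access`` is true
    when additionally granting the endosymbiont direct source/sink access to
    every nonzero environmental compound does.  The two flags are not
    mutually exclusive.
    """
    if pair_is_viable(pair, tolerance=tolerance):
        raise ModelError("diagnose_nonviability called on a viable pair")
    candidates = candidate_transport_compounds(pair)
    with_transport = add_universal_transport(pair, sorted(candidates))
    transport_fixes = pair_is_viable(with_transport, tolerance=tolerance)
    if transport_fixes:
        return RepairResult(
            cause_transport=True,
            cause_access=False,
            candidate_compounds=candidates,
        )
    with_access = with_transport.with_extra_columns(_endo_access_columns(pair))
    combination_fixes = pair_is_viable(with_access, tolerance=tolerance)
    return RepairResult(
        cause_transport=False,
        cause_access=combination_fixes,
        candidate_compounds=candidates,
        fixable=combination_fixes,
    )


def _viable_with(
    pair: EndosymbiosisModel, compounds: Sequence[str], tolerance: float
) -> bool:
    return pair_is_viable(add_universal_transport(pair, compounds), tolerance=tolerance)


def minimal_transport_set(
    pair: EndosymbiosisModel,
    order_seed: int,
    tolerance: float = VIABILITY_TOLERANCE,
) -> Set[str]:
    """An irreducible set of transported compounds restoring pair viability.

    Starting from the full candidate set, single compounds are tentatively
    removed in a seeded random order; a removal is kept whenever the pair
    stays viable without that compound.  The result is irreducible (dropping
    any member breaks viability) and estimates the minimum repair size; a
    greedy pass does not guarantee the true minimum, so callers wanting a
    cardinality estimate should take the best of several seeds.
    """
    candidates = sorted(candidate_transport_compounds(pair))
    if not _viable_with(pair, candidates, tolerance):
        raise ModelError(
            "minimal_transport_set requires a pair fixable by transport alone"
        )
    rng = np.random.default_rng(order_seed)
    order = list(rng.permutation(len(candidates)))
    keep = set(candidates)
    for idx in order:
        compound = candidates[idx]
        trial = sorted(keep - {compound})
        if _viable_with(pair, trial, tolerance):
            keep.discard(compound)
    return keep


def best_minimal_transport_set(
    pair: EndosymbiosisModel,
    seed: int,
    restarts: int = 5,
    tolerance: float = VIABILITY_TOLERANCE,
) -> Set[str]:
    """Smallest irreducible transport set found over several greedy restarts."""
    rng = np.random.default_rng(seed)
    best: Optional[Set[str]] = None
    for _ in range(restarts):
        s = minimal_transport_set(pair, int(rng.integers(2**31 - 1)), tolerance)
        if best is None or len(s) < len(best):
            best = s
        if len(best) == 1:
            break
    assert best is not None
    return best


def single_specificity(
    pair: EndosymbiosisModel, tolerance: float = VIABILITY_TOLERANCE
) -> bool:
    """True when exactly one candidate compound alone restores viability.

    Exhaustive singleton scan over the candidate set; meaningful when some
    singleton repair exists.
    """
    candidates = sorted(candidate_transport_compounds(pair))
    rescuers = [c for c in candidates if _viable_with(pair, [c], tolerance)]
    return len(rescuers) == 1
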
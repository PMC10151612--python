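"""Mutation scans: bound-relaxation mutations on ancestral metabolisms and
host-endosymbiont pairs.

A mutation relaxes one reaction's flux bounds by a large factor (default
1000), effectively removing that reaction as a limiting constraint:
``[l, u] -> [-factor*|l|, factor*u]``.  Relaxing a constraint of a
maximization problem can never decrease the optimum, so every mutation is
neutral or beneficial; it is *beneficial* when the growth rate strictly
increases (beyond numerical noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Union

import numpy as np

from .core import Environment, MetabolicModel, ModelError, Reaction
from .endosymbiosis import EndosymbiosisModel
from .fba import maximize_growth

logger = logging.getLogger(__name__)

#: Default bound-relaxation factor for a single mutation.
MUTATION_FACTOR = 1000.0

#: Default factor for tightening all bounds of bound-insensitive models.
TIGHTEN_FACTOR = 100.0

#: Relative growth increase above which a mutation counts as beneficial
#: (guards against solver noise creating phantom beneficial mutations).
BENEFICIAL_RTOL = 1e-6


class MutationContext(str, Enum):
    ANCESTRAL_HOST = "ancestral_host"
    ANCESTRAL_ENDO = "ancestral_endo"
    PAIR_HOST_REACTION = "pair_host_reaction"
    PAIR_ENDO_REACTION = "pair_endo_reaction"


@dataclass
class MutationEffect:
    reaction_id: str
    context: MutationContext
    baseline_growth: float
    mutated_growth: float
    beneficial: bool
    exceeds_host_ancestor: bool = False
    exceeds_endo_ancestor: bool = False
    solver_failed: bool = False


@dataclass
class EvolvabilityComparison:
    """Cross-entity summary of single-mutation scans in one environment."""

    n_beneficial: Dict[str, int]
    paired_diff_host: Dict[str, int]  # per host reaction: ancestor - pair
    paired_diff_endo: Dict[str, int]
    max_growth_reached: Dict[str, float]
    exceed_host_fraction: Optional[float]  # of pair-beneficial host-reaction mutations
    exceed_endo_fraction: Optional[float]  # of pair-beneficial endo-reaction mutations
    effects: Dict[str, List[MutationEffect]] = field(default_factory=dict)


def mutate_bounds(reaction: Reaction, factor: float = MUTATION_FACTOR) -> Reaction:
    """Relaxed copy of a reaction: ``[-factor*|l|, factor*u]``.

    For the unusual case ``l > 0`` the formula flips the sign of the lower
    bound (making the reaction reversible); such reactions are flagged in the
    log but handled verbatim.
    """
    if factor < 1:
        raise ModelError(f"mutation factor must be >= 1, got {factor}")
    if reaction.lower_bound > 0:
        logger.warning(
            "mutating reaction %s with positive lower bound %g: relaxation "
            "flips its direction constraint", reaction.id, reaction.lower_bound,
        )
    out = reaction.copy()
    out.lower_bound = -factor * abs(reaction.lower_bound)
    out.upper_bound = factor * reaction.upper_bound
    return out


def tighten_all_bounds(
    model: MetabolicModel, factor: float = TIGHTEN_FACTOR
) -> MetabolicModel:
    """Copy of ``model`` with every reaction's bounds divided by ``factor``.

    Used to move bound-insensitive models (where the environment, not the
    reactions, limits growth) into a regime where bound mutations have
    visible effects."""
    if factor <= 1:
        raise ModelError(f"tightening factor must be > 1, got {factor}")
    out = model.copy()
    for rxn in out.reactions:
        rxn.lower_bound /= factor
        rxn.upper_bound /= factor
    return out


def _is_beneficial(baseline: float, mutated: float) -> bool:
    scale = max(abs(baseline), 1e-12)
    return (mutated - baseline) / scale > BENEFICIAL_RTOL


def _exceeds(mutated: float, ancestor: float) -> bool:
    return mutated > ancestor * (1.0 + BENEFICIAL_RTOL)


def scan_mutations(
    entity: Union[MetabolicModel, EndosymbiosisModel],
    context: MutationContext,
    env: Optional[Environment] = None,
    factor: float = MUTATION_FACTOR,
    host_ancestor_growth: Optional[float] = None,
    endo_ancestor_growth: Optional[float] = None,
) -> List[MutationEffect]:
    """One bound-relaxation mutation per reaction, bounds restored between
    evaluations.

    For a pair, host-reaction and endosymbiont-reaction scans run separately
    (pick the context); the entity itself is never modified — mutations are
    applied to the LP's column bounds only.
    """
    if isinstance(entity, EndosymbiosisModel):
        if context not in (
            MutationContext.PAIR_HOST_REACTION,
            MutationContext.PAIR_ENDO_REACTION,
        ):
            raise ModelError(f"context {context} requires an ancestral model")
        reactions = (
            entity.host.reactions
            if context is MutationContext.PAIR_HOST_REACTION
            else entity.endo.reactions
        )
        offset = (
            0 if context is MutationContext.PAIR_HOST_REACTION else entity.n_host_rxns
        )
        col_lo, col_hi = entity.column_bounds()
        baseline = entity.solve(env).growth

        def solve_with(j: int, lb: float, ub: float) -> float:
            old = col_lo[j], col_hi[j]
            col_lo[j], col_hi[j] = lb, ub
            sol = entity.solve(env, column_lower=col_lo, column_upper=col_hi)
            col_lo[j], col_hi[j] = old
            return sol.growth

    else:
        if context in (
            MutationContext.PAIR_HOST_REACTION,
            MutationContext.PAIR_ENDO_REACTION,
        ):
            raise ModelError(f"context {context} requires a pair system")
        reactions = entity.reactions
        offset = 0
        from .fba import _column_bounds, solve_lp  # local to keep surface small

        col_lo, col_hi = _column_bounds(entity)
        row_lo, row_hi = entity.row_bounds(env)
        obj = np.zeros(len(entity.reactions))
        obj[entity.biomass_index] = 1.0
        baseline = solve_lp(entity.S, row_lo, row_hi, col_lo, col_hi, obj).growth

        def solve_with(j: int, lb: float, ub: float) -> float:
            old = col_lo[j], col_hi[j]
            col_lo[j], col_hi[j] = lb, ub
            sol = solve_lp(entity.S, row_lo, row_hi, col_lo, col_hi, obj)
            col_lo[j], col_hi[j] = old
            return sol.growth

    effects: List[MutationEffect] = []
    for j, rxn in enumerate(reactions):
        mutated = mutate_bounds(rxn, factor)
        growth = solve_with(offset + j, mutated.lower_bound, mutated.upper_bound)
        effects.append(
            MutationEffect(
                reaction_id=rxn.id,
                context=context,
                baseline_growth=baseline,
                mutated_growth=growth,
                beneficial=_is_beneficial(baseline, growth),
                exceeds_host_ancestor=(
                    _exceeds(growth, host_ancestor_growth)
                    if host_ancestor_growth is not None
                    else False
                ),
                exceeds_endo_ancestor=(
                    _exceeds(growth, endo_ancestor_growth)
                    if endo_ancestor_growth is not None
                    else False
                ),
            )
        )
    return effects


def compare_evolvability(
    pair: EndosymbiosisModel,
    host: MetabolicModel,
    endo: MetabolicModel,
    env: Optional[Environment] = None,
    factor: float = MUTATION_FACTOR,
) -> EvolvabilityComparison:
    """Scan all four contexts in one joint environment and collate.

    Paired differences are per reaction over the shared reaction sets
    (ancestor-context beneficial indicator minus pair-context indicator);
    exceed fractions are the share of pair-beneficial mutations whose mutated
    pair growth surpasses the corresponding ancestor's unmutated growth.
    """
    env = env if env is not None else pair.joint_env
    host_growth = maximize_growth(host, env).growth
    endo_growth = maximize_growth(endo, env).growth
    scans = {
        "ancestral_host": scan_mutations(host, MutationContext.ANCESTRAL_HOST, env, factor),
        "ancestral_endo": scan_mutations(endo, MutationContext.ANCESTRAL_ENDO, env, factor),
        "pair_host_reaction": scan_mutations(
            pair, MutationContext.PAIR_HOST_REACTION, env, factor,
            host_ancestor_growth=host_growth, endo_ancestor_growth=endo_growth,
        ),
        "pair_endo_reaction": scan_mutations(
            pair, MutationContext.PAIR_ENDO_REACTION, env, factor,
            host_ancestor_growth=host_growth, endo_ancestor_growth=endo_growth,
        ),
    }
    n_beneficial = {k: sum(e.beneficial for e in v) for k, v in scans.items()}

    def paired(anc: List[MutationEffect], par: List[MutationEffect]) -> Dict[str, int]:
        par_by_id = {e.reaction_id: e for e in par}
        return {
            e.reaction_id: int(e.beneficial) - int(par_by_id[e.reaction_id].beneficial)
            for e in anc
        }

    def exceed_fraction(effects: List[MutationEffect], which: str) -> Optional[float]:
        beneficial = [e for e in effects if e.beneficial]
        if not beneficial:
            return None
        flag = "exceeds_host_ancestor" if which == "host" else "exceeds_endo_ancestor"
        return sum(getattr(e, flag) for e in beneficial) / len(beneficial)

    max_growth = {
        k: max([e.mutated_growth for e in v] + [v[0].baseline_growth if v else 0.0])
        for k, v in scans.items()
    }
    return EvolvabilityComparison(
        n_beneficial=n_beneficial,
        paired_diff_host=paired(scans["ancestral_host"], scans["pair_host_reaction"]),
        paired_diff_endo=paired(scans["ancestral_endo"], scans["pair_endo_reaction"]),
        max_growth_reached=max_growth,
        exceed_host_fraction=exceed_fraction(scans["pair_host_reaction"], "host"),
        exceed_endo_fraction=exceed_fraction(scans["pair_endo_reaction"], "endo"),
        effects=scans,
    )
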
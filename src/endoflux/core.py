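"""Domain types for constraint-based metabolic models and the restructuring
operations that prepare them for host-endosymbiont analyses.

A :class:`MetabolicModel` is a stoichiometric system ``S`` (compounds x
reactions) with per-reaction flux bounds, a designated biomass reaction, and
an *externalized environment*: instead of source/sink exchange reactions, the
availability of each extracellular compound is encoded as a pair of bounds
``a_j <= c'_j <= b_j`` on the net production rate ``c'_j = sum_k S[j,k] x_k``
of that compound.  Internal compounds (cytoplasm ``c`` and periplasm ``p``)
are held at steady state, ``c'_j = 0``.

Sign convention: uptake of an environmental compound by the cell makes its
derivative negative, so an availability of ``m`` units becomes
``env_lower = -m``; secretion capacity sits in ``env_upper >= 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

COMPARTMENTS = ("c", "e", "p")

#: Conventional "effectively unbounded" flux magnitude used by the large
#: model collections; also the default bound on added transport reactions.
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Fatal structural problem in a metabolic model or operation input."""


@dataclass(frozen=True, order=True)
class Compound:
    """A chemical species in one compartment.

    Identity across compartments (e.g. for transport, or for mapping an
    endosymbiont's exterior onto its host's cytoplasm) is by ``base_id``
    alone; identity within a namespace is the ``(base_id, compartment)``
    pair.
    """

    base_id: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelError(
                f"unknown compartment {self.compartment!r} for compound "
                f"{self.base_id!r}; expected one of {COMPARTMENTS}"
            )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.base_id}[{self.compartment}]"


@dataclass
class Reaction:
    """A flux-carrying reaction with signed stoichiometry and box bounds.

    Bounds are in the collections' customary mmol/gDW/h scale.  ``is_exchange``
    marks raw-model source/sink pseudo-reactions that are removed when the
    environment is externalized.
    """

    id: str
    stoichiometry: Dict[Compound, float]
    lower_bound: float
    upper_bound: float
    is_biomass: bool = False
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r} has lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            is_biomass=self.is_biomass,
            is_exchange=self.is_exchange,
        )


@dataclass
class Environment:
    """Derivative bounds for extracellular compounds, keyed by base_id.

    Every entry ``(a, b)`` satisfies ``a <= 0 <= b``; ``-a`` is the amount of
    the compound available for net consumption, ``b`` the capacity of the
    environment to absorb net secretion.
    """

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for base_id, (a, b) in self.bounds.items():
            if not (a <= 0.0 <= b):
                raise ModelError(
                    f"environment bounds for {base_id!r} must satisfy "
                    f"a <= 0 <= b, got ({a}, {b})"
                )

    def get(self, base_id: str) -> Tuple[float, float]:
        return self.bounds.get(base_id, (0.0, 0.0))

    def copy(self) -> "Environment":
        return Environment(dict(self.bounds))

    def __contains__(self, base_id: str) -> bool:
        return base_id in self.bounds


def merge_environments(env_a: Environment, env_b: Environment) -> Environment:
    """Elementwise sum of two environments (the *joint environment*).

    A compound present in only one input contributes its own bounds; summing
    intervals that each contain zero yields an interval containing zero, so
    each ancestor remains feasible in the merged environment.
    """
    merged: Dict[str, Tuple[float, float]] = {}
    for base_id in sorted(set(env_a.bounds) | set(env_b.bounds)):
        a1, b1 = env_a.get(base_id)
        a2, b2 = env_b.get(base_id)
        merged[base_id] = (a1 + a2, b1 + b2)
    return Environment(merged)


@dataclass
class MetabolicModel:
    """A (possibly harmonized) metabolic model.

    ``compounds`` fixes the row order of the stoichiometric matrix; after
    harmonization all models of a collection share one row indexing so that
    the same row is the same compound everywhere.
    """

    id: str
    compounds: List[Compound]
    reactions: List[Reaction]
    env_lower: np.ndarray
    env_upper: np.ndarray
    biomass_index: int
    collection_tag: str = "default"

    def __post_init__(self) -> None:
        n = len(self.compounds)
        if len(set(self.compounds)) != n:
            raise ModelError(f"model {self.id!r}: duplicate compounds in namespace")
        self.env_lower = np.asarray(self.env_lower, dtype=float)
        self.env_upper = np.asarray(self.env_upper, dtype=float)
        if self.env_lower.shape != (n,) or self.env_upper.shape != (n,):
            raise ModelError(f"model {self.id!r}: environment vectors must have length {n}")
        biomass = [i for i, r in enumerate(self.reactions) if r.is_biomass]
        if biomass != [self.biomass_index]:
            raise ModelError(
                f"model {self.id!r}: exactly one biomass reaction required at "
                f"biomass_index; flagged {biomass}, declared {self.biomass_index}"
            )
        self._index: Dict[Compound, int] = {c: i for i, c in enumerate(self.compounds)}
        self._S: Optional[sparse.csc_array] = None

    # -- matrix ---------------------------------------------------------

    @property
    def S(self) -> sparse.csc_array:
        """Sparse stoichiometric matrix, compounds x reactions."""
        if self._S is None:
            rows, cols, vals = [], [], []
            for j, rxn in enumerate(self.reactions):
                for compound, coef in rxn.stoichiometry.items():
                    try:
                        rows.append(self._index[compound])
                    except KeyError:
                        raise ModelError(
                            f"model {self.id!r}: reaction {rxn.id!r} references "
                            f"compound {compound} outside the namespace"
                        ) from None
                    cols.append(j)
                    vals.append(coef)
            self._S = sparse.csc_array(
                (vals, (rows, cols)),
                shape=(len(self.compounds), len(self.reactions)),
            )
        return self._S

    def row_of(self, compound: Compound) -> int:
        return self._index[compound]

    def has_compound(self, compound: Compound) -> bool:
        return compound in self._index

    # -- convenience ----------------------------------------------------

    @property
    def is_raw(self) -> bool:
        """True while exchange pseudo-reactions are still present."""
        return any(r.is_exchange for r in self.reactions)

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reactions[self.biomass_index]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def environment(self) -> Environment:
        """The model's own environment as an :class:`Environment` object."""
        bounds: Dict[str, Tuple[float, float]] = {}
        for i, c in enumerate(self.compounds):
            if c.compartment == "e" and (self.env_lower[i] != 0.0 or self.env_upper[i] != 0.0):
                bounds[c.base_id] = (float(self.env_lower[i]), float(self.env_upper[i]))
        return Environment(bounds)

    def row_bounds(self, env: Optional[Environment] = None) -> Tuple[np.ndarray, np.ndarray]:
        """Per-row derivative bounds: steady state internally, ``env`` on e-rows."""
        n = len(self.compounds)
        lo = np.zeros(n)
        hi = np.zeros(n)
        if env is None:
            mask = np.array([c.compartment == "e" for c in self.compounds])
            lo[mask] = self.env_lower[mask]
            hi[mask] = self.env_upper[mask]
        else:
            for i, c in enumerate(self.compounds):
                if c.compartment == "e":
                    lo[i], hi[i] = env.get(c.base_id)
        return lo, hi

    def copy(self, new_id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            id=new_id or self.id,
            compounds=list(self.compounds),
            reactions=[r.copy() for r in self.reactions],
            env_lower=self.env_lower.copy(),
            env_upper=self.env_upper.copy(),
            biomass_index=self.biomass_index,
            collection_tag=self.collection_tag,
        )

    def without_reaction(self, reaction_id: str) -> "MetabolicModel":
        """Copy of the model with one (non-biomass) reaction deleted."""
        keep = [r.copy() for r in self.reactions if r.id != reaction_id]
        if len(keep) == len(self.reactions):
            raise ModelError(f"model {self.id!r}: no reaction {reaction_id!r}")
        biomass = [i for i, r in enumerate(keep) if r.is_biomass]
        if len(biomass) != 1:
            raise ModelError("cannot delete the biomass reaction")
        return MetabolicModel(
            id=self.id,
            compounds=list(self.compounds),
            reactions=keep,
            env_lower=self.env_lower.copy(),
            env_upper=self.env_upper.copy(),
            biomass_index=biomass[0],
            collection_tag=self.collection_tag,
        )

    def validate(self) -> None:
        """Check the structural invariants of a restructured model."""
        for i, c in enumerate(self.compounds):
            if c.compartment in ("c", "p"):
                if self.env_lower[i] != 0.0 or self.env_upper[i] != 0.0:
                    raise ModelError(
                        f"model {self.id!r}: internal compound {c} must be at "
                        f"steady state (env bounds zero)"
                    )
            else:
                if not (self.env_lower[i] <= 0.0 <= self.env_upper[i]):
                    raise ModelError(
                        f"model {self.id!r}: environmental compound {c} bounds "
                        f"must straddle zero"
                    )
        _ = self.S  # raises on out-of-namespace stoichiometry


@dataclass
class EndoPartition:
    """An endosymbiont's stoichiometric matrix split by compound location.

    ``S_E`` holds the rows of compounds strictly inside the endosymbiont (its
    ``c`` and ``p`` compartments, private to it), ``S_EtoH`` the rows of its
    ``e``-compartment compounds re-mapped onto the corresponding ``base_id@c``
    rows of the shared (host-side) namespace.  An e-compound whose base_id has
    no cytoplasmic counterpart anywhere in the namespace cannot be re-mapped;
    it is kept on a flagged fresh *orphan* row (a structural marker for the
    endosymbiont needing direct environment access).
    """

    model: MetabolicModel
    namespace: List[Compound]
    internal_compounds: List[Compound]
    S_E: sparse.csc_array          # internal_compounds x reactions
    S_EtoH: sparse.csc_array       # namespace x reactions (entries on @c rows)
    orphan_base_ids: List[str]
    S_orphan: sparse.csc_array     # orphan rows x reactions
    e_row_targets: Dict[Compound, Compound]  # endo e-compound -> host c-compound

    @property
    def has_orphans(self) -> bool:
        return bool(self.orphan_base_ids)


# ---------------------------------------------------------------------------
# Restructuring operations
# ---------------------------------------------------------------------------


def harmonize_namespace(models: Sequence[MetabolicModel]) -> List[MetabolicModel]:
    """Re-index a set of models onto one shared, sorted compound namespace.

    After harmonization the same ``(base_id, compartment)`` pair occupies the
    same row in every model.  The operation is idempotent and independent of
    the order of the input list (the union namespace is sorted).
    """
    if not models:
        raise ModelError("harmonize_namespace requires at least one model")
    tags = {m.collection_tag for m in models}
    if len(tags) > 1:
        raise ModelError(
            f"models from different collections cannot be harmonized: {sorted(tags)}"
        )
    namespace = sorted({c for m in models for c in m.compounds})
    out = []
    for m in models:
        lo = np.zeros(len(namespace))
        hi = np.zeros(len(namespace))
        index = {c: i for i, c in enumerate(namespace)}
        for i, c in enumerate(m.compounds):
            lo[index[c]] = m.env_lower[i]
            hi[index[c]] = m.env_upper[i]
        out.append(
            MetabolicModel(
                id=m.id,
                compounds=list(namespace),
                reactions=[r.copy() for r in m.reactions],
                env_lower=lo,
                env_upper=hi,
                biomass_index=m.biomass_index,
                collection_tag=m.collection_tag,
            )
        )
    return out


def externalize_environment(model: MetabolicModel) -> MetabolicModel:
    """Replace exchange reactions with equivalent derivative bounds.

    A source/sink reaction touching a single environmental compound with
    coefficient ``s`` and flux range ``[l, u]`` forces the rest of the network
    to satisfy ``c'_j = -s*r`` for some ``r`` in ``[l, u]``; the induced
    interval becomes the compound's environment bounds.  For the customary
    sink form (``X[e] ->``, coefficient -1) the bounds transfer unchanged.
    Duplicate exchanges for one compound have their intervals summed (with a
    logged warning).  The maximum growth of the model is unchanged.
    """
    env: Dict[int, Tuple[float, float]] = {}
    keep: List[Reaction] = []
    seen: Dict[int, int] = {}
    for rxn in model.reactions:
        if not rxn.is_exchange:
            keep.append(rxn.copy())
            continue
        if len(rxn.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {rxn.id!r} must touch exactly one compound"
            )
        (compound, coef), = rxn.stoichiometry.items()
        if compound.compartment != "e" or abs(coef) != 1.0:
            raise ModelError(
                f"exchange reaction {rxn.id!r} must touch one environmental "
                f"compound with coefficient +/-1 (got {compound} x {coef})"
            )
        row = model.row_of(compound)
        endpoints = sorted((-coef * rxn.lower_bound, -coef * rxn.upper_bound))
        if row in env:
            seen[row] += 1
            logger.warning(
                "model %s: duplicate exchange %s for %s; summing bounds",
                model.id, rxn.id, compound,
            )
            a, b = env[row]
            env[row] = (a + endpoints[0], b + endpoints[1])
        else:
            seen[row] = 1
            env[row] = (endpoints[0], endpoints[1])
    lo = np.zeros(len(model.compounds))
    hi = np.zeros(len(model.compounds))
    for row, (a, b) in env.items():
        lo[row], hi[row] = a, b
    biomass_index = next(i for i, r in enumerate(keep) if r.is_biomass)
    out = MetabolicModel(
        id=model.id,
        compounds=list(model.compounds),
        reactions=keep,
        env_lower=lo,
        env_upper=hi,
        biomass_index=biomass_index,
        collection_tag=model.collection_tag,
    )
    out.validate()
    return out


def partition_for_endosymbiont(model: MetabolicModel) -> EndoPartition:
    """Split a model's matrix into endosymbiont-internal and host-facing rows.

    In an endosymbiosis the endosymbiont's extracellular compartment *is* the
    host's cytoplasm, so every e-row of the endosymbiont is re-mapped to the
    ``base_id@c`` row of the shared namespace.  Rows without any cytoplasmic
    counterpart become flagged orphan rows.
    """
    namespace = list(model.compounds)
    c_rows = {c.base_id for c in namespace if c.compartment == "c"}
    internal = [c for c in namespace if c.compartment in ("c", "p")]
    internal_index = {c: i for i, c in enumerate(internal)}
    ns_index = {c: i for i, c in enumerate(namespace)}

    orphans: List[str] = []
    orphan_index: Dict[str, int] = {}
    e_row_targets: Dict[Compound, Compound] = {}

    rows_E, cols_E, vals_E = [], [], []
    rows_H, cols_H, vals_H = [], [], []
    rows_O, cols_O, vals_O = [], [], []
    for j, rxn in enumerate(model.reactions):
        for compound, coef in rxn.stoichiometry.items():
            if compound.compartment in ("c", "p"):
                rows_E.append(internal_index[compound])
                cols_E.append(j)
                vals_E.append(coef)
            elif compound.base_id in c_rows:
                target = Compound(compound.base_id, "c")
                e_row_targets[compound] = target
                rows_H.append(ns_index[target])
                cols_H.append(j)
                vals_H.append(coef)
            else:
                if compound.base_id not in orphan_index:
                    orphan_index[compound.base_id] = len(orphans)
                    orphans.append(compound.base_id)
                    logger.info(
                        "model %s: e-compound %s has no cytoplasmic counterpart; "
                        "kept on orphan row", model.id, compound,
                    )
                rows_O.append(orphan_index[compound.base_id])
                cols_O.append(j)
                vals_O.append(coef)

    n_rxn = len(model.reactions)
    return EndoPartition(
        model=model,
        namespace=namespace,
        internal_compounds=internal,
        S_E=sparse.csc_array((vals_E, (rows_E, cols_E)), shape=(len(internal), n_rxn)),
        S_EtoH=sparse.csc_array((vals_H, (rows_H, cols_H)), shape=(len(namespace), n_rxn)),
        orphan_base_ids=orphans,
        S_orphan=sparse.csc_array((vals_O, (rows_O, cols_O)), shape=(len(orphans), n_rxn)),
        e_row_targets=e_row_targets,
    )


def shared_reaction_fraction(model_a: MetabolicModel, model_b: MetabolicModel) -> float:
    """Jaccard fraction of shared reaction ids between two models."""
    ids_a = set(model_a.reaction_ids)
    ids_b = set(model_b.reaction_ids)
    union = ids_a | ids_b
    if not union:
        return 0.0
    return len(ids_a & ids_b) / len(union)
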
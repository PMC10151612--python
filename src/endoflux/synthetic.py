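"""Synthetic metabolic networks with known ground truth.

Two sources of inputs for the analyses and their tests:

* a family of tiny hand-built fixtures (``TOY-*``) whose solo, pair, and
  community growth rates have closed forms derivable by hand, and

* a seeded random generator of guaranteed-viable linear-pathway models and
  of host-endosymbiont pairs with engineered nonviability causes, emulating
  the structure of curated model collections (multi-compartment, one biomass
  reaction, an environment that supports growth) at toy scale.

Generated models are backbone-first: each environmental substrate feeds a
transport step and a chain of internal conversions ending in a biomass
precursor; biomass consumes one unit of each precursor.  With no shortcut
reactions the maximum growth has the closed form
``min_k availability_k / biomass_demand_k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    Compound,
    Environment,
    MetabolicModel,
    ModelError,
    Reaction,
    harmonize_namespace,
)
from .endosymbiosis import EndosymbiosisModel, build_pair, maximize_pair_growth
from .fba import VIABILITY_TOLERANCE, maximize_growth
from .repair import add_universal_transport, candidate_transport_compounds

logger = logging.getLogger(__name__)


class Defect(str, Enum):
    NONE = "none"
    TRANSPORT = "transport_deficient"
    ACCESS = "access_deficient"
    BOTH = "both"


@dataclass
class GroundTruth:
    """What the generator knows to be true about its output."""

    expected_solo_growth: Dict[str, float] = field(default_factory=dict)
    expected_pair_growth: Optional[float] = None
    defect: Defect = Defect.NONE
    rescuing_compounds: Set[str] = field(default_factory=set)


@dataclass
class GeneratorParams:
    """Knobs of the random model generator; the seed fully determines the
    output.

    Defaults put the models in the environment-limited regime of the large
    curated collections (reaction bounds 100 versus availability 10, so the
    medium, not the reactions, binds growth); :meth:`bound_limited` gives the
    opposite regime in which bound mutations have visible effects.
    """

    n_env_substrates: int = 3
    pathway_depth: int = 2
    redundancy: int = 0
    env_availability: float = 10.0
    bound_magnitude: float = 100.0
    seed: int = 0
    heterogeneous_biomass: bool = False
    #: extra environmental compounds no reaction uses (inert medium
    #: components, present in real media); shared names across a collection
    n_unused_env: int = 1

    def __post_init__(self) -> None:
        if self.n_env_substrates < 1 or self.pathway_depth < 1:
            raise ModelError("substrate count and pathway depth must be >= 1")
        if self.redundancy < 0:
            raise ModelError("redundancy must be >= 0")
        if self.env_availability <= 0 or self.bound_magnitude <= 0:
            raise ModelError("availability and bound magnitude must be positive")

    @property
    def n_internal_compounds(self) -> int:
        return self.n_env_substrates * self.pathway_depth

    @property
    def n_reactions(self) -> int:
        return self.n_env_substrates * self.pathway_depth + 1 + self.redundancy

    @classmethod
    def bound_limited(cls, seed: int = 0, **kwargs) -> "GeneratorParams":
        """Preset where reaction bounds, not the environment, bind growth."""
        kwargs.setdefault("bound_magnitude", 5.0)
        kwargs.setdefault("env_availability", 10.0)
        return cls(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Hand-built fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    name: str
    models: Dict[str, MetabolicModel]
    ground_truth: GroundTruth
    host_id: Optional[str] = None
    endo_id: Optional[str] = None
    pair: Optional[EndosymbiosisModel] = None
    shared_env: Optional[Environment] = None

    @property
    def model(self) -> MetabolicModel:
        if len(self.models) != 1:
            raise ModelError(f"fixture {self.name} holds multiple models")
        return next(iter(self.models.values()))

    @property
    def host(self) -> MetabolicModel:
        return self.models[self.host_id]

    @property
    def endo(self) -> MetabolicModel:
        return self.models[self.endo_id]


def _toy(
    model_id: str,
    reactions: Sequence[Tuple[str, Dict[Tuple[str, str], float], float, float, bool]],
    env: Dict[str, Tuple[float, float]],
    collection_tag: str = "toy",
    extra_compounds: Sequence[Tuple[str, str]] = (),
) -> MetabolicModel:
    """Build an externalized toy model from (id, stoich, lb, ub, biomass)
    tuples; the compound namespace is inferred from the stoichiometries
    (plus any explicitly listed reaction-free compounds)."""
    compounds = sorted(
        {Compound(b, c) for _, st, _, _, _ in reactions for (b, c) in st}
        | {Compound(b, c) for b, c in extra_compounds}
    )
    index = {c: i for i, c in enumerate(compounds)}
    rxns = [
        Reaction(
            id=rid,
            stoichiometry={Compound(b, c): v for (b, c), v in st.items()},
            lower_bound=lb,
            upper_bound=ub,
            is_biomass=bio,
        )
        for rid, st, lb, ub, bio in reactions
    ]
    lo = np.zeros(len(compounds))
    hi = np.zeros(len(compounds))
    for base_id, (a, b) in env.items():
        i = index[Compound(base_id, "e")]
        lo[i], hi[i] = a, b
    biomass_index = next(i for i, r in enumerate(rxns) if r.is_biomass)
    model = MetabolicModel(
        id=model_id,
        compounds=compounds,
        reactions=rxns,
        env_lower=lo,
        env_upper=hi,
        biomass_index=biomass_index,
        collection_tag=collection_tag,
    )
    model.validate()
    return model


def _chain_model(
    model_id: str,
    substrate: str,
    product: str,
    transport_bound: float = 100.0,
    availability: float = 10.0,
    rxn_suffix: str = "",
) -> MetabolicModel:
    """Linear chain  substrate[e] -> substrate[c] -> product[c] -> biomass."""
    s = rxn_suffix
    return _toy(
        model_id,
        [
            (f"T{s}", {(substrate, "e"): -1.0, (substrate, "c"): 1.0}, 0.0, transport_bound, False),
            (f"R{s}", {(substrate, "c"): -1.0, (product, "c"): 1.0}, 0.0, 100.0, False),
            (f"BIO{s}", {(product, "c"): -1.0}, 0.0, 100.0, True),
        ],
        {substrate: (-availability, 0.0)},
    )


def _fx_toy_a() -> Fixture:
    m = _chain_model("TOY-A", "A", "B", rxn_suffix="_A")
    return Fixture("TOY-A", {m.id: m}, GroundTruth(expected_solo_growth={m.id: 10.0}))


def _fx_toy_b() -> Fixture:
    m = _chain_model("TOY-B", "N", "M", rxn_suffix="_B")
    return Fixture("TOY-B", {m.id: m}, GroundTruth(expected_solo_growth={m.id: 10.0}))


def _fx_toy_c() -> Fixture:
    # consumes orphan substrate D[e] directly (no D[c] anywhere) and carries
    # an A transporter that lets it host an A-consuming endosymbiont
    m = _toy(
        "TOY-C",
        [
            ("RD_C", {("D", "e"): -1.0, ("P", "c"): 1.0}, 0.0, 100.0, False),
            ("TA_C", {("A", "e"): -1.0, ("A", "c"): 1.0}, -100.0, 100.0, False),
            ("BIO_C", {("P", "c"): -1.0}, 0.0, 100.0, True),
        ],
        {"D": (-10.0, 0.0)},
    )
    return Fixture("TOY-C", {m.id: m}, GroundTruth(expected_solo_growth={m.id: 10.0}))


def _fx_toy_mut() -> Fixture:
    m = _chain_model("TOY-MUT", "A", "B", transport_bound=5.0, rxn_suffix="_M")
    return Fixture("TOY-MUT", {m.id: m}, GroundTruth(expected_solo_growth={m.id: 5.0}))


def _pair_fixture(
    name: str,
    host: MetabolicModel,
    endo: MetabolicModel,
    gt: GroundTruth,
    transports: Sequence[str] = (),
) -> Fixture:
    host_h, endo_h = harmonize_namespace([host, endo])
    pair = build_pair(host_h, endo_h)
    if transports:
        pair = add_universal_transport(pair, transports)
    return Fixture(
        name,
        {host_h.id: host_h, endo_h.id: endo_h},
        gt,
        host_id=host_h.id,
        endo_id=endo_h.id,
        pair=pair,
    )


def _fx_pair_v() -> Fixture:
    host = _fx_toy_a().model
    endo = host.copy(new_id="TOY-A2")
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-A2": 10.0},
        expected_pair_growth=10.0,
    )
    return _pair_fixture("TOY-PAIR-V", host, endo, gt)


def _fx_pair_t() -> Fixture:
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-B": 10.0},
        expected_pair_growth=0.0,
        defect=Defect.TRANSPORT,
        rescuing_compounds={"N"},
    )
    return _pair_fixture("TOY-PAIR-T", _fx_toy_a().model, _fx_toy_b().model, gt)


def _fx_pair_t_fixed() -> Fixture:
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-B": 10.0},
        expected_pair_growth=10.0,
    )
    return _pair_fixture(
        "TOY-PAIR-T-FIXED", _fx_toy_a().model, _fx_toy_b().model, gt, transports=["N"]
    )


def _fx_pair_x() -> Fixture:
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-C": 10.0},
        expected_pair_growth=0.0,
        defect=Defect.ACCESS,
    )
    return _pair_fixture("TOY-PAIR-X", _fx_toy_a().model, _fx_toy_c().model, gt)


def _fx_pair_r() -> Fixture:
    # endosymbiont viable on either of two substrates: two redundant rescuers
    endo = _toy(
        "TOY-R",
        [
            ("T1_R", {("N1", "e"): -1.0, ("N1", "c"): 1.0}, 0.0, 100.0, False),
            ("C1_R", {("N1", "c"): -1.0, ("M", "c"): 1.0}, 0.0, 100.0, False),
            ("T2_R", {("N2", "e"): -1.0, ("N2", "c"): 1.0}, 0.0, 100.0, False),
            ("C2_R", {("N2", "c"): -1.0, ("M", "c"): 1.0}, 0.0, 100.0, False),
            ("BIO_R", {("M", "c"): -1.0}, 0.0, 100.0, True),
        ],
        {"N1": (-10.0, 0.0), "N2": (-10.0, 0.0)},
    )
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-R": 20.0},
        expected_pair_growth=0.0,
        defect=Defect.TRANSPORT,
        rescuing_compounds={"N1", "N2"},
    )
    return _pair_fixture("TOY-PAIR-R", _fx_toy_a().model, endo, gt)


def _fx_pair_j() -> Fixture:
    # endosymbiont needs two substrates jointly: minimal repair has size two
    endo = _toy(
        "TOY-J",
        [
            ("T1_J", {("N1", "e"): -1.0, ("N1", "c"): 1.0}, 0.0, 100.0, False),
            ("T2_J", {("N2", "e"): -1.0, ("N2", "c"): 1.0}, 0.0, 100.0, False),
            ("BIO_J", {("N1", "c"): -1.0, ("N2", "c"): -1.0}, 0.0, 100.0, True),
        ],
        {"N1": (-10.0, 0.0), "N2": (-10.0, 0.0)},
    )
    gt = GroundTruth(
        expected_solo_growth={"TOY-A": 10.0, "TOY-J": 10.0},
        expected_pair_growth=0.0,
        defect=Defect.TRANSPORT,
        rescuing_compounds={"N1", "N2"},
    )
    return _pair_fixture("TOY-PAIR-J", _fx_toy_a().model, endo, gt)


def _fx_comm_u() -> Fixture:
    fx = _fx_pair_t_fixed()
    fx.name = "TOY-COMM-U"
    fx.shared_env = Environment({"A": (-20.0, 0.0), "N": (-20.0, 0.0)})
    fx.ground_truth.expected_pair_growth = 10.0
    return fx


def _fx_comm_n() -> Fixture:
    fx = _fx_pair_v()
    fx.name = "TOY-COMM-N"
    fx.shared_env = Environment({"A": (-20.0, 0.0)})
    return fx


_FIXTURES = {
    "TOY-A": _fx_toy_a,
    "TOY-B": _fx_toy_b,
    "TOY-C": _fx_toy_c,
    "TOY-MUT": _fx_toy_mut,
    "TOY-PAIR-V": _fx_pair_v,
    "TOY-PAIR-T": _fx_pair_t,
    "TOY-PAIR-T-FIXED": _fx_pair_t_fixed,
    "TOY-PAIR-X": _fx_pair_x,
    "TOY-PAIR-R": _fx_pair_r,
    "TOY-PAIR-J": _fx_pair_j,
    "TOY-COMM-U": _fx_comm_u,
    "TOY-COMM-N": _fx_comm_n,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str) -> Fixture:
    """Build a named analytic fixture (models, pair system, ground truth)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ModelError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Random generator
# ---------------------------------------------------------------------------


def _build_chain_model(
    model_id: str,
    substrates: Sequence[str],
    params: GeneratorParams,
    rng: np.random.Generator,
    access_substrates: Sequence[str] = (),
    collection_tag: str = "synthetic",
) -> Tuple[MetabolicModel, float]:
    """Backbone + shortcuts; returns the model and its closed-form expected
    growth (exact when ``redundancy == 0``).

    Reaction capacities are drawn per reaction from
    ``[0.5, 1.0] * bound_magnitude`` (heterogeneous bounds, as in curated
    collections, so that in the bound-limited regime individual reactions
    are bottlenecks).  ``access_substrates`` are consumed directly from the
    e-compartment (no cytoplasmic copy anywhere), the engineered
    access-type defect.  Closed form:
    ``min(biomass_cap, min_k min(availability, chain_cap_k) / demand_k)``.
    """
    reactions: List[Tuple[str, Dict[Tuple[str, str], float], float, float, bool]] = []
    biomass_stoich: Dict[Tuple[str, str], float] = {}
    internal: List[Tuple[str, str]] = []
    chain_limits: List[float] = []

    def draw_bound() -> float:
        return float(rng.uniform(0.5, 1.0) * params.bound_magnitude)

    def demand() -> float:
        return float(rng.uniform(0.5, 2.0)) if params.heterogeneous_biomass else 1.0

    for sub in substrates:
        chain = [(sub, "c")] + [
            (f"{model_id}.{sub}.I{level}", "c") for level in range(1, params.pathway_depth)
        ]
        internal.extend(chain)
        caps = [draw_bound() for _ in range(params.pathway_depth)]
        reactions.append(
            (f"T_{sub}.{model_id}", {(sub, "e"): -1.0, chain[0]: 1.0}, 0.0, caps[0], False)
        )
        for level in range(1, params.pathway_depth):
            reactions.append(
                (
                    f"C_{sub}.{level}.{model_id}",
                    {chain[level - 1]: -1.0, chain[level]: 1.0},
                    0.0,
                    caps[level],
                    False,
                )
            )
        coef = demand()
        biomass_stoich[chain[-1]] = -coef
        chain_limits.append(min(params.env_availability, min(caps)) / coef)
    for sub in access_substrates:
        precursor = (f"{model_id}.{sub}.P", "c")
        internal.append(precursor)
        cap = draw_bound()
        reactions.append(
            (f"U_{sub}.{model_id}", {(sub, "e"): -1.0, precursor: 1.0}, 0.0, cap, False)
        )
        coef = demand()
        biomass_stoich[precursor] = -coef
        chain_limits.append(min(params.env_availability, cap) / coef)
    for k in range(params.redundancy):
        if len(internal) < 2:
            break  # no distinct compound pair to connect
        i, j = rng.choice(len(internal), size=2, replace=False)
        reactions.append(
            (
                f"X_{k}.{model_id}",
                {internal[int(i)]: -1.0, internal[int(j)]: 1.0},
                0.0,
                draw_bound(),
                False,
            )
        )
    biomass_cap = draw_bound()
    reactions.append((f"BIO.{model_id}", dict(biomass_stoich), 0.0, biomass_cap, True))
    env = {
        sub: (-params.env_availability, 0.0)
        for sub in list(substrates) + list(access_substrates)
    }
    extra = [(f"U{k}", "e") for k in range(params.n_unused_env)]
    for base_id, _ in extra:
        env[base_id] = (-params.env_availability, 0.0)
    model = _toy(
        model_id, reactions, env, collection_tag=collection_tag, extra_compounds=extra
    )
    expected = min(biomass_cap, min(chain_limits))
    return model, expected


def generate_model(
    params: GeneratorParams,
    model_id: str = "synthetic-0",
    substrates: Optional[Sequence[str]] = None,
    collection_tag: str = "synthetic",
) -> Tuple[MetabolicModel, GroundTruth]:
    """A guaranteed-viable random model with a closed-form expected growth.

    Expected growth (exact for ``redundancy == 0``) is
    ``min(min_k availability/demand_k, bound_magnitude)`` — the tighter of
    the environment and the chain capacity.  The model is verified viable by
    FBA before return; a failed verification regenerates with a perturbed
    seed (up to 10 attempts).
    """
    substrates = list(substrates) if substrates is not None else [
        f"S{i}" for i in range(params.n_env_substrates)
    ]
    last_error: Optional[str] = None
    for attempt in range(10):
        rng = np.random.default_rng((params.seed + 1000003 * attempt) % 2**31)
        model, expected = _build_chain_model(
            model_id, substrates, params, rng, collection_tag=collection_tag
        )
        growth = maximize_growth(model).growth
        if growth >= VIABILITY_TOLERANCE:
            gt = GroundTruth(expected_solo_growth={model_id: expected})
            return model, gt
        last_error = f"growth {growth} below tolerance"
        logger.warning(
            "generated model %s failed FBA verification (attempt %d): %s",
            model_id, attempt, last_error,
        )
    raise ModelError(f"could not generate a viable model {model_id!r}: {last_error}")


def generate_pair_with_defect(
    params: GeneratorParams,
    defect: Defect = Defect.NONE,
    n_deficits: int = 1,
    host_id: str = "host",
    endo_id: str = "endo",
    collection_tag: str = "synthetic",
    validate: bool = True,
) -> Tuple[MetabolicModel, MetabolicModel, GroundTruth]:
    """A host-endosymbiont pair with an engineered nonviability cause.

    ``Defect.NONE``      the endosymbiont lives on the host's own substrates
                         (which the host already transports): viable pair.
    ``Defect.TRANSPORT`` the endosymbiont additionally requires substrates
                         the host cannot move into its cytoplasm; the
                         recorded rescuing compounds are exactly the missing
                         transports.
    ``Defect.ACCESS``    the endosymbiont consumes a compound straight from
                         the e-compartment, with no cytoplasmic counterpart
                         anywhere: unfixable by transport.
    ``Defect.BOTH``      both edits.
    """
    if n_deficits < 1:
        raise ModelError("n_deficits must be >= 1")
    shared = [f"S{i}" for i in range(params.n_env_substrates)]
    host, host_gt = generate_model(
        params, host_id, substrates=shared, collection_tag=collection_tag
    )
    rng = np.random.default_rng((params.seed * 2 + 1) % 2**31)

    extra_transport: List[str] = []
    extra_access: List[str] = []
    if defect in (Defect.TRANSPORT, Defect.BOTH):
        extra_transport = [f"NX{k}.{endo_id}" for k in range(n_deficits)]
    if defect in (Defect.ACCESS, Defect.BOTH):
        extra_access = [f"DX{k}.{endo_id}" for k in range(n_deficits)]
    endo, endo_expected = _build_chain_model(
        endo_id,
        shared + extra_transport,
        params,
        rng,
        access_substrates=extra_access,
        collection_tag=collection_tag,
    )
    gt = GroundTruth(
        expected_solo_growth={
            host_id: host_gt.expected_solo_growth[host_id],
            endo_id: endo_expected,
        },
        defect=defect,
        rescuing_compounds=set(extra_transport),
    )
    if validate:
        _validate_pair_labels(host, endo, gt)
    return host, endo, gt


def _validate_pair_labels(
    host: MetabolicModel, endo: MetabolicModel, gt: GroundTruth
) -> None:
    """Self-validation: confirm the recorded defect label by running the
    diagnosis LPs on the emitted pair."""
    host_h, endo_h = harmonize_namespace([host, endo])
    pair = build_pair(host_h, endo_h)
    growth = maximize_pair_growth(pair).growth
    viable = growth >= VIABILITY_TOLERANCE
    if gt.defect is Defect.NONE:
        if not viable:
            raise ModelError("defect-free pair generated nonviable")
        return
    if viable:
        raise ModelError(f"pair labelled {gt.defect} generated viable")
    candidates = candidate_transport_compounds(pair)
    repaired = add_universal_transport(pair, sorted(candidates))
    transport_fixes = maximize_pair_growth(repaired).growth >= VIABILITY_TOLERANCE
    if gt.defect is Defect.TRANSPORT and not transport_fixes:
        raise ModelError("transport-deficient pair not fixable by transport")
    if gt.defect in (Defect.ACCESS, Defect.BOTH) and transport_fixes:
        raise ModelError("access-deficient pair unexpectedly fixable by transport")
    if gt.defect is Defect.TRANSPORT and not gt.rescuing_compounds <= candidates:
        raise ModelError("rescuing compounds missing from the candidate set")


def generate_collection(
    n_models: int,
    params: GeneratorParams,
    p_defective: float = 0.0,
    collection_tag: str = "synthetic",
) -> List[MetabolicModel]:
    """A harmonized collection of random models sharing substrate names.

    With probability ``p_defective`` a model carries one private extra
    substrate that no other model can transport; such a model is viable on
    its own but makes any pairing in which it is the endosymbiont
    transport-deficient, giving the collection a known expected fraction of
    nonviable directed pairs.
    """
    if n_models < 1:
        raise ModelError("n_models must be >= 1")
    rng = np.random.default_rng(params.seed % 2**31)
    shared = [f"S{i}" for i in range(params.n_env_substrates)]
    models: List[MetabolicModel] = []
    for m in range(n_models):
        model_id = f"{collection_tag}-{m:03d}"
        subs = list(shared)
        if rng.random() < p_defective:
            subs.append(f"PRIV.{model_id}")
        sub_params = GeneratorParams(
            n_env_substrates=params.n_env_substrates,
            pathway_depth=params.pathway_depth,
            redundancy=params.redundancy,
            env_availability=params.env_availability,
            bound_magnitude=params.bound_magnitude,
            seed=int(rng.integers(2**31 - 1)),
            heterogeneous_biomass=params.heterogeneous_biomass,
            n_unused_env=params.n_unused_env,
        )
        model, _ = generate_model(
            sub_params, model_id, substrates=subs, collection_tag=collection_tag
        )
        models.append(model)
    return harmonize_namespace(models)
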
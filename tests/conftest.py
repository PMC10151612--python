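"""Shared fixtures: analytic toy models and small seeded synthetic
collections.  Everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import endoflux as ef
from endoflux.core import Compound, MetabolicModel, Reaction


@pytest.fixture
def toy():
    """Factory for the named analytic fixtures."""
    return ef.make_fixture


@pytest.fixture(scope="session")
def small_collection():
    """12 harmonized synthetic models, ~40% carrying a private substrate
    that makes them nonviable as endosymbionts."""
    return ef.generate_collection(
        12, ef.GeneratorParams(seed=1), p_defective=0.4
    )


@pytest.fixture
def raw_toy_a() -> MetabolicModel:
    """Raw (pre-externalization) three-reaction chain with an exchange sink
    for its substrate: A[e] -> A[c] -> B[c] -> biomass, uptake 10."""
    A_e, A_c, B_c = Compound("A", "e"), Compound("A", "c"), Compound("B", "c")
    return MetabolicModel(
        id="TOY-A-RAW",
        compounds=sorted([A_e, A_c, B_c]),
        reactions=[
            Reaction("T_A", {A_e: -1.0, A_c: 1.0}, 0.0, 100.0),
            Reaction("R_A", {A_c: -1.0, B_c: 1.0}, 0.0, 100.0),
            Reaction("BIO_A", {B_c: -1.0}, 0.0, 100.0, is_biomass=True),
            Reaction("EX_A", {A_e: -1.0}, -10.0, 0.0, is_exchange=True),
        ],
        env_lower=np.zeros(3),
        env_upper=np.zeros(3),
        biomass_index=2,
        collection_tag="toy",
    )


def de_externalize(model: MetabolicModel) -> MetabolicModel:
    """Inverse restructuring: turn environment bounds back into exchange
    sink reactions (used to exercise externalization on generated models)."""
    out = model.copy(new_id=f"{model.id}-raw")
    for base_id, (a, b) in sorted(model.environment.bounds.items()):
        out.reactions.append(
            Reaction(
                id=f"EX_{base_id}",
                stoichiometry={Compound(base_id, "e"): -1.0},
                lower_bound=a,
                upper_bound=b,
                is_exchange=True,
            )
        )
    return MetabolicModel(
        id=out.id,
        compounds=list(out.compounds),
        reactions=out.reactions,
        env_lower=np.zeros(len(out.compounds)),
        env_upper=np.zeros(len(out.compounds)),
        biomass_index=out.biomass_index,
        collection_tag=out.collection_tag,
    )
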
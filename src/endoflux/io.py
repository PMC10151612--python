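"""Reading and writing metabolic models.

Three on-disk forms:

* the *toy TSV* dialect — a hand-writable sectioned tab-separated format
  with exact coefficients, used for the analytic fixtures;
* SBML Level 3 with the flux-bounds/objective (fbc) extension, for
  interoperability with curated model collections;
* a collection archive (one JSON metadata file plus one MatrixMarket file
  per model) for harmonized collections.

Raw models carry exchange pseudo-reactions (ids prefixed ``EX_``); after
:func:`endoflux.core.externalize_environment` those become derivative
bounds, and the writers synthesize equivalent sink reactions on export so
that a write/load/externalize round trip is the identity.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import io as scipy_io
from scipy import sparse

from .core import Compound, MetabolicModel, ModelError, Reaction

Pathish = Union[str, os.PathLike]

_TSV_SECTIONS = ("model", "compounds", "reactions", "stoichiometry", "environment")


# ---------------------------------------------------------------------------
# Toy TSV dialect
# ---------------------------------------------------------------------------


def load_toy_tsv(path: Pathish) -> MetabolicModel:
    """Parse the sectioned toy TSV dialect into a (possibly raw) model."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ModelError(f"cannot read model file {path}: {exc}") from exc
    section = None
    meta: Dict[str, str] = {}
    compounds: List[Compound] = []
    rxn_rows: List[Tuple[str, float, float, set]] = []
    stoich: Dict[str, Dict[Compound, float]] = {}
    env: Dict[str, Tuple[float, float]] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if section not in _TSV_SECTIONS:
                raise ModelError(f"{path}:{lineno}: unknown section [{section}]")
            continue
        fields = line.split("\t")
        if section == "model":
            meta[fields[0]] = fields[1]
        elif section == "compounds":
            compounds.append(Compound(fields[0], fields[1]))
        elif section == "reactions":
            flags = set(fields[3].split(",")) if len(fields) > 3 and fields[3] else set()
            rxn_rows.append((fields[0], float(fields[1]), float(fields[2]), flags))
        elif section == "stoichiometry":
            rid, base, comp, coef = fields[0], fields[1], fields[2], float(fields[3])
            stoich.setdefault(rid, {})[Compound(base, comp)] = coef
        elif section == "environment":
            env[fields[0]] = (float(fields[1]), float(fields[2]))
        else:
            raise ModelError(f"{path}:{lineno}: content outside any section")
    if "id" not in meta:
        raise ModelError(f"{path}: missing model id")
    reactions = []
    for rid, lb, ub, flags in rxn_rows:
        if rid not in stoich:
            raise ModelError(f"{path}: reaction {rid!r} has no stoichiometry")
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich[rid],
                lower_bound=lb,
                upper_bound=ub,
                is_biomass="biomass" in flags,
                is_exchange="exchange" in flags,
            )
        )
    biomass = [i for i, r in enumerate(reactions) if r.is_biomass]
    if len(biomass) != 1:
        raise ModelError(
            f"{path}: exactly one biomass reaction required, found {len(biomass)}"
        )
    if not compounds:
        compounds = sorted({c for r in reactions for c in r.stoichiometry})
    lo = np.zeros(len(compounds))
    hi = np.zeros(len(compounds))
    index = {c: i for i, c in enumerate(compounds)}
    for base_id, (a, b) in env.items():
        compound = Compound(base_id, "e")
        if compound not in index:
            raise ModelError(f"{path}: environment entry for unknown compound {base_id!r}")
        lo[index[compound]], hi[index[compound]] = a, b
    return MetabolicModel(
        id=meta["id"],
        compounds=compounds,
        reactions=reactions,
        env_lower=lo,
        env_upper=hi,
        biomass_index=biomass[0],
        collection_tag=meta.get("collection", "default"),
    )


def write_toy_tsv(model: MetabolicModel, path: Pathish) -> None:
    lines = ["[model]", f"id\t{model.id}", f"collection\t{model.collection_tag}"]
    lines.append("[compounds]")
    for c in model.compounds:
        lines.append(f"{c.base_id}\t{c.compartment}")
    lines.append("[reactions]")
    for r in model.reactions:
        flags = ",".join(
            f for f, on in (("biomass", r.is_biomass), ("exchange", r.is_exchange)) if on
        )
        lines.append(f"{r.id}\t{r.lower_bound:.17g}\t{r.upper_bound:.17g}\t{flags}")
    lines.append("[stoichiometry]")
    for r in model.reactions:
        for c, v in sorted(r.stoichiometry.items()):
            lines.append(f"{r.id}\t{c.base_id}\t{c.compartment}\t{v:.17g}")
    env = model.environment
    if env.bounds:
        lines.append("[environment]")
        for base_id, (a, b) in sorted(env.bounds.items()):
            lines.append(f"{base_id}\t{a:.17g}\t{b:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

_SID_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(text: str) -> str:
    sid = _SID_SAFE.sub("_", text)
    return sid if sid and not sid[0].isdigit() else f"_{sid}"


def write_sbml(model: MetabolicModel, path: Pathish) -> None:
    """Serialize to SBML L3V1 with the fbc (version 2) extension.

    Externalized environments are encoded as synthesized ``EX_`` sink
    reactions carrying the derivative bounds, the standard interchange
    convention; original compound names are kept in species ``name``
    attributes so sanitized ids round-trip."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_sid(model.id))
    sb.setName(model.id)
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(False)
    sb.appendAnnotation(f"<collection xmlns='https://endoflux/ns'>{model.collection_tag}</collection>")
    for comp_id in sorted({c.compartment for c in model.compounds}):
        comp = sb.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
    species_id: Dict[Compound, str] = {}
    for c in model.compounds:
        sp = sb.createSpecies()
        sid = f"M_{_sid(c.base_id)}_{c.compartment}"
        species_id[c] = sid
        sp.setId(sid)
        sp.setName(c.base_id)
        sp.setCompartment(c.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    def add_parameter(pid: str, value: float) -> str:
        p = sb.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    def add_reaction(rid: str, name: str, stoich: Dict[Compound, float],
                     lb: float, ub: float) -> None:
        rx = sb.createReaction()
        rx.setId(rid)
        rx.setName(name)
        rx.setReversible(lb < 0)
        rx.setFast(False)
        for compound, coef in stoich.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(species_id[compound])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(add_parameter(f"{rid}_lb", lb))
        rplug.setUpperFluxBound(add_parameter(f"{rid}_ub", ub))

    for r in model.reactions:
        rid = f"EX_{_sid(r.id)}" if r.is_exchange and not r.id.startswith("EX_") else _sid(r.id)
        add_reaction(rid, r.id, r.stoichiometry, r.lower_bound, r.upper_bound)
    # synthesize sink reactions for an externalized environment
    for base_id, (a, b) in sorted(model.environment.bounds.items()):
        compound = Compound(base_id, "e")
        add_reaction(f"EX_{_sid(base_id)}_env", f"EX_{base_id}_env",
                     {compound: -1.0}, a, b)
    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(_sid(model.biomass_reaction.id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"failed to write SBML to {path}")


def load_sbml(path: Pathish) -> MetabolicModel:
    """Load an SBML L3 + fbc model as a *raw* model (exchange reactions
    flagged, environment not yet externalized)."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError(
            f"unreadable SBML file {path}: "
            f"{doc.getError(0).getMessage() if doc.getNumErrors() else 'unknown error'}"
        )
    sb = doc.getModel()
    if sb is None:
        raise ModelError(f"no model element in {path}")
    collection = "default"
    if sb.isSetAnnotation():
        m = re.search(r"<collection[^>]*>([^<]+)</collection>", sb.getAnnotationString())
        if m:
            collection = m.group(1)
    compounds: Dict[str, Compound] = {}
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        comp = sp.getCompartment()
        if comp not in ("c", "e", "p"):
            raise ModelError(
                f"{path}: species {sp.getId()!r} in unknown compartment {comp!r}"
            )
        base = sp.getName() or sp.getId()
        compounds[sp.getId()] = Compound(base, comp)
    mplug = sb.getPlugin("fbc")
    objective_rxns: List[str] = []
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient() != 0:
                objective_rxns.append(fo.getReaction())
    if len(objective_rxns) != 1:
        raise ModelError(
            f"{path}: exactly one objective (biomass) reaction required, "
            f"found {len(objective_rxns)}"
        )
    reactions: List[Reaction] = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: Dict[Compound, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            c = compounds[ref.getSpecies()]
            stoich[c] = stoich.get(c, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            c = compounds[ref.getSpecies()]
            stoich[c] = stoich.get(c, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -float("inf"), float("inf")
        if rplug is not None:
            lbp = sb.getParameter(rplug.getLowerFluxBound())
            ubp = sb.getParameter(rplug.getUpperFluxBound())
            if lbp is not None:
                lb = lbp.getValue()
            if ubp is not None:
                ub = ubp.getValue()
        reactions.append(
            Reaction(
                id=rx.getName() or rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_biomass=rx.getId() == objective_rxns[0],
                is_exchange=rx.getId().startswith("EX_"),
            )
        )
    namespace = sorted(set(compounds.values()))
    biomass = [i for i, r in enumerate(reactions) if r.is_biomass]
    return MetabolicModel(
        id=sb.getName() or sb.getId(),
        compounds=namespace,
        reactions=reactions,
        env_lower=np.zeros(len(namespace)),
        env_upper=np.zeros(len(namespace)),
        biomass_index=biomass[0],
        collection_tag=collection,
    )


def load_model(path: Pathish, dialect: Optional[str] = None) -> MetabolicModel:
    """Load a model file; ``dialect`` is ``"toy_tsv"`` or ``"sbml_fbc"``
    (inferred from the extension when omitted)."""
    if dialect is None:
        dialect = "sbml_fbc" if str(path).endswith((".xml", ".sbml")) else "toy_tsv"
    if dialect == "toy_tsv":
        return load_toy_tsv(path)
    if dialect == "sbml_fbc":
        return load_sbml(path)
    raise ModelError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Harmonized collection archive
# ---------------------------------------------------------------------------


def save_collection(models: Sequence[MetabolicModel], directory: Pathish) -> None:
    """Write a harmonized collection: shared namespace and per-model
    metadata in ``collection.json``, stoichiometries as MatrixMarket text."""
    if not models:
        raise ModelError("empty collection")
    namespace = models[0].compounds
    for m in models:
        if m.compounds != namespace:
            raise ModelError("collection must be harmonized before saving")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": 1,
        "collection_tag": models[0].collection_tag,
        "namespace": [[c.base_id, c.compartment] for c in namespace],
        "models": [],
    }
    for m in models:
        meta["models"].append(
            {
                "id": m.id,
                "matrix_file": f"{_sid(m.id)}.mtx",
                "biomass_index": m.biomass_index,
                "reactions": [
                    {
                        "id": r.id,
                        "lower_bound": r.lower_bound,
                        "upper_bound": r.upper_bound,
                        "is_biomass": r.is_biomass,
                        "is_exchange": r.is_exchange,
                    }
                    for r in m.reactions
                ],
                "environment": {
                    c.base_id: [float(m.env_lower[i]), float(m.env_upper[i])]
                    for i, c in enumerate(namespace)
                    if m.env_lower[i] != 0.0 or m.env_upper[i] != 0.0
                },
            }
        )
        scipy_io.mmwrite(directory / f"{_sid(m.id)}.mtx", sparse.coo_matrix(m.S))
    (directory / "collection.json").write_text(json.dumps(meta, indent=1))


def load_collection(directory: Pathish) -> List[MetabolicModel]:
    directory = Path(directory)
    meta = json.loads((directory / "collection.json").read_text())
    namespace = [Compound(b, c) for b, c in meta["namespace"]]
    index = {c: i for i, c in enumerate(namespace)}
    models: List[MetabolicModel] = []
    for entry in meta["models"]:
        S = sparse.csc_array(scipy_io.mmread(directory / entry["matrix_file"]))
        reactions = []
        for j, rmeta in enumerate(entry["reactions"]):
            col = S[:, [j]].tocoo()
            stoich = {namespace[i]: float(v) for i, v in zip(col.row, col.data)}
            reactions.append(
                Reaction(
                    id=rmeta["id"],
                    stoichiometry=stoich,
                    lower_bound=rmeta["lower_bound"],
                    upper_bound=rmeta["upper_bound"],
                    is_biomass=rmeta["is_biomass"],
                    is_exchange=rmeta["is_exchange"],
                )
            )
        lo = np.zeros(len(namespace))
        hi = np.zeros(len(namespace))
        for base_id, (a, b) in entry["environment"].items():
            i = index[Compound(base_id, "e")]
            lo[i], hi[i] = a, b
        models.append(
            MetabolicModel(
                id=entry["id"],
                compounds=list(namespace),
                reactions=reactions,
                env_lower=lo,
                env_upper=hi,
                biomass_index=entry["biomass_index"],
                collection_tag=meta["collection_tag"],
            )
        )
    return models
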
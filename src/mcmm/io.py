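"""Readers and writers for taxon models (JSON dialect and SBML L3+FBC).

The JSON dialect is the canonical internal format; its schema is documented in
``docs/model_schema.md``. SBML Level 3 with the FBC package is supported for
interoperability: bounds become FBC flux-bound parameters, the biomass
reaction becomes the (maximized) FBC objective, and metabolite formulas map to
``fbc:chemicalFormula``. Exchange reactions are written with the ``EX_``
prefix and a single reactant; models using the opposite secretion sign
convention (single product) are normalized on load so that positive flux
always means secretion.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml

from .gem_core import Metabolite, Reaction, TaxonModel, ValidationError

__all__ = ["load_taxon_model", "write_model", "model_to_dict", "model_from_dict"]

_FLAG_KEYS = ("host_absorbable", "host_supplied", "residual_fiber",
              "carbon_source_override")


class FormatError(ValueError):
    """Unparseable model file; message names the offending element."""


# ---------------------------------------------------------------- JSON

def model_to_dict(model: TaxonModel) -> dict:
    return {
        "taxon_id": model.taxon_id,
        "rank": model.rank,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "annotations": m.annotations,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "exchange": r.is_exchange,
                "biomass": r.is_biomass,
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> TaxonModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "e"),
                formula=m.get("formula"),
                annotations=dict(m.get("annotations", {})),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                is_exchange=bool(r.get("exchange", False)),
                is_biomass=bool(r.get("biomass", False)),
            )
            for r in data["reactions"]
        ]
        taxon_id = data["taxon_id"]
        rank = data.get("rank", "genus")
    except (KeyError, TypeError, ValueError) as err:
        raise FormatError(f"malformed model JSON: {err!r}") from err
    return TaxonModel.from_parts(taxon_id, mets, rxns, rank=rank)


# ---------------------------------------------------------------- SBML

def _notes_string(pairs: dict) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return (
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _parse_notes(node) -> dict:
    if node is None or not node.isSetNotes():
        return {}
    text = node.getNotesString()
    return dict(re.findall(r"<p>\s*([\w]+)\s*:\s*([^<]*?)\s*</p>", text))


def _write_sbml(model: TaxonModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.taxon_id))
    sbml_model.setName(model.taxon_id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)
    sbml_model.setNotes(_notes_string({"rank": model.rank,
                                       "taxon_id": model.taxon_id}))

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(_sid(comp_id))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)
        flags = {k: v for k, v in met.annotations.items() if k in _FLAG_KEYS and v}
        if flags:
            sp.setNotes(_notes_string(flags))

    def bound_param(value: float) -> str:
        pid = "b_" + re.sub(r"[^\w]", "_", f"{value:.10g}")
        if sbml_model.getParameter(pid) is None:
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId(_sid(rxn.id))
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid(met))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(_sid(model.biomass_reaction_id))
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _sid(raw: str) -> str:
    """SBML SId-safe identifier (round-trips for our id conventions)."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    return sid if re.match(r"[A-Za-z_]", sid) else "_" + sid


def _read_sbml(path: Path) -> TaxonModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise FormatError(
            f"SBML parse error line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML file contains no model element")
    mplug = sbml_model.getPlugin("fbc")

    model_notes = _parse_notes(sbml_model)
    taxon_id = model_notes.get("taxon_id", sbml_model.getId())
    rank = model_notes.get("rank", "genus")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula() or None
        annotations = {
            k: True for k, v in _parse_notes(sp).items()
            if k in _FLAG_KEYS and v.lower() in ("true", "1", "yes")
        }
        mets.append(Metabolite(sp.getId(), sp.getName(), sp.getCompartment(),
                               formula, annotations))

    biomass_ids = set()
    if mplug is not None and mplug.getActiveObjective() is not None:
        for i in range(mplug.getActiveObjective().getNumFluxObjectives()):
            biomass_ids.add(
                mplug.getActiveObjective().getFluxObjective(i).getReaction()
            )

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rplug is not None:
            lo = sbml_model.getParameter(rplug.getLowerFluxBound())
            hi = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lo is not None:
                lb = lo.getValue()
            if hi is not None:
                ub = hi.getValue()
        is_exchange = len(stoich) == 1 and rx.getId().startswith("EX_")
        if is_exchange and next(iter(stoich.values())) > 0:
            # opposite sign convention (positive = uptake): normalize
            stoich = {k: -v for k, v in stoich.items()}
            lb, ub = -ub, -lb
        rxns.append(
            Reaction(rx.getId(), stoich, lb, ub,
                     is_exchange=is_exchange,
                     is_biomass=rx.getId() in biomass_ids)
        )
    return TaxonModel.from_parts(taxon_id, mets, rxns, rank=rank)


# ---------------------------------------------------------------- API

def write_model(model: TaxonModel, path, format: str | None = None) -> None:
    """Write a taxon model as JSON (canonical) or SBML L3+FBC."""
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def load_taxon_model(path, format: str | None = None) -> TaxonModel:
    """Load a taxon model, validating structural invariants.

    Raises :class:`FormatError` on parse failure and
    :class:`~mcmm.gem_core.ValidationError` on invariant violations
    (no/multiple biomass reactions, dangling metabolite references).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as err:
            raise FormatError(f"{path}: line {err.lineno}: {err.msg}") from err
        return model_from_dict(data)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")
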
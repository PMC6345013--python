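"""Model serialization: SBML Level 3 + fbc, a JSON dialect, and TSV tables.

All three formats round-trip ids, names, bounds, GPR strings, kinds,
subsystems and the objective.  Stoichiometric coefficients are exact
rationals in memory; JSON and TSV serialize them as decimal strings when
the denominator is 10-smooth and as ``p/q`` otherwise, so the round trip
is exact.  SBML stores coefficients as doubles read back through their
shortest decimal representation, which is exact for every coefficient the
bundled fixtures produce.

The TSV dialect is a directory holding ``reactions.tsv`` (id, name,
equation, lower_bound, upper_bound, gpr, subsystem, kind),
``metabolites.tsv`` (id, name, formula, charge, compartment) and a small
``model.tsv`` key-value table (model id, objective, compartment names).
"""

from __future__ import annotations

import json
import re
from fractions import Fraction
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .core import (MetabolicModel, Metabolite, Reaction, as_coefficient,
                   format_coefficient)

__all__ = ["read_model", "write_model", "ModelIOError"]


class ModelIOError(ValueError):
    """Raised for unreadable or inconsistent model files."""


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    if path.is_dir() or path.suffix == "" :
        return "tsv"
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ModelIOError(f"cannot infer model format from {path}")


def read_model(path, fmt: Optional[str] = None) -> MetabolicModel:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        return _read_json(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ModelIOError(f"unknown format {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelIOError(f"unknown format {fmt!r}")


def _build_model(model_id, name, compartments, metabolites, reactions,
                 objective, notes) -> MetabolicModel:
    """Assemble and validate, collecting unknown-metabolite offenders."""
    model = MetabolicModel(model_id, name)
    model.compartments = dict(compartments)
    for met in metabolites:
        model.add_metabolite(met)
    for rxn in reactions:  # pre-register genes; files are the authority
        model.genes |= rxn.gpr.genes()
    offenders = []
    for rxn in reactions:
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            offenders.extend((rxn.id, m) for m in missing)
            continue
        model.add_reaction(rxn)
    if offenders:
        listing = "; ".join(f"{rid} -> {mid}" for rid, mid in offenders)
        raise ModelIOError(f"reactions reference unknown metabolites: {listing}")
    for rid, weight in objective.items():
        if rid not in model.reactions:
            raise ModelIOError(f"objective references unknown reaction {rid!r}")
    model.objective = {rid: float(w) for rid, w in objective.items()}
    model.notes = list(notes)
    model.validate()
    return model


# --------------------------------------------------------------------------
# JSON
# --------------------------------------------------------------------------


def _write_json(model: MetabolicModel, path: Path) -> None:
    payload = {
        "id": model.id,
        "name": model.name,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula,
             "charge": m.charge, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {mid: format_coefficient(c)
                               for mid, c in r.stoichiometry.items()},
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gpr": r.gpr.to_string(), "subsystem": r.subsystem,
             "kind": r.kind}
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "objective": model.objective,
        "notes": model.notes,
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")


def _read_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"malformed JSON model file {path}: {exc}") from exc
    metabolites = [
        Metabolite(m["id"], m.get("name", ""), m.get("formula", ""),
                   m.get("charge"), m.get("compartment", "c"))
        for m in payload.get("metabolites", [])
    ]
    reactions = [
        Reaction(r["id"], r.get("name", ""),
                 {mid: as_coefficient(c)
                  for mid, c in r["stoichiometry"].items()},
                 float(r["lower_bound"]), float(r["upper_bound"]),
                 r.get("gpr", ""), r.get("subsystem", ""),
                 r.get("kind", "metabolic"))
        for r in payload.get("reactions", [])
    ]
    model = _build_model(payload.get("id", "model"), payload.get("name", ""),
                         payload.get("compartments", {}), metabolites,
                         reactions, payload.get("objective", {}),
                         payload.get("notes", []))
    model.genes |= set(payload.get("genes", []))
    return model


# --------------------------------------------------------------------------
# TSV
# --------------------------------------------------------------------------

_ARROWS = ("<=>", "-->", "<--")


def _equation_string(rxn: Reaction) -> str:
    return rxn.equation()


def _parse_equation(text: str, reaction_id: str) -> Dict[str, Fraction]:
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelIOError(
            f"reaction {reaction_id!r}: equation {text!r} lacks an arrow")
    left, right = text.split(arrow, 1)
    stoich: Dict[str, Fraction] = {}

    def consume(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, mid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, mid = as_coefficient(parts[0]), parts[1]
            else:
                raise ModelIOError(
                    f"reaction {reaction_id!r}: cannot parse term {term!r}")
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff
    consume(left, -1)
    consume(right, +1)
    if arrow == "<--":
        stoich = {mid: -c for mid, c in stoich.items()}
    return stoich


_REACTION_COLUMNS = ["id", "name", "equation", "lower_bound", "upper_bound",
                     "gpr", "subsystem", "kind"]
_METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment"]


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [{"id": m.id, "name": m.name, "formula": m.formula,
          "charge": "" if m.charge is None else m.charge,
          "compartment": m.compartment}
         for m in model.metabolites.values()], columns=_METABOLITE_COLUMNS)
    rxns = pd.DataFrame(
        [{"id": r.id, "name": r.name, "equation": _equation_string(r),
          "lower_bound": repr(r.lower_bound), "upper_bound": repr(r.upper_bound),
          "gpr": r.gpr.to_string(), "subsystem": r.subsystem, "kind": r.kind}
         for r in model.reactions.values()], columns=_REACTION_COLUMNS)
    meta_rows = [("id", model.id), ("name", model.name)]
    meta_rows += [("compartment", f"{code}:{label}")
                  for code, label in model.compartments.items()]
    meta_rows += [("objective", f"{rid}:{weight!r}")
                  for rid, weight in model.objective.items()]
    meta_rows += [("note", note) for note in model.notes]
    meta = pd.DataFrame(meta_rows, columns=["key", "value"])
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)
    meta.to_csv(path / "model.tsv", sep="\t", index=False)


def _read_tsv(path: Path) -> MetabolicModel:
    path = Path(path)
    met_file = path / "metabolites.tsv"
    rxn_file = path / "reactions.tsv"
    if not met_file.exists() or not rxn_file.exists():
        raise ModelIOError(
            f"TSV model directory {path} must contain metabolites.tsv and "
            f"reactions.tsv")
    mets_df = pd.read_csv(met_file, sep="\t", dtype=str, keep_default_na=False)
    rxns_df = pd.read_csv(rxn_file, sep="\t", dtype=str, keep_default_na=False)
    for df, cols, fname in ((mets_df, _METABOLITE_COLUMNS, "metabolites.tsv"),
                            (rxns_df, _REACTION_COLUMNS, "reactions.tsv")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ModelIOError(f"{fname} is missing columns: {missing}")
    metabolites = [
        Metabolite(row["id"], row["name"], row["formula"],
                   None if row["charge"] == "" else int(row["charge"]),
                   row["compartment"])
        for row in mets_df.to_dict("records")
    ]
    reactions = []
    for row in rxns_df.to_dict("records"):
        try:
            lb, ub = float(row["lower_bound"]), float(row["upper_bound"])
        except ValueError as exc:
            raise ModelIOError(
                f"reaction {row['id']!r}: bad bounds "
                f"({row['lower_bound']!r}, {row['upper_bound']!r})") from exc
        reactions.append(Reaction(
            row["id"], row["name"], _parse_equation(row["equation"], row["id"]),
            lb, ub, row["gpr"], row["subsystem"], row["kind"]))
    model_id, name, compartments, objective, notes = "model", "", {}, {}, []
    meta_file = path / "model.tsv"
    if meta_file.exists():
        meta_df = pd.read_csv(meta_file, sep="\t", dtype=str,
                              keep_default_na=False)
        for row in meta_df.to_dict("records"):
            key, value = row["key"], row["value"]
            if key == "id":
                model_id = value
            elif key == "name":
                name = value
            elif key == "compartment":
                code, label = value.split(":", 1)
                compartments[code] = label
            elif key == "objective":
                rid, weight = value.rsplit(":", 1)
                objective[rid] = float(weight)
            elif key == "note":
                notes.append(value)
    return _build_model(model_id, name, compartments, metabolites, reactions,
                        objective, notes)


# --------------------------------------------------------------------------
# SBML (Level 3 Version 1 with the fbc version 2 package)
# --------------------------------------------------------------------------

_SID_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    return prefix + _SID_SAFE.sub("__", raw)


def _notes_xml(pairs: Dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items() if v != "")
    return ("<body xmlns=\"http://www.w3.org/1999/xhtml\">" + body + "</body>")


_NOTE_RE = re.compile(r"<p>\s*([^:<]+):\s*(.*?)\s*</p>", re.S)


def _parse_notes(notes_string: str) -> Dict[str, str]:
    return dict(_NOTE_RE.findall(notes_string or ""))


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sid("", model.id) or "model")
    smodel.setName(model.name)
    fbc = smodel.getPlugin("fbc")
    fbc.setStrict(False)
    if model.notes:
        smodel.setNotes(_notes_xml({f"note{i}": n
                                    for i, n in enumerate(model.notes)}))

    for code, label in model.compartments.items():
        comp = smodel.createCompartment()
        comp.setId(_sid("C_", code))
        comp.setName(label)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = smodel.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(_sid("C_", met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setNotes(_notes_xml({"original_id": met.id,
                                "compartment_code": met.compartment}))
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sfbc.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId(_sid("G_", gene))
        gp.setLabel(gene)

    def _bound_param(value: float, tag: str) -> str:
        pid = _sid("", f"bnd_{tag}")
        param = smodel.createParameter()
        param.setId(pid)
        param.setValue(float(value))
        param.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        sr = smodel.createReaction()
        rid = _sid("R_", rxn.id)
        sr.setId(rid)
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        sr.setNotes(_notes_xml({"original_id": rxn.id, "kind": rxn.kind,
                                "subsystem": rxn.subsystem}))
        for mid, coeff in rxn.stoichiometry.items():
            value = float(coeff)
            ref = sr.createReactant() if value < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", mid))
            ref.setStoichiometry(abs(value))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(rxn.lower_bound, f"{rid}_lb"))
        rfbc.setUpperFluxBound(_bound_param(rxn.upper_bound, f"{rid}_ub"))
        if not rxn.gpr.is_empty:
            # infix parsing requires SId-safe tokens, so write gene-product
            # ids (G_...) rather than labels (which may start with a digit)
            sid_gpr = rxn.gpr.substitute(
                {g: [_sid("G_", g)] for g in rxn.gpr.genes()})
            gpa = rfbc.createGeneProductAssociation()
            gpa.setAssociation(sid_gpr.to_string(), True, False)

    if model.objective:
        objective = fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        for rid, weight in model.objective.items():
            fo = objective.createFluxObjective()
            fo.setReaction(_sid("R_", rid))
            fo.setCoefficient(float(weight))
        fbc.setActiveObjectiveId("obj")

    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelIOError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelIOError(f"cannot read SBML file {path}: "
                           f"{doc.getErrorLog().toString()}")
    smodel = doc.getModel()
    if smodel is None:
        raise ModelIOError(f"SBML file {path} contains no model")
    fbc = smodel.getPlugin("fbc")

    comp_codes: Dict[str, str] = {}
    compartments: Dict[str, str] = {}
    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        code = comp.getId()[2:] if comp.getId().startswith("C_") else comp.getId()
        comp_codes[comp.getId()] = code
        compartments[code] = comp.getName() or code

    gene_labels: Dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    species_ids: Dict[str, str] = {}
    metabolites = []
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        notes = _parse_notes(sp.getNotesString() if sp.isSetNotes() else "")
        original = notes.get("original_id") or sp.getId()
        species_ids[sp.getId()] = original
        sfbc = sp.getPlugin("fbc")
        formula = sfbc.getChemicalFormula() if (
            sfbc is not None and sfbc.isSetChemicalFormula()) else ""
        charge = sfbc.getCharge() if (
            sfbc is not None and sfbc.isSetCharge()) else None
        metabolites.append(Metabolite(
            original, sp.getName(), formula, charge,
            notes.get("compartment_code",
                      comp_codes.get(sp.getCompartment(), "c"))))

    def _param_value(pid: str) -> float:
        param = smodel.getParameter(pid)
        if param is None:
            raise ModelIOError(f"missing flux-bound parameter {pid!r}")
        return param.getValue()

    reactions = []
    rxn_ids: Dict[str, str] = {}
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        notes = _parse_notes(sr.getNotesString() if sr.isSetNotes() else "")
        original = notes.get("original_id") or sr.getId()
        rxn_ids[sr.getId()] = original
        stoich: Dict[str, Fraction] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = species_ids[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, Fraction(0)) - as_coefficient(
                repr(ref.getStoichiometry()))
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = species_ids[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, Fraction(0)) + as_coefficient(
                repr(ref.getStoichiometry()))
        rfbc = sr.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound():
            raise ModelIOError(f"reaction {original!r} lacks fbc flux bounds")
        lb = _param_value(rfbc.getLowerFluxBound())
        ub = _param_value(rfbc.getUpperFluxBound())
        gpr = ""
        if rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = assoc.toInfix(True)
                for gid, label in gene_labels.items():
                    if gid != label:
                        gpr = re.sub(rf"(?<![A-Za-z0-9_]){re.escape(gid)}"
                                     rf"(?![A-Za-z0-9_])", label, gpr)
        reactions.append(Reaction(
            original, sr.getName(), stoich, lb, ub, gpr,
            notes.get("subsystem", ""), notes.get("kind", "metabolic")))

    objective = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            objective[rxn_ids[fo.getReaction()]] = fo.getCoefficient()

    model = _build_model(
        smodel.getId() or "model", smodel.getName(), compartments,
        metabolites, reactions, objective, [])
    model.genes |= set(gene_labels.values())
    return model
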
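"""SBML read/write for constraint-based models.

Uses the Level 2 dialect of the classic COBRA exports: flux bounds live
in kinetic-law parameters named ``LOWER_BOUND``/``UPPER_BOUND`` and the
GPR rule, subsystem and reaction kind are carried as
``GENE_ASSOCIATION:`` / ``SUBSYSTEM:`` / ``KIND:`` lines inside the
reaction notes. Writing renders GPRs in canonical form, so a
write-read-write round trip is byte-identical.
"""

from __future__ import annotations

import re

import libsbml

from .gpr import parse_gpr
from .model import (
    VMAX,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    infer_reaction_kind,
)

__all__ = ["read_sbml", "write_sbml", "SBMLReadError"]

_NOTE_RE = re.compile(r"(GENE_ASSOCIATION|SUBSYSTEM|KIND):\s*([^<\n]*)")


class SBMLReadError(ModelError):
    """Raised when an SBML document cannot be interpreted as a model."""


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize ``model`` as SBML Level 2 Version 4."""
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(model.id)

    for comp_id in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(False)
        sp.setInitialConcentration(0.0)

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setReversible(rxn.reversible)
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
        notes = (
            '<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>GENE_ASSOCIATION: {rxn.gpr.to_string()}</p>"
            f"<p>SUBSYSTEM: {rxn.subsystem}</p>"
            f"<p>KIND: {rxn.kind}</p>"
            "</body>"
        )
        if sr.setNotes(notes) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ModelError(f"reaction {rxn.id}: could not encode notes")
        kl = sr.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for name, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("FLUX_VALUE", 0.0),
        ):
            p = kl.createParameter()
            p.setId(name)
            p.setValue(value)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise ModelError(f"failed to write SBML to {path}")


def read_sbml(path: str) -> MetabolicModel:
    """Parse an SBML file written in the dialect of :func:`write_sbml`."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise SBMLReadError(f"{path}: not a parseable SBML document")
    sm = doc.getModel()
    model = MetabolicModel(
        id=sm.getId() or "model",
        compartments={
            sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())
        },
    )
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        name = sp.getName()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name="" if name == sp.getId() else name,
                compartment=sp.getCompartment(),
            )
        )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        for met_id in stoich:
            if not model.has_metabolite(met_id):
                raise SBMLReadError(
                    f"reaction {rid}: species reference to undeclared metabolite {met_id!r}"
                )

        fields = {"GENE_ASSOCIATION": "", "SUBSYSTEM": "", "KIND": ""}
        if sr.isSetNotes():
            notes_str = sr.getNotesString()
            for key, value in _NOTE_RE.findall(notes_str):
                fields[key] = value.strip()

        lb, ub = None, None
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        if lb is None:
            lb = -VMAX if sr.getReversible() else 0.0
        if ub is None:
            ub = VMAX

        try:
            gpr = parse_gpr(fields["GENE_ASSOCIATION"])
        except ValueError as exc:
            raise SBMLReadError(f"reaction {rid}: malformed GENE_ASSOCIATION ({exc})") from exc
        kind = fields["KIND"] or infer_reaction_kind(rid, stoich)
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=fields["SUBSYSTEM"],
                kind=kind,
            )
        )
    return model
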
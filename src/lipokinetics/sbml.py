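"""SBML Level 3 export of a reaction network.

The document has one compartment, one species per network species, global
parameters for the rate constants, mass-action kinetic laws (the
pit-normalised attachment channels carry their explicit rate expression
k_A * L_ex * P_i / (P_1 + ... + P_Nmax + 1)), and the wash as a discrete
event that empties the external-lipoplex pool at the incubation time.  The
writer emits the XML directly; :func:`read_sbml_summary` re-imports the
structure for round-trip checks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .network import ATTACH, WASH, ReactionNetwork

__all__ = ["export_sbml", "read_sbml_summary", "SBML_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(parent):
    return ET.SubElement(parent, f"{{{MATHML_NS}}}math")


def _apply(parent, op, *children_builders):
    ap = ET.SubElement(parent, f"{{{MATHML_NS}}}apply")
    ET.SubElement(ap, f"{{{MATHML_NS}}}{op}")
    for build in children_builders:
        build(ap)
    return ap


def _ci(name):
    def build(parent):
        el = ET.SubElement(parent, f"{{{MATHML_NS}}}ci")
        el.text = f" {name} "
    return build


def _cn(value):
    def build(parent):
        el = ET.SubElement(parent, f"{{{MATHML_NS}}}cn")
        el.text = f" {value} "
    return build


def export_sbml(network: ReactionNetwork, path) -> Path:
    """Write ``network`` as an SBML Level 3 Version 2 document.

    The wash is exported as an event (L_ex := 0 at t = t_inc) rather than a
    reaction, so the document holds len(reactions) - 1 reaction elements.
    """
    design = network.design
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          {"id": f"lipoplex_transfection_{network.variant}"})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", {
            "id": sp,
            "compartment": "cell",
            "initialAmount": str(design.L_ex0 if sp == "L_ex" else 0),
            "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "false",
            "constant": "false",
        })

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    seen = {}
    for r in network.reactions:
        pid = f"k_{r.label}"
        seen[r.label] = pid
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter",
                      {"id": pid, "value": repr(r.rate_constant), "constant": "true"})
    ET.SubElement(params_el, f"{{{SBML_NS}}}parameter",
                  {"id": "t_inc", "value": repr(design.t_inc), "constant": "true"})

    pit_species = [s for s in network.species if s == "P" or s.startswith("P_")]
    reactions_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        if r.rate_kind == WASH:
            continue
        rx = ET.SubElement(reactions_el, f"{{{SBML_NS}}}reaction",
                           {"id": f"r_{r.label}", "reversible": "false"})
        if r.reactants:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, n in r.reactants.items():
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(n), "constant": "true"})
        if r.products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, n in r.products.items():
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                              {"species": sp, "stoichiometry": str(n), "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = _math(kl)
        k = seen[r.label]
        if r.rate_kind == ATTACH:
            # k_A * L_ex * [P_i] / (sum of pits + 1)
            numerator_terms = [_ci(k), _ci("L_ex")]
            pit = [sp for sp in r.reactants if sp != "L_ex"]
            if pit:
                numerator_terms.append(_ci(pit[0]))

            def denom(parent):
                _apply(parent, "plus", *[_ci(sp) for sp in pit_species], _cn(1))

            _apply(math, "divide",
                   lambda p: _apply(p, "times", *numerator_terms), denom)
        else:
            reactant = next(iter(r.reactants))
            _apply(math, "times", _ci(k), _ci(reactant))

    events_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfEvents")
    ev = ET.SubElement(events_el, f"{{{SBML_NS}}}event",
                       {"id": "wash", "useValuesFromTriggerTime": "true"})
    trig = ET.SubElement(ev, f"{{{SBML_NS}}}trigger",
                         {"initialValue": "false", "persistent": "true"})
    _apply(_math(trig), "geq",
           lambda p: ET.SubElement(p, f"{{{MATHML_NS}}}csymbol", {
               "encoding": "text",
               "definitionURL": "http://www.sbml.org/sbml/symbols/time",
           }).__setattr__("text", " t "),
           _ci("t_inc"))
    assigns = ET.SubElement(ev, f"{{{SBML_NS}}}listOfEventAssignments")
    ea = ET.SubElement(assigns, f"{{{SBML_NS}}}eventAssignment", {"variable": "L_ex"})
    _math(ea).append(_make_cn_zero())

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
    return path


def _make_cn_zero():
    el = ET.Element(f"{{{MATHML_NS}}}cn")
    el.text = " 0 "
    return el


def read_sbml_summary(path) -> dict:
    """Structural re-import: ids and counts, used to validate an export."""
    tree = ET.parse(path)
    root = tree.getroot()
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise ValueError(f"not an SBML Level 3 document: root tag {root.tag!r}")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError("SBML document has no model element")
    species = [el.get("id") for el in model.findall(
        f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")]
    reactions = [el.get("id") for el in model.findall(
        f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction")]
    events = [el.get("id") for el in model.findall(
        f"{{{SBML_NS}}}listOfEvents/{{{SBML_NS}}}event")]
    for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        for attr in ("compartment", "initialAmount", "constant"):
            if el.get(attr) is None:
                raise ValueError(f"species {el.get('id')!r} missing attribute {attr!r}")
    return {
        "n_species": len(species),
        "n_reactions": len(reactions),
        "n_events": len(events),
        "species": species,
        "reactions": reactions,
    }
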
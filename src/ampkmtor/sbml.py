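"""SBML Level 3 export of the reaction network.

Writes the species, global parameters, and reactions (with MathML kinetic
laws) of a :class:`~ampkmtor.network.ReactionNetwork` as an SBML L3V2
document for interoperability with standard pathway tools.  Import is out
of scope.
"""

from __future__ import annotations

from pathlib import Path
from xml.etree import ElementTree as ET

from .network import CONSERVATION_GROUPS, ReactionNetwork, default_initial_state

__all__ = ["to_sbml", "write_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(*factors: str, denominators: list[tuple[str, str]] = ()) -> ET.Element:
    """MathML for k * f1 * ... / prod((K_i + X_i))."""
    math = ET.Element(f"{{{MATHML_NS}}}math")
    top = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    if denominators:
        ET.SubElement(top, f"{{{MATHML_NS}}}divide")
        num = ET.SubElement(top, f"{{{MATHML_NS}}}apply")
        ET.SubElement(num, f"{{{MATHML_NS}}}times")
        for f in factors:
            ET.SubElement(num, f"{{{MATHML_NS}}}ci").text = f
        den = ET.SubElement(top, f"{{{MATHML_NS}}}apply")
        ET.SubElement(den, f"{{{MATHML_NS}}}times")
        for k_name, x_name in denominators:
            term = ET.SubElement(den, f"{{{MATHML_NS}}}apply")
            ET.SubElement(term, f"{{{MATHML_NS}}}plus")
            ET.SubElement(term, f"{{{MATHML_NS}}}ci").text = k_name
            ET.SubElement(term, f"{{{MATHML_NS}}}ci").text = x_name
        if len(denominators) == 1:
            # unwrap the single-term times
            den.remove(den[0])
            only = term
            den.clear()
            for child in only:
                den.append(child)
    else:
        ET.SubElement(top, f"{{{MATHML_NS}}}times")
        for f in factors:
            ET.SubElement(top, f"{{{MATHML_NS}}}ci").text = f
    return math


def to_sbml(network: ReactionNetwork, model_id: str = "ampk_mtor_signaling") -> str:
    """Serialize the network as an SBML L3V2 document string."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", attrib={"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", attrib={"id": model_id})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment", attrib={
        "id": "cell", "size": "1", "constant": "true", "spatialDimensions": "3",
    })

    y0 = default_initial_state(network.params)
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for name, init in zip(network.species, y0):
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", attrib={
            "id": name, "compartment": "cell",
            "initialConcentration": repr(float(init)),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false",
        })

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, value in sorted(network.params.to_dict().items()):
        ET.SubElement(params_el, f"{{{SBML_NS}}}parameter", attrib={
            "id": name, "value": repr(float(value)), "constant": "true",
        })

    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rxn = ET.SubElement(rxns_el, f"{{{SBML_NS}}}reaction", attrib={
            "id": r.id, "reversible": "false",
        })
        reactants = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
        for s in r.substrates:
            ET.SubElement(reactants, f"{{{SBML_NS}}}speciesReference", attrib={
                "species": s, "stoichiometry": "1", "constant": "true"})
        products = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
        for s in r.products:
            ET.SubElement(products, f"{{{SBML_NS}}}speciesReference", attrib={
                "species": s, "stoichiometry": "1", "constant": "true"})
        if r.modifier:
            mods = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfModifiers")
            ET.SubElement(mods, f"{{{SBML_NS}}}modifierSpeciesReference",
                          attrib={"species": r.modifier})
        law = ET.SubElement(rxn, f"{{{SBML_NS}}}kineticLaw")
        factors = [r.rate_param]
        if r.modifier:
            factors.append(r.modifier)
        factors.extend(r.substrates)
        denominators = []
        if r.ka_param:
            denominators.append((r.ka_param, r.modifier))
        if r.km_param:
            denominators.append((r.km_param, r.substrates[0]))
        law.append(_math(*factors, denominators=denominators))

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def write_sbml(network: ReactionNetwork, path: str | Path, **kw) -> None:
    Path(path).write_text(to_sbml(network, **kw))
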
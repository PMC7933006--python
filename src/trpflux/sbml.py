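"""Minimal SBML Level 3 export / import of the reaction network.

Writes an SBML L3 core document with compartments, species (boundary
species clamped via ``boundaryCondition``/``constant``), reactions with
MathML kinetic laws, and local parameters holding the kinetic constants.
The reader is writer-matched: it parses documents produced by
:func:`export_sbml` (gene assignment, rate-law kind and oxygen dependence
travel in a small annotation element) and round-trips species and reaction
counts and parameter values exactly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .model import (
    ModelDefinition,
    ParameterSet,
    ReactionDef,
    SpeciesDef,
)

__all__ = ["export_sbml", "import_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://github.com/trpflux/sbml-annotations"

ET.register_namespace("", SBML_NS)
ET.register_namespace("math", MATHML_NS)
ET.register_namespace("trpflux", ANNOT_NS)


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def _num(value: float) -> str:
    return repr(float(value))


# -- MathML builders ---------------------------------------------------------

def _ci(name: str) -> ET.Element:
    e = ET.Element(_q("ci", MATHML_NS))
    e.text = f" {name} "
    return e


def _apply(op: str, *args: ET.Element) -> ET.Element:
    e = ET.Element(_q("apply", MATHML_NS))
    e.append(ET.Element(_q(op, MATHML_NS)))
    e.extend(args)
    return e


def _kinetic_math(r: ReactionDef, oxygen: bool) -> ET.Element:
    if r.rate_law == "irreversible_mm":
        s = r.substrates[0][0]
        core = _apply("divide",
                      _apply("times", _ci("vmax"), _ci(s)),
                      _apply("plus", _ci(f"km_{s}"), _ci(s)))
        if oxygen and r.oxygen_dependent:
            core = _apply("times", core,
                          _apply("divide", _ci("oxygen_level"),
                                 _apply("plus", _ci("km_oxygen"), _ci("oxygen_level"))))
        expr = core
    elif r.rate_law == "antiport_exchange":
        (s_out, _), (c_in, _) = r.substrates
        (s_in, _), (c_out, _) = r.products
        num = _apply("minus",
                     _apply("times", _ci(s_out), _ci(c_in)),
                     _apply("times", _ci("keq_bias"), _ci(s_in), _ci(c_out)))
        den = _apply("times",
                     _apply("plus", _ci(f"km_{s_out}"), _ci(s_out), _ci(s_in)),
                     _apply("plus", _ci(f"km_{c_in}"), _ci(c_in), _ci(c_out)))
        expr = _apply("times", _ci("vmax"), _apply("divide", num, den))
    else:  # first_order_clearance
        expr = _apply("times", _ci("kclear"), _ci(r.substrates[0][0]))
    math = ET.Element(_q("math", MATHML_NS))
    math.append(expr)
    return math


def export_sbml(model: ModelDefinition, params: ParameterSet | None = None, path=None) -> str:
    """Serialise the model to an SBML L3 string; optionally write to ``path``."""
    params = params if params is not None else model.baseline_params
    root = ET.Element(_q("sbml"), {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, _q("model"), {
        "id": "trpflux_hepatocyte",
        "substanceUnits": model.units.get("concentration", "mM-equivalent"),
        "timeUnits": model.units.get("time", "h"),
    })
    annot = ET.SubElement(mdl, _q("annotation"))
    ET.SubElement(annot, _q("modelInfo", ANNOT_NS), {
        "oxygenTermEnabled": str(model.oxygen_term_enabled).lower(),
    })

    comps = ET.SubElement(mdl, _q("listOfCompartments"))
    for cid in ("extracellular", "intracellular"):
        ET.SubElement(comps, _q("compartment"),
                      {"id": cid, "size": "1", "constant": "true"})

    sp_list = ET.SubElement(mdl, _q("listOfSpecies"))
    for s in model.species:
        ET.SubElement(sp_list, _q("species"), {
            "id": s.id,
            "name": s.display_name or s.id,
            "compartment": s.compartment,
            "initialConcentration": _num(s.initial_concentration),
            "boundaryCondition": str(s.is_boundary).lower(),
            "constant": str(s.is_boundary).lower(),
            "hasOnlySubstanceUnits": "false",
        })

    par_list = ET.SubElement(mdl, _q("listOfParameters"))
    ET.SubElement(par_list, _q("parameter"), {
        "id": "oxygen_level", "value": _num(params.oxygen_level), "constant": "true",
    })

    rx_list = ET.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        rx = ET.SubElement(rx_list, _q("reaction"), {
            "id": r.id,
            "reversible": str(r.rate_law == "antiport_exchange").lower(),
        })
        rannot = ET.SubElement(rx, _q("annotation"))
        ET.SubElement(rannot, _q("reactionInfo", ANNOT_NS), {
            "gene": r.gene or "",
            "rateLaw": r.rate_law,
            "oxygenDependent": str(r.oxygen_dependent).lower(),
        })
        if r.substrates:
            lor = ET.SubElement(rx, _q("listOfReactants"))
            for sid, coeff in r.substrates:
                ET.SubElement(lor, _q("speciesReference"),
                              {"species": sid, "stoichiometry": _num(coeff), "constant": "true"})
        if r.products:
            lop = ET.SubElement(rx, _q("listOfProducts"))
            for sid, coeff in r.products:
                ET.SubElement(lop, _q("speciesReference"),
                              {"species": sid, "stoichiometry": _num(coeff), "constant": "true"})
        kl = ET.SubElement(rx, _q("kineticLaw"))
        kl.append(_kinetic_math(r, model.oxygen_term_enabled))
        lp = ET.SubElement(kl, _q("listOfLocalParameters"))

        def local(pid, value):
            ET.SubElement(lp, _q("localParameter"), {"id": pid, "value": _num(value)})

        if r.rate_law == "first_order_clearance":
            local("kclear", params.kclear[r.id])
        else:
            local("vmax", params.vmax[r.id])
            for sid, km in params.km.get(r.id, {}).items():
                local(f"km_{sid}", km)
            if r.rate_law == "antiport_exchange":
                local("keq_bias", params.keq_bias.get(r.id, 1.0))
            if r.oxygen_dependent and r.id in params.km_oxygen:
                local("km_oxygen", params.km_oxygen[r.id])

    ET.indent(root)
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def import_sbml(source) -> tuple[ModelDefinition, ParameterSet]:
    """Read a document written by :func:`export_sbml`.

    ``source`` is a path or an SBML string.  Returns the reconstructed
    model and parameter set.
    """
    text = source
    if not str(source).lstrip().startswith("<"):
        with open(source) as fh:
            text = fh.read()
    root = ET.fromstring(text)
    mdl = root.find(_q("model"))
    if mdl is None:
        raise ValueError("no <model> element found")
    info = mdl.find(f"{_q('annotation')}/{_q('modelInfo', ANNOT_NS)}")
    oxygen_enabled = info is not None and info.get("oxygenTermEnabled") == "true"

    species = []
    for el in mdl.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        species.append(SpeciesDef(
            id=el.get("id"),
            display_name=el.get("name", ""),
            compartment=el.get("compartment"),
            is_boundary=el.get("boundaryCondition") == "true",
            initial_concentration=float(el.get("initialConcentration", "0")),
        ))

    oxygen_level = 1.0
    for el in mdl.findall(f"{_q('listOfParameters')}/{_q('parameter')}"):
        if el.get("id") == "oxygen_level":
            oxygen_level = float(el.get("value"))

    reactions = []
    params = ParameterSet(oxygen_level=oxygen_level)
    for rx in mdl.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        rid = rx.get("id")
        rinfo = rx.find(f"{_q('annotation')}/{_q('reactionInfo', ANNOT_NS)}")
        gene = rinfo.get("gene") or None if rinfo is not None else None
        rate_law = rinfo.get("rateLaw") if rinfo is not None else "irreversible_mm"
        oxy = rinfo is not None and rinfo.get("oxygenDependent") == "true"

        def refs(tag):
            return [(el.get("species"), float(el.get("stoichiometry", "1")))
                    for el in rx.findall(f"{_q(tag)}/{_q('speciesReference')}")]

        reactions.append(ReactionDef(rid, gene, refs("listOfReactants"),
                                     refs("listOfProducts"), rate_law, oxy))
        for el in rx.findall(f"{_q('kineticLaw')}/{_q('listOfLocalParameters')}/{_q('localParameter')}"):
            pid, value = el.get("id"), float(el.get("value"))
            if pid == "vmax":
                params.vmax[rid] = value
            elif pid == "kclear":
                params.kclear[rid] = value
            elif pid == "keq_bias":
                params.keq_bias[rid] = value
            elif pid == "km_oxygen":
                params.km_oxygen[rid] = value
            elif pid.startswith("km_"):
                params.km.setdefault(rid, {})[pid[3:]] = value

    units = {
        "concentration": mdl.get("substanceUnits", "mM-equivalent"),
        "time": mdl.get("timeUnits", "h"),
    }
    model = ModelDefinition(species=species, reactions=reactions, baseline_params=params,
                            units=units, oxygen_term_enabled=oxygen_enabled)
    return model, params
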
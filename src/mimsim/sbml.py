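"""Minimal SBML Level 3 read/write for NetworkModel.

This is a deliberately small subset of SBML: one compartment, species with
initial concentrations, reactions with explicit mass-action /
Michaelis-Menten kinetic laws and local parameters.  Species roles and
moiety compositions — which SBML core has no vocabulary for — travel in a
per-element ``<annotation>`` block as JSON, so a write/read round trip is
lossless.  Files written by other tools are readable as long as they follow
the common conventions the reader understands: local kinetic-law parameters
named ``kon``/``koff`` for reversible reactions and ``kcat`` (plus ``Km``)
for enzyme-modifier reactions.
"""

from __future__ import annotations

import json
from pathlib import Path

from lxml import etree

from .network import (
    CatalyticReaction,
    ModelFormatError,
    NetworkModel,
    ReversibleReaction,
    SpeciesDecl,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANN_NS = "https://mimsim.invalid/ns"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS


def _math(expr) -> etree._Element:
    """Build a MathML tree from a nested ('op', args...) / 'ci' / number spec."""
    if isinstance(expr, (int, float)):
        el = etree.SubElement if False else etree.Element
        cn = etree.Element(_M + "cn")
        cn.text = repr(float(expr))
        return cn
    if isinstance(expr, str):
        ci = etree.Element(_M + "ci")
        ci.text = " " + expr + " "
        return ci
    op, *args = expr
    apply_el = etree.Element(_M + "apply")
    apply_el.append(etree.Element(_M + op))
    for a in args:
        apply_el.append(_math(a))
    return apply_el


def _annotation(payload: dict) -> etree._Element:
    ann = etree.Element(_S + "annotation")
    holder = etree.SubElement(ann, "{%s}mimsim" % ANN_NS, nsmap={"mimsim": ANN_NS})
    holder.text = json.dumps(payload)
    return ann


def _read_annotation(element) -> dict:
    holder = element.find(_S + "annotation/{%s}mimsim" % ANN_NS)
    if holder is None or not holder.text:
        return {}
    return json.loads(holder.text)


def write_sbml(model: NetworkModel, path: str | Path) -> None:
    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS}, level="3", version="2")
    mdl = etree.SubElement(root, _S + "model", id="mimsim_model")
    meta = {}
    if model.annotations:
        meta["annotations"] = model.annotations
    if meta:
        mdl.append(_annotation(meta))

    comps = etree.SubElement(mdl, _S + "listOfCompartments")
    etree.SubElement(
        comps, _S + "compartment", id="cell", constant="true", size="1", spatialDimensions="3"
    )

    lospecies = etree.SubElement(mdl, _S + "listOfSpecies")
    for s in model.species:
        el = etree.SubElement(
            lospecies,
            _S + "species",
            id=s.id,
            name=s.name,
            compartment="cell",
            initialConcentration=repr(float(s.initial_concentration)),
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
        el.append(_annotation({"role": s.role, "composition": s.composition}))

    lorx = etree.SubElement(mdl, _S + "listOfReactions")
    for r in model.reversible:
        el = etree.SubElement(lorx, _S + "reaction", id=r.id, reversible="true")
        el.append(_annotation({"type": "reversible"}))
        _stoich_list(el, "listOfReactants", r.reactants)
        _stoich_list(el, "listOfProducts", r.products)
        kl = etree.SubElement(el, _S + "kineticLaw")
        math = etree.SubElement(kl, _M + "math", nsmap={None: MATHML_NS})
        fwd = ("times", "kon", *r.reactants)
        rev = ("times", "koff", *r.products)
        math.append(_math(("minus", fwd, rev)))
        lop = etree.SubElement(kl, _S + "listOfLocalParameters")
        etree.SubElement(lop, _S + "localParameter", id="kon", value=repr(float(r.kon)))
        etree.SubElement(lop, _S + "localParameter", id="koff", value=repr(float(r.koff)))
    for c in model.catalytic:
        el = etree.SubElement(lorx, _S + "reaction", id=c.id, reversible="false")
        el.append(_annotation({"type": "catalytic", "law": c.law}))
        _stoich_list(el, "listOfReactants", [c.substrate])
        _stoich_list(el, "listOfProducts", [c.product])
        lomod = etree.SubElement(el, _S + "listOfModifiers")
        etree.SubElement(lomod, _S + "modifierSpeciesReference", species=c.enzyme)
        kl = etree.SubElement(el, _S + "kineticLaw")
        math = etree.SubElement(kl, _M + "math", nsmap={None: MATHML_NS})
        if c.law == "mass_action":
            math.append(_math(("times", "kcat", c.enzyme, c.substrate)))
        else:
            math.append(
                _math(
                    ("divide",
                     ("times", "kcat", c.enzyme, c.substrate),
                     ("plus", "Km", c.substrate))
                )
            )
        lop = etree.SubElement(kl, _S + "listOfLocalParameters")
        etree.SubElement(lop, _S + "localParameter", id="kcat", value=repr(float(c.kcat)))
        if c.law == "michaelis_menten":
            etree.SubElement(lop, _S + "localParameter", id="Km", value=repr(float(c.Km)))

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _stoich_list(parent, tag: str, species_ids) -> None:
    lst = etree.SubElement(parent, _S + tag)
    for sid in species_ids:
        etree.SubElement(
            lst, _S + "speciesReference", species=sid, stoichiometry="1", constant="true"
        )


def _local_params(rx) -> dict[str, float]:
    out: dict[str, float] = {}
    for lp in rx.findall(_S + "kineticLaw/" + _S + "listOfLocalParameters/" + _S + "localParameter"):
        out[lp.get("id")] = float(lp.get("value"))
    # SBML L2 compatibility
    for lp in rx.findall(_S + "kineticLaw/" + _S + "listOfParameters/" + _S + "parameter"):
        out[lp.get("id")] = float(lp.get("value"))
    return out


def _species_refs(rx, tag: str) -> list[str]:
    return [
        ref.get("species")
        for ref in rx.findall(_S + tag + "/" + _S + "speciesReference")
    ]


def read_sbml(path: str | Path) -> NetworkModel:
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ModelFormatError(f"{path}: root element is not <sbml>")
    mdl = root.find(_S + "model")
    if mdl is None:
        raise ModelFormatError(f"{path}: no <model> element")

    meta = _read_annotation(mdl)
    species: list[SpeciesDecl] = []
    for el in mdl.findall(_S + "listOfSpecies/" + _S + "species"):
        sid = el.get("id")
        if sid is None:
            raise ModelFormatError(f"{path}: species without id")
        ann = _read_annotation(el)
        conc = el.get("initialConcentration") or el.get("initialAmount") or "0"
        species.append(
            SpeciesDecl(
                id=sid,
                name=el.get("name") or sid,
                role=ann.get("role", "basic"),
                composition=ann.get("composition", {}),
                initial_concentration=float(conc),
            )
        )

    reversible: list[ReversibleReaction] = []
    catalytic: list[CatalyticReaction] = []
    for rx in mdl.findall(_S + "listOfReactions/" + _S + "reaction"):
        rid = rx.get("id") or f"rx{len(reversible) + len(catalytic)}"
        ann = _read_annotation(rx)
        params = _local_params(rx)
        reactants = _species_refs(rx, "listOfReactants")
        products = _species_refs(rx, "listOfProducts")
        modifiers = [
            ref.get("species")
            for ref in rx.findall(_S + "listOfModifiers/" + _S + "modifierSpeciesReference")
        ]
        kind = ann.get("type")
        if kind is None:  # infer from structure
            kind = "catalytic" if modifiers else "reversible"
        if kind == "reversible":
            if "kon" not in params or "koff" not in params:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r}: reversible reaction needs kon/koff "
                    f"local parameters (found {sorted(params)})"
                )
            reversible.append(
                ReversibleReaction(
                    id=rid, reactants=reactants, products=products,
                    kon=params["kon"], koff=params["koff"],
                )
            )
        else:
            if not modifiers:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r}: catalytic reaction needs an enzyme modifier"
                )
            if "kcat" not in params:
                raise ModelFormatError(
                    f"{path}: reaction {rid!r}: catalytic reaction needs a kcat local parameter"
                )
            law = ann.get("law") or ("michaelis_menten" if "Km" in params else "mass_action")
            catalytic.append(
                CatalyticReaction(
                    id=rid, enzyme=modifiers[0], substrate=reactants[0],
                    product=products[0], kcat=params["kcat"], law=law,
                    Km=params.get("Km"),
                )
            )

    return NetworkModel(
        species=species, reversible=reversible, catalytic=catalytic,
        annotations=meta.get("annotations", {}),
    )
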
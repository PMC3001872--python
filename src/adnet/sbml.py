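"""One-way export of the model as an SBML Level 3 document.

The document carries the seven species, the 17 pathway rates as constant
parameters, the three net conversion fluxes as assignment rules, and the
species derivatives as rate rules in content MathML.  The irreversibility
of neuronal death is encoded as a piecewise (the conversion flux is floored
at zero); the zero-boundary projection applied during integration is a
solver feature and is not represented in the exported document.

Written directly against the SBML L3 XML schema with ``lxml``.
"""

from __future__ import annotations

from lxml import etree

from .model import SPECIES, ModelSpec

__all__ = ["export_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_M = "{%s}" % MATHML_NS


def _ci(name: str):
    el = etree.Element(_M + "ci")
    el.text = f" {name} "
    return el


def _cn(value: float):
    el = etree.Element(_M + "cn")
    el.text = f" {value:g} "
    return el


def _apply(op: str, *args):
    el = etree.Element(_M + "apply")
    el.append(etree.Element(_M + op))
    for a in args:
        el.append(a)
    return el


def _times(rate_id: str, species: str):
    return _apply("times", _ci(rate_id), _ci(species))


def _math(content):
    math = etree.Element(_M + "math")
    math.append(content)
    return math


def _phi_n_raw():
    # alpha_2*Ap + alpha_3*M1 - alpha_1*Aq
    return _apply(
        "minus",
        _apply("plus", _times("alpha_2", "Ap"), _times("alpha_3", "M1")),
        _times("alpha_1", "Aq"),
    )


def _phi_n(floor: bool):
    if not floor:
        return _phi_n_raw()
    piecewise = etree.Element(_M + "piecewise")
    piece = etree.SubElement(piecewise, _M + "piece")
    piece.append(_phi_n_raw())
    piece.append(_apply("gt", _phi_n_raw(), _cn(0.0)))
    otherwise = etree.SubElement(piecewise, _M + "otherwise")
    otherwise.append(_cn(0.0))
    return piecewise


def _phi_a():
    # alpha_5*M1 - alpha_4*M2
    return _apply("minus", _times("alpha_5", "M1"), _times("alpha_4", "M2"))


def _phi_m():
    # (a8+a13)*Ab + a9*M1 + a10*Nd - (a6+a11)*Ns - (a7+a12)*Aq - a14*M2
    gains = _apply(
        "plus",
        _times("alpha_8", "Abeta"),
        _times("alpha_13", "Abeta"),
        _times("alpha_9", "M1"),
        _times("alpha_10", "Nd"),
    )
    losses = _apply(
        "plus",
        _times("alpha_6", "Ns"),
        _times("alpha_11", "Ns"),
        _times("alpha_7", "Aq"),
        _times("alpha_12", "Aq"),
        _times("alpha_14", "M2"),
    )
    return _apply("minus", gains, losses)


def _d_abeta():
    return _apply(
        "minus",
        _apply("minus", _times("alpha_15", "Ns"), _times("alpha_16", "M2")),
        _times("alpha_r", "Abeta"),
    )


def export_sbml(model: ModelSpec, path) -> None:
    """Write the model to ``path`` as an SBML L3V2 document."""
    S = "{%s}" % SBML_NS
    nsmap = {None: SBML_NS}
    sbml = etree.Element(S + "sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(sbml, S + "model", id="ad_neuroinflammation_network",
                           timeUnits="year")

    comps = etree.SubElement(mdl, S + "listOfCompartments")
    etree.SubElement(comps, S + "compartment", id="local_volume",
                     spatialDimensions="3", size="1", constant="true")

    species_el = etree.SubElement(mdl, S + "listOfSpecies")
    for name, value in zip(SPECIES, model.initial):
        etree.SubElement(
            species_el, S + "species", id=name, compartment="local_volume",
            initialAmount=f"{value:g}", hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
        )

    params = etree.SubElement(mdl, S + "listOfParameters")
    for rate_id, value in model.rates.as_dict().items():
        etree.SubElement(params, S + "parameter", id=rate_id,
                         value=f"{value:g}", constant="true")
    for flux in ("phi_N", "phi_A", "phi_M"):
        etree.SubElement(params, S + "parameter", id=flux, constant="false")

    rules = etree.SubElement(mdl, S + "listOfRules")

    def assignment(variable, content):
        rule = etree.SubElement(rules, S + "assignmentRule", variable=variable)
        rule.append(_math(content))

    def rate(variable, content):
        rule = etree.SubElement(rules, S + "rateRule", variable=variable)
        rule.append(_math(content))

    assignment("phi_N", _phi_n(model.floor_neuron_flux))
    assignment("phi_A", _phi_a())
    assignment("phi_M", _phi_m())

    rate("Ns", _apply("minus", _ci("phi_N")))
    rate("Nd", _ci("phi_N"))
    rate("Aq", _apply("minus", _ci("phi_A")))
    rate("Ap", _ci("phi_A"))
    rate("M1", _ci("phi_M"))
    rate("M2", _apply("minus", _ci("phi_M")))
    rate("Abeta", _d_abeta())

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)
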
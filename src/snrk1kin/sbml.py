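"""SBML Level 3 export of the model (one reaction per network entry).

The document is authored directly as SBML L3V2 core XML with kinetic
laws spelled out in MathML, matching the package's rate-law definitions
symbol for symbol, so the model can be opened in standard kinetic-model
tooling.  The export snapshots the feeding phase: the external sucrose
reservoir is a constant boundary parameter (the pre-onset zero-input
phase is a protocol feature, not part of the network).
"""

from __future__ import annotations

from lxml import etree

from .network import ReactionNetwork, default_network
from .params import ParameterSet
from .state import STATE_NAMES, ModelState, default_initial_state

__all__ = ["export_sbml", "SBML_NS", "MATHML_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_M = "{%s}" % MATHML_NS


# --- tiny MathML expression builders ---------------------------------------

def _ci(name: str) -> etree._Element:
    el = etree.Element(_M + "ci")
    el.text = f" {name} "
    return el


def _cn(value: float) -> etree._Element:
    el = etree.Element(_M + "cn")
    el.text = f" {value!r} "
    return el


def _apply(op: str, *args: etree._Element) -> etree._Element:
    el = etree.Element(_M + "apply")
    el.append(etree.Element(_M + op))
    for a in args:
        el.append(a)
    return el


def _times(*args):
    return _apply("times", *args)


def _plus(*args):
    return _apply("plus", *args)


def _divide(num, den):
    return _apply("divide", num, den)


def _sat(species: str, km: str) -> etree._Element:
    """Michaelis saturation factor S/(KM+S)."""
    return _divide(_ci(species), _plus(_ci(km), _ci(species)))


def _kinetic_math(name: str, kind: str) -> etree._Element:
    """Rate expression for one reaction, by rate-law kind."""
    if name == "Suc_import":
        expr = _times(_ci("vmax_suc_import"), _sat("suc_external", "km_suc_import"))
    elif name == "cFBPase_input":
        expr = _ci("v_cfbpase")
    elif name == "PGI":
        expr = _times(_ci("k_pgi"), _ci("F6P"))
    elif name == "PGM":
        expr = _times(_ci("k_pgm"), _ci("G6P"))
    elif name == "UGPase":
        expr = _times(_ci("k_ugpase"), _ci("G1P"))
    elif name == "SPS":
        expr = _times(
            _ci("k_sps"), _ci("E_SPS_act"),
            _sat("F6P", "km_sps_f6p"), _sat("UDPG", "km_sps_udpg"),
        )
    elif name == "TPS":
        expr = _times(
            _ci("vmax_tps"), _sat("G6P", "km_tps_g6p"), _sat("UDPG", "km_tps_udpg")
        )
    elif name == "TPP":
        expr = _times(_ci("k_tpp"), _ci("T6P"))
    elif name == "Trehalase":
        expr = _times(_ci("vmax_trehalase"), _sat("Tre", "km_trehalase"))
    elif name == "Inv":
        expr = _divide(
            _times(_ci("vmax_inv"), _ci("Suc")),
            _times(
                _plus(_cn(1.0), _divide(_ci("Glc"), _ci("ki_inv_glc"))),
                _plus(
                    _times(
                        _ci("km_inv"),
                        _plus(_cn(1.0), _divide(_ci("Fru"), _ci("ki_inv_fru"))),
                    ),
                    _ci("Suc"),
                ),
            ),
        )
    elif name == "GlcK":
        expr = _divide(
            _times(_ci("vmax_glck"), _ci("Glc")),
            _times(
                _plus(_ci("km_glck"), _ci("Glc")),
                _plus(_cn(1.0), _divide(_ci("G6P"), _ci("ki_glck_g6p"))),
            ),
        )
    elif name == "FrcK":
        expr = _divide(
            _times(_ci("vmax_frck"), _ci("Fru")),
            _times(
                _plus(_ci("km_frck"), _ci("Fru")),
                _plus(_cn(1.0), _divide(_ci("F6P"), _ci("ki_frck_f6p"))),
            ),
        )
    elif name == "SuSy":
        expr = _times(_ci("k_susy"), _ci("Suc"))
    elif name == "Suc_export":
        expr = _times(_ci("vmax_suc_export"), _sat("Suc", "km_suc_export"))
    elif name == "SnRK1_phos":
        x_t = _divide(_ci("T6P"), _ci("ki_t6p"))
        x_g1 = _divide(_ci("G1P"), _ci("ki_g1p"))
        x_g6 = _divide(_ci("G6P"), _ci("ki_g6p"))
        expr = _divide(
            _times(
                _ci("vmax_snrk1"), _ci("E_SPS_act"),
                _plus(_cn(1.0), _times(_ci("k_partial"), _divide(_ci("T6P"), _ci("ki_t6p")))),
            ),
            _plus(
                _ci("km_snrk1"),
                _times(
                    _ci("E_SPS_act"),
                    _plus(
                        _cn(1.0), x_t, x_g1, x_g6,
                        _times(
                            _divide(_ci("T6P"), _ci("ki_t6p")),
                            _divide(_ci("G1P"), _ci("ki_g1p")),
                        ),
                        _times(
                            _divide(_ci("T6P"), _ci("ki_t6p")),
                            _divide(_ci("G6P"), _ci("ki_g6p")),
                        ),
                    ),
                ),
            ),
        )
    elif name == "PP_dephos":
        expr = _times(_ci("vmax_pp"), _sat("E_SPS_inact", "km_pp"))
    else:
        raise ValueError(f"unsupported reaction/rate-law kind: {name} ({kind})")
    return expr


def export_sbml(
    params: ParameterSet,
    network: ReactionNetwork | None = None,
    path: str = "model.xml",
    init: ModelState | None = None,
    model_id: str = "snrk1_carbohydrate_model",
) -> str:
    """Write the model as an SBML L3V2 document; returns the path."""
    net = network if network is not None else default_network()
    if init is None:
        init = default_initial_state(e_sps_total=params.e_sps_total)

    nsmap = {None: SBML_NS}
    S = "{%s}" % SBML_NS
    root = etree.Element(S + "sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, S + "model")
    model.set("id", model_id)
    model.set("timeUnits", "hour")

    comps = etree.SubElement(model, S + "listOfCompartments")
    comp = etree.SubElement(comps, S + "compartment")
    comp.set("id", "cytosol")
    comp.set("size", "1")
    comp.set("constant", "true")
    comp.set("spatialDimensions", "3")

    species_list = etree.SubElement(model, S + "listOfSpecies")
    for name in STATE_NAMES:
        sp = etree.SubElement(species_list, S + "species")
        sp.set("id", name)
        sp.set("compartment", "cytosol")
        sp.set("initialConcentration", repr(getattr(init, name)))
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    plist = etree.SubElement(model, S + "listOfParameters")
    for pname in params.names():
        pe = etree.SubElement(plist, S + "parameter")
        pe.set("id", pname)
        pe.set("value", repr(params[pname]))
        pe.set("constant", "true")

    rlist = etree.SubElement(model, S + "listOfReactions")
    for rxn in net.reactions:
        re_ = etree.SubElement(rlist, S + "reaction")
        re_.set("id", rxn.name)
        re_.set("reversible", "false")
        reactants = {k: -v for k, v in rxn.stoich.items() if v < 0}
        products = {k: v for k, v in rxn.stoich.items() if v > 0}
        if reactants:
            lo = etree.SubElement(re_, S + "listOfReactants")
            for spn, coeff in reactants.items():
                ref = etree.SubElement(lo, S + "speciesReference")
                ref.set("species", spn)
                ref.set("stoichiometry", repr(float(coeff)))
                ref.set("constant", "true")
        if products:
            lo = etree.SubElement(re_, S + "listOfProducts")
            for spn, coeff in products.items():
                ref = etree.SubElement(lo, S + "speciesReference")
                ref.set("species", spn)
                ref.set("stoichiometry", repr(float(coeff)))
                ref.set("constant", "true")
        kl = etree.SubElement(re_, S + "kineticLaw")
        math = etree.SubElement(kl, _M + "math")
        math.append(_kinetic_math(rxn.name, rxn.kind))

    tree = etree.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return path
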
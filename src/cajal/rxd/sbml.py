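"""SBML Level 3 Version 1 (core) export of point reaction dynamics.

Only well-mixed point models (no diffusion) are exportable: one SBML
compartment, one species per registered species with its initial
concentration, one reaction per Reaction with a content-MathML kinetic
law generated from the sympy rate expression.  A small reader parses such
documents back (species, initial values, kinetic laws) so exported models
can be re-simulated and compared — the round-trip used by the tests.

The writer/reader is deliberately minimal: it covers the constructs this
package emits, with an in-package structural validator.
"""

from __future__ import annotations

from xml.sax.saxutils import escape

import sympy
from lxml import etree

from ..errors import CajalError
from .core import Reaction, RxdModel

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class UnsupportedExportError(CajalError):
    pass


def _content_mathml(expr: sympy.Expr) -> str:
    """Content-MathML for the expression forms reaction rates use
    (sums, products, powers, rationals, exp/log)."""
    if isinstance(expr, sympy.Symbol):
        return f"<ci>{escape(expr.name)}</ci>"
    if isinstance(expr, sympy.Integer):
        return f"<cn>{int(expr)}</cn>"
    if isinstance(expr, sympy.Rational):
        return (f"<apply><divide/><cn>{int(expr.p)}</cn>"
                f"<cn>{int(expr.q)}</cn></apply>")
    if isinstance(expr, sympy.Float):
        return f"<cn>{float(expr)!r}</cn>"
    if isinstance(expr, sympy.Add):
        args = "".join(_content_mathml(a) for a in expr.args)
        return f"<apply><plus/>{args}</apply>"
    if isinstance(expr, sympy.Mul):
        args = "".join(_content_mathml(a) for a in expr.args)
        return f"<apply><times/>{args}</apply>"
    if isinstance(expr, sympy.Pow):
        base, exponent = expr.args
        return (f"<apply><power/>{_content_mathml(base)}"
                f"{_content_mathml(exponent)}</apply>")
    if isinstance(expr, sympy.exp):
        return f"<apply><exp/>{_content_mathml(expr.args[0])}</apply>"
    if isinstance(expr, sympy.log):
        return f"<apply><ln/>{_content_mathml(expr.args[0])}</apply>"
    raise UnsupportedExportError(
        f"cannot express {type(expr).__name__} in the exported kinetic law")


def _mathml(expr: sympy.Expr) -> str:
    return f'<math xmlns="{MATHML_NS}">{_content_mathml(expr)}</math>'


def _net_rate_expr(rxn: Reaction) -> sympy.Expr:
    from .reactions import _net_rate

    names = set(rxn.reactants) | set(rxn.products)
    if not rxn.mass_action:
        names |= {str(s) for s in sympy.sympify(rxn.rate_f).free_symbols}
    syms = {n: sympy.Symbol(n) for n in names}
    return _net_rate(rxn, syms)


def export_sbml(model: RxdModel, compartment: str = "cell",
                level_check: bool = True) -> str:
    """Serialize a point model to an SBML L3V1 document string."""
    for sp in model.species:
        if sp.d != 0.0:
            raise UnsupportedExportError(
                f"species {sp.name!r} has diffusion; only point dynamics "
                "can be exported to SBML")
        if _npoints(sp) != 1:
            raise UnsupportedExportError(
                "SBML export requires single-location species")
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             f'<sbml xmlns="{SBML_NS}" level="3" version="1">',
             '  <model id="cajal_point_model">',
             '    <listOfCompartments>',
             f'      <compartment id="{compartment}" size="1" '
             'spatialDimensions="3" constant="true"/>',
             '    </listOfCompartments>',
             '    <listOfSpecies>']
    for sp in model.species:
        init = float(next(iter(sp.values.values()))[0])
        lines.append(
            f'      <species id="{escape(sp.name)}" compartment="{compartment}" '
            f'initialConcentration="{init!r}" hasOnlySubstanceUnits="false" '
            'boundaryCondition="false" constant="false"/>')
    lines.append('    </listOfSpecies>')
    lines.append('    <listOfReactions>')
    for k, rxn in enumerate(model.reactions):
        rid = rxn.name or f"r{k}"
        lines.append(f'      <reaction id="{escape(rid)}" reversible="'
                     f'{"true" if rxn.rate_b is not None else "false"}" fast="false">')
        if rxn.reactants:
            lines.append('        <listOfReactants>')
            for name, stoich in rxn.reactants.items():
                lines.append(f'          <speciesReference species="{escape(name)}" '
                             f'stoichiometry="{stoich}" constant="true"/>')
            lines.append('        </listOfReactants>')
        if rxn.products:
            lines.append('        <listOfProducts>')
            for name, stoich in rxn.products.items():
                lines.append(f'          <speciesReference species="{escape(name)}" '
                             f'stoichiometry="{stoich}" constant="true"/>')
            lines.append('        </listOfProducts>')
        lines.append('        <kineticLaw>')
        lines.append('          ' + _mathml(_net_rate_expr(rxn)))
        lines.append('        </kineticLaw>')
        lines.append('      </reaction>')
    lines.append('    </listOfReactions>')
    lines.append('  </model>')
    lines.append('</sbml>')
    doc = "\n".join(lines)
    if level_check:
        validate_sbml(doc)
    return doc


def _npoints(sp) -> int:
    return sum(len(arr) for arr in sp.values.values())


# ---------------------------------------------------------------------------
# structural validation + import


def validate_sbml(doc: str) -> None:
    """Structural checks: well-formed XML, required SBML elements and
    attributes, species references resolving, one kinetic law each."""
    root = etree.fromstring(doc.encode())
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise CajalError("not an SBML document")
    if root.get("level") != "3" or root.get("version") != "1":
        raise CajalError("expected SBML level 3 version 1")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise CajalError("missing <model>")
    species = model.findall(
        f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    ids = set()
    for sp in species:
        if sp.get("id") is None or sp.get("compartment") is None:
            raise CajalError("species missing id/compartment")
        ids.add(sp.get("id"))
    comps = {c.get("id") for c in model.findall(
        f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")}
    for sp in species:
        if sp.get("compartment") not in comps:
            raise CajalError(f"species {sp.get('id')} references unknown compartment")
    for rxn in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        for ref in rxn.iter(f"{{{SBML_NS}}}speciesReference"):
            if ref.get("species") not in ids:
                raise CajalError(
                    f"reaction {rxn.get('id')} references unknown species "
                    f"{ref.get('species')}")
        laws = rxn.findall(f"{{{SBML_NS}}}kineticLaw")
        if len(laws) != 1:
            raise CajalError(f"reaction {rxn.get('id')} needs exactly one kineticLaw")


def _mathml_to_sympy(node) -> sympy.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        return _mathml_to_sympy(children[0])
    if tag == "cn":
        if node.get("type") == "rational":
            num = sympy.Integer(int(node.text.strip()))
            den = sympy.Integer(int(node[0].tail.strip()))
            return num / den
        return sympy.Rational(node.text.strip()) if "." not in node.text \
            else sympy.Float(node.text.strip())
    if tag == "ci":
        return sympy.Symbol(node.text.strip())
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c) for c in children[1:]]
        if op == "plus":
            return sympy.Add(*args)
        if op == "times":
            return sympy.Mul(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "root":
            return sympy.sqrt(args[0])
        if op == "exp":
            return sympy.exp(args[0])
        if op == "ln":
            return sympy.log(args[0])
        raise CajalError(f"unsupported MathML operator {op!r}")
    raise CajalError(f"unsupported MathML node {tag!r}")


def import_sbml(doc: str):
    """Parse an exported document back into ``(species, initials, rates)``.

    ``rates`` maps species name -> net sympy rate expression (dC/dt),
    assembled from kinetic laws and stoichiometries — sufficient to
    re-simulate the point model for round-trip comparison.
    """
    validate_sbml(doc)
    root = etree.fromstring(doc.encode())
    model = root.find(f"{{{SBML_NS}}}model")
    species, initials = [], {}
    for sp in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        species.append(sp.get("id"))
        initials[sp.get("id")] = float(sp.get("initialConcentration", "0"))
    rates = {name: sympy.Integer(0) for name in species}
    for rxn in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        law = rxn.find(f"{{{SBML_NS}}}kineticLaw")
        math_node = law.find(f"{{{MATHML_NS}}}math")
        rate = _mathml_to_sympy(math_node)
        for ref in rxn.findall(
                f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"):
            rates[ref.get("species")] -= int(float(ref.get("stoichiometry", "1"))) * rate
        for ref in rxn.findall(
                f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"):
            rates[ref.get("species")] += int(float(ref.get("stoichiometry", "1"))) * rate
    return species, initials, rates
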
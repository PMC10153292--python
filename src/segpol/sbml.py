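"""SBML Level 3 Version 1 export/import of the reaction network.

The document encodes the *network* — compartments per cell, species,
reactions with kinetic laws — not a bare ODE dump.  Guarded
exponentiation ``max(eps, x) ** n`` is expressed with the piecewise
construct of SBML math, so any consuming tool reproduces the guard
semantics exactly.  The PTC + HH capture uses non-integer stoichiometries
(HH0 on the PTC/PH side, PTC0 on the HH side) to encode the
concentration-scale asymmetry of the normalized model.

Export is self-contained lxml; :func:`import_sbml` is a scoped reader: it
accepts documents written by this package (identified by their model
annotation) and rebuilds the native compiled model, raising
``UnsupportedSBMLError`` for anything else.  :func:`evaluate_document_rhs`
interprets the document's own MathML to recover dy/dt independently of
the native right-hand side — the semantic half of the round-trip check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lxml import etree

from .catalog import ParameterSet, load_catalog
from .grid import GridSpec
from .kinetics import GuardConfig
from .model import ODESystem, Reaction, build_model

__all__ = [
    "SBML_NS",
    "MATHML_NS",
    "ModelDocument",
    "SBMLValidationError",
    "UnsupportedSBMLError",
    "export_sbml",
    "import_sbml",
    "write_sbml",
    "read_sbml",
    "validate_document",
    "evaluate_document_rhs",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://segpol.readthedocs.io/sbml-annotation"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS
_A = "{%s}" % ANNOT_NS


class SBMLValidationError(ValueError):
    pass


class UnsupportedSBMLError(ValueError):
    pass


@dataclass
class ModelDocument:
    """A serialized model: the SBML element tree plus convenience counts."""

    tree: etree._ElementTree

    @property
    def root(self) -> etree._Element:
        return self.tree.getroot()

    @property
    def model_element(self) -> etree._Element:
        return self.root.find(_S + "model")

    def _count(self, list_tag: str, item_tag: str) -> int:
        lst = self.model_element.find(_S + list_tag)
        return 0 if lst is None else len(lst.findall(_S + item_tag))

    @property
    def n_species(self) -> int:
        return self._count("listOfSpecies", "species")

    @property
    def n_parameters(self) -> int:
        return self._count("listOfParameters", "parameter")

    @property
    def n_reactions(self) -> int:
        return self._count("listOfReactions", "reaction")

    def to_string(self) -> str:
        return etree.tostring(
            self.tree, pretty_print=True, xml_declaration=True,
            encoding="UTF-8").decode()

    def write(self, path) -> None:
        self.tree.write(str(path), pretty_print=True, xml_declaration=True,
                        encoding="UTF-8")


# ---------------------------------------------------------------------------
# math expression builder (tuple IR -> MathML)
# ---------------------------------------------------------------------------
# expr := ("ci", name) | ("cn", float) | (op, expr, ...) with op in
# {"plus","times","minus","divide","power","ln","gmax"}; "gmax" is the
# guard max(eps, x), rendered as piecewise.

def _ci(name: str): return ("ci", name)
def _cn(v: float): return ("cn", float(v))


_LN2 = ("ln", _cn(2.0))


def _emit(parent: etree._Element, expr) -> None:
    op = expr[0]
    if op == "ci":
        e = etree.SubElement(parent, _M + "ci")
        e.text = " " + expr[1] + " "
        return
    if op == "cn":
        v = expr[1]
        e = etree.SubElement(parent, _M + "cn")
        if v != 0 and (abs(v) < 1e-4 or abs(v) >= 1e6):
            mant, ex = f"{v:e}".split("e")
            e.set("type", "e-notation")
            e.text = " " + mant.rstrip("0").rstrip(".") + " "
            sep = etree.SubElement(e, _M + "sep")
            sep.tail = " " + str(int(ex)) + " "
        else:
            e.text = " " + repr(v) + " "
        return
    if op == "gmax":
        # piecewise(x, x > eps, eps)
        _, x, eps = expr
        pw = etree.SubElement(parent, _M + "piecewise")
        piece = etree.SubElement(pw, _M + "piece")
        _emit(piece, x)
        cond = etree.SubElement(piece, _M + "apply")
        etree.SubElement(cond, _M + "gt")
        _emit(cond, x)
        _emit(cond, eps)
        other = etree.SubElement(pw, _M + "otherwise")
        _emit(other, eps)
        return
    ap = etree.SubElement(parent, _M + "apply")
    etree.SubElement(ap, _M + op)
    for sub in expr[1:]:
        _emit(ap, sub)


def _parse_expr(el: etree._Element):
    tag = etree.QName(el).localname
    if tag == "ci":
        return ("ci", el.text.strip())
    if tag == "cn":
        if el.get("type") == "e-notation":
            sep = el.find(_M + "sep")
            return ("cn", float(f"{el.text.strip()}e{sep.tail.strip()}"))
        return ("cn", float(el.text.strip()))
    if tag == "piecewise":
        piece = el.find(_M + "piece")
        kids = list(piece)
        other = el.find(_M + "otherwise")
        return ("piecewise", _parse_expr(kids[0]), _parse_expr(kids[1]),
                _parse_expr(list(other)[0]))
    if tag == "apply":
        kids = list(el)
        op = etree.QName(kids[0]).localname
        return (op, *[_parse_expr(k) for k in kids[1:]])
    raise UnsupportedSBMLError(f"unsupported MathML element <{tag}>")


def _eval_expr(expr, env: dict[str, float]) -> float:
    op = expr[0]
    if op == "ci":
        return env[expr[1]]
    if op == "cn":
        return expr[1]
    args = [_eval_expr(a, env) for a in expr[1:]]
    if op == "plus":
        return sum(args)
    if op == "times":
        return math.prod(args)
    if op == "minus":
        return args[0] - args[1] if len(args) == 2 else -args[0]
    if op == "divide":
        return args[0] / args[1]
    if op == "power":
        return args[0] ** args[1]
    if op == "ln":
        return math.log(args[0])
    if op == "gt":
        return 1.0 if args[0] > args[1] else 0.0
    if op == "piecewise":
        return args[0] if args[1] != 0.0 else args[2]
    raise UnsupportedSBMLError(f"unsupported MathML operator {op!r}")


# ---------------------------------------------------------------------------
# kinetic-law rendering (mirrors the compiled kernel, one law per template)
# ---------------------------------------------------------------------------

def _g(x, guard: GuardConfig):
    return ("gmax", x, _cn(guard.epsilon)) if guard.enabled else x


def _phi_math(x, kappa: str, nu: str, guard):
    xn = ("power", _g(x, guard), _ci(nu))
    return ("divide", xn, ("plus", ("power", _ci(kappa), _ci(nu)), xn))


def _psi_math(r, kappa: str, nu: str, guard):
    rn = ("power", _g(r, guard), _ci(nu))
    psi = ("minus", _cn(1.0),
           ("divide", rn, ("plus", ("power", _ci(kappa), _ci(nu)), rn)))
    return _g(psi, guard)


def _v_of(hname: str):
    return ("divide", _LN2, _ci(hname))


def _law_math(model: ODESystem, rx: Reaction):
    """MathML IR of a reaction's flux (species referenced by document id)."""
    g = model.guard
    sp = model.species_name

    if rx.law == "txn_ind_rep":
        hgene, ip, rp = rx.args
        mods = rx.modifiers
        if len(mods) > 2:
            I = ("plus", *[_ci(sp(i)) for i in mods[:-1]])
        else:
            I = _ci(sp(mods[0]))
        psi = _psi_math(_ci(sp(mods[-1])), f"kappa_{rp}", f"nu_{rp}", g)
        x = ("power", _g(("times", I, psi), g), _ci(f"nu_{ip}"))
        return ("times", _v_of(hgene),
                ("divide", x,
                 ("plus", ("power", _ci(f"kappa_{ip}"), _ci(f"nu_{ip}")), x)))
    if rx.law == "txn_ci":
        hgene, rp = rx.args
        return ("times", _v_of(hgene),
                _psi_math(_ci(sp(rx.modifiers[0])), f"kappa_{rp}", f"nu_{rp}", g))
    if rx.law == "txn_wg":
        (hgene,) = rx.args
        ci_, iwg, cn = (sp(i) for i in rx.modifiers)
        S = ("plus",
             ("times", _ci("alpha_CIwg"),
              _phi_math(_ci(ci_), "kappa_CIwg", "nu_CIwg", g),
              _psi_math(_ci(cn), "kappa_CNwg", "nu_CNwg", g)),
             ("times", _ci("alpha_WGwg"), _phi_math(_ci(iwg), "kappa_WGwg", "nu_WGwg", g)))
        return ("times", _v_of(hgene), ("divide", S, ("plus", _cn(1.0), S)))
    if rx.law == "linear":
        rate_name, scale = rx.args
        if scale == "halflife":
            rate = _v_of(rate_name)
        elif scale == 1.0:
            rate = _ci(rate_name)
        else:
            rate = ("times", _ci(rate_name), _cn(scale))
        src = rx.reactants[0][0] if rx.reactants else rx.modifiers[0]
        return ("times", rate, _ci(sp(src)))
    if rx.law == "cleave":
        ptc_T = ("plus", *[_ci(sp(i)) for i in rx.modifiers])
        return ("times", _ci("C_CI"), _ci(sp(rx.reactants[0][0])),
                _phi_math(ptc_T, "kappa_PTCCI", "nu_PTCCI", g))
    if rx.law == "bind":
        (iptc, _), (ihh, _) = rx.reactants
        if model.params["nu_PTCHH"] == 1.0:
            hh_term = _ci(sp(ihh))  # plain mass action, no guard needed
        else:
            hh_term = ("power", _g(_ci(sp(ihh)), g), _ci("nu_PTCHH"))
        return ("times", _ci("kappa_PTCHH"), _ci(sp(iptc)), hh_term)
    raise AssertionError(f"unknown law {rx.law}")  # pragma: no cover


def _stoichiometries(model: ODESystem, rx: Reaction):
    """Resolved (reactants, products) with numeric stoichiometries."""
    if rx.law != "bind":
        return rx.reactants, rx.products
    hh0, ptc0 = model.params["HH0"], model.params["PTC0"]
    (iptc, _), (ihh, _) = rx.reactants
    (iph, _) = rx.products[0]
    return ((iptc, hh0), (ihh, ptc0)), ((iph, hh0),)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sbml(model: ODESystem, x0: np.ndarray | None = None) -> ModelDocument:
    """Serialize the built model (and optionally a starting state) to L3V1."""
    if model._single:
        raise ValueError("single-cell models with fixed inputs are not exported")
    if x0 is None:
        x0 = np.zeros(model.n_states)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_states,):
        raise ValueError("x0 length mismatch")

    nsmap = {None: SBML_NS}
    root = etree.Element(_S + "sbml", nsmap=nsmap, level="3", version="1")
    spec = model.grid.spec
    mdl = etree.SubElement(
        root, _S + "model",
        id=f"segment_polarity_{spec.rows}x{spec.cols}",
        name="Segment polarity network model")

    annot = etree.SubElement(mdl, _S + "annotation")
    info = etree.SubElement(annot, _A + "segpol", nsmap={"sp": ANNOT_NS})
    etree.SubElement(info, _A + "grid", rows=str(spec.rows), cols=str(spec.cols),
                     periodicRows=str(spec.periodic[0]).lower(),
                     periodicCols=str(spec.periodic[1]).lower())
    etree.SubElement(info, _A + "guard", enabled=str(model.guard.enabled).lower(),
                     epsilon=repr(model.guard.epsilon))

    lst = etree.SubElement(mdl, _S + "listOfCompartments")
    for r, c in model.grid.cells:
        etree.SubElement(lst, _S + "compartment", id=f"cell_{r}_{c}",
                         spatialDimensions="3", size="1", constant="true")

    lst = etree.SubElement(mdl, _S + "listOfSpecies")
    for i in range(model.n_states):
        cell_i = i // 33
        r, c = model.grid.cells[cell_i]
        etree.SubElement(
            lst, _S + "species", id=model.species_name(i),
            compartment=f"cell_{r}_{c}",
            initialConcentration=repr(float(x0[i])),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")

    lst = etree.SubElement(mdl, _S + "listOfParameters")
    for name, value in model.params.to_dict().items():
        etree.SubElement(lst, _S + "parameter", id=name, value=repr(value),
                         constant="true")

    lst = etree.SubElement(mdl, _S + "listOfReactions")
    for rx in model.reactions:
        re_ = etree.SubElement(lst, _S + "reaction", id=rx.rid,
                               reversible="false", fast="false")
        reactants, products = _stoichiometries(model, rx)
        if reactants:
            lr = etree.SubElement(re_, _S + "listOfReactants")
            for idx, st in reactants:
                etree.SubElement(lr, _S + "speciesReference",
                                 species=model.species_name(idx),
                                 stoichiometry=repr(float(st)), constant="true")
        if products:
            lp = etree.SubElement(re_, _S + "listOfProducts")
            for idx, st in products:
                etree.SubElement(lp, _S + "speciesReference",
                                 species=model.species_name(idx),
                                 stoichiometry=repr(float(st)), constant="true")
        mods = [i for i in rx.modifiers]
        if rx.law == "bind":
            mods = []
        if mods:
            lm = etree.SubElement(re_, _S + "listOfModifiers")
            for idx in mods:
                etree.SubElement(lm, _S + "modifierSpeciesReference",
                                 species=model.species_name(idx))
        kl = etree.SubElement(re_, _S + "kineticLaw")
        math_el = etree.SubElement(kl, "{%s}math" % MATHML_NS,
                                   nsmap={None: MATHML_NS})
        _emit(math_el, _law_math(model, rx))

    doc = ModelDocument(etree.ElementTree(root))
    issues = validate_document(doc)
    if issues:
        raise SBMLValidationError("; ".join(issues))
    return doc


def write_sbml(model: ODESystem, path, x0: np.ndarray | None = None) -> ModelDocument:
    doc = export_sbml(model, x0)
    doc.write(path)
    return doc


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_document(doc: ModelDocument) -> list[str]:
    """Structural L3V1 checks; returns a list of problems (empty = valid)."""
    issues: list[str] = []
    root = doc.root
    if etree.QName(root).namespace != SBML_NS or etree.QName(root).localname != "sbml":
        return [f"root element is not SBML L3V1 core: {root.tag}"]
    if root.get("level") != "3" or root.get("version") != "1":
        issues.append("level/version attributes are not 3/1")
    mdl = doc.model_element
    if mdl is None:
        return issues + ["missing <model>"]

    comp_ids = [c.get("id") for c in mdl.findall(f"{_S}listOfCompartments/{_S}compartment")]
    sp_els = mdl.findall(f"{_S}listOfSpecies/{_S}species")
    sp_ids = [s.get("id") for s in sp_els]
    par_els = mdl.findall(f"{_S}listOfParameters/{_S}parameter")
    par_ids = [p.get("id") for p in par_els]
    for label, ids in (("compartment", comp_ids), ("species", sp_ids),
                       ("parameter", par_ids)):
        if len(set(ids)) != len(ids):
            issues.append(f"duplicate {label} ids")
        if any(i is None for i in ids):
            issues.append(f"{label} without id")
    comp_set = set(comp_ids)
    for s in sp_els:
        if s.get("compartment") not in comp_set:
            issues.append(f"species {s.get('id')} references unknown compartment")
        if s.get("initialConcentration") is None:
            issues.append(f"species {s.get('id')} lacks initialConcentration")
    for p in par_els:
        if p.get("value") is None:
            issues.append(f"parameter {p.get('id')} lacks a value")
    known = set(sp_ids)
    for rx in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = rx.get("id")
        for ref in rx.iter(_S + "speciesReference"):
            if ref.get("species") not in known:
                issues.append(f"reaction {rid}: unknown species reference")
            if ref.get("stoichiometry") is None:
                issues.append(f"reaction {rid}: missing stoichiometry")
        kl = rx.find(_S + "kineticLaw")
        if kl is None or kl.find(_M + "math") is None:
            issues.append(f"reaction {rid}: missing kinetic law math")
    return issues


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def read_sbml(path) -> ODESystem:
    return import_sbml(ModelDocument(etree.parse(str(path))))


def import_sbml(doc: ModelDocument) -> ODESystem:
    """Rebuild the native model from a document written by this package.

    The rebuilt :class:`~segpol.model.ODESystem` gains an
    ``initial_state`` attribute holding the document's initial
    concentrations.  Foreign documents raise ``UnsupportedSBMLError``.
    """
    issues = validate_document(doc)
    if issues:
        raise SBMLValidationError("; ".join(issues))
    mdl = doc.model_element
    grid_el = mdl.find(f"{_S}annotation/{_A}segpol/{_A}grid")
    guard_el = mdl.find(f"{_S}annotation/{_A}segpol/{_A}guard")
    if grid_el is None or guard_el is None:
        raise UnsupportedSBMLError(
            "document lacks the grid/guard annotation this reader requires")
    spec = GridSpec(int(grid_el.get("rows")), int(grid_el.get("cols")),
                    (grid_el.get("periodicRows") == "true",
                     grid_el.get("periodicCols") == "true"))
    guard = GuardConfig(enabled=guard_el.get("enabled") == "true",
                        epsilon=float(guard_el.get("epsilon")))

    catalog = load_catalog()
    values: dict[str, float] = {}
    for p in mdl.findall(f"{_S}listOfParameters/{_S}parameter"):
        pid = p.get("id")
        if pid not in catalog:
            raise UnsupportedSBMLError(f"parameter {pid!r} is not in the catalog")
        values[pid] = float(p.get("value"))
    missing = set(catalog.names) - set(values)
    if missing:
        raise UnsupportedSBMLError(f"missing parameters: {sorted(missing)}")
    params = ParameterSet(values, catalog=catalog)

    model = build_model(spec, params, guard)
    x0 = np.zeros(model.n_states)
    seen = set()
    for s in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        sid = s.get("id")
        try:
            idx = model.species_names.index(sid)
        except ValueError:
            raise UnsupportedSBMLError(f"species {sid!r} is not in the catalog")
        x0[idx] = float(s.get("initialConcentration"))
        seen.add(sid)
    if len(seen) != model.n_states:
        raise UnsupportedSBMLError(
            f"expected {model.n_states} species, found {len(seen)}")
    model.initial_state = x0
    return model


# ---------------------------------------------------------------------------
# independent evaluation of the document's own math
# ---------------------------------------------------------------------------

def evaluate_document_rhs(doc: ModelDocument, state: np.ndarray) -> np.ndarray:
    """dy/dt computed by interpreting the document's MathML kinetic laws.

    Independent of the native compiled kernel: species order follows the
    document's species list, fluxes are evaluated from the parsed math and
    accumulated through the listed stoichiometries.
    """
    mdl = doc.model_element
    sp_ids = [s.get("id") for s in mdl.findall(f"{_S}listOfSpecies/{_S}species")]
    state = np.asarray(state, dtype=float)
    if state.shape != (len(sp_ids),):
        raise ValueError(f"state length must be {len(sp_ids)}")
    env = dict(zip(sp_ids, state.tolist()))
    for p in mdl.findall(f"{_S}listOfParameters/{_S}parameter"):
        env[p.get("id")] = float(p.get("value"))
    idx = {sid: i for i, sid in enumerate(sp_ids)}
    out = np.zeros(len(sp_ids))
    for rx in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        math_el = rx.find(f"{_S}kineticLaw/{_M}math")
        flux = _eval_expr(_parse_expr(list(math_el)[0]), env)
        for ref in rx.findall(f"{_S}listOfReactants/{_S}speciesReference"):
            out[idx[ref.get("species")]] -= float(ref.get("stoichiometry")) * flux
        for ref in rx.findall(f"{_S}listOfProducts/{_S}speciesReference"):
            out[idx[ref.get("species")]] += float(ref.get("stoichiometry")) * flux
    return out
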
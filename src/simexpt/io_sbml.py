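"""SBML Level 3 import/export for reaction-network models.

Supports the subset of SBML L3 (core + the *groups* package) that the model
representation needs: compartments, species, reversible mass-action reactions
and Michaelis-Menten enzymatic steps, boundary-condition species for buffered
pools, events for time-series stimuli, and groups carrying the pathway
hierarchy.  Files without groups load flat, with every entity a child of the
root.

Kinetic laws are classified by their local-parameter signature: ``Kf``/``Kb``
(or the common ``k1``/``k2``) mark mass action; ``Km``/``kcat`` with a
modifier species mark a Michaelis-Menten enzyme.  Anything else raises,
naming the reaction, rather than silently mis-simulating it.

Hierarchical paths are carried in ``name`` attributes (SBML ids cannot hold
'/'); ids are sanitized path strings.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .model import (Compartment, Enzyme, HHCompartment, ModelError, Pool,
                    Reaction, ReactionModel, parent_path)

__all__ = ["read_sbml", "write_sbml", "SBML_NS", "GROUPS_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
GROUPS_NS = "http://www.sbml.org/sbml/level3/version1/groups/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"

_NSMAP = {None: SBML_NS, "groups": GROUPS_NS}


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def _fmt(x: float) -> str:
    return repr(float(x))


def _sid(path: str) -> str:
    """Sanitize a '/'-path into a valid SBML SId."""
    out = []
    for c in path.strip("/"):
        if c == "/":
            out.append("__")
        elif c.isalnum() or c == "_":
            out.append(c)
        else:
            out.append("_")
    sid = "".join(out)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x" + sid
    return sid


# --------------------------------------------------------------------------
# MathML builders
# --------------------------------------------------------------------------

def _mml(tag: str) -> etree._Element:
    return etree.Element(_q(tag, MATHML_NS))


def _ci(name: str) -> etree._Element:
    el = _mml("ci")
    el.text = f" {name} "
    return el


def _cn(value: float) -> etree._Element:
    el = _mml("cn")
    el.text = f" {_fmt(value)} "
    return el


def _apply(op: str, *args: etree._Element) -> etree._Element:
    ap = _mml("apply")
    ap.append(_mml(op))
    for a in args:
        ap.append(a)
    return ap


def _power(base: etree._Element, n: int) -> etree._Element:
    if n == 1:
        return base
    return _apply("power", base, _cn(float(n)))


def _mass_action_math(rxn: Reaction, sid_of: dict[str, str]) -> etree._Element:
    fwd = _apply("times", _ci("Kf"),
                 *[_power(_ci(sid_of[p]), n) for p, n in rxn.substrates])
    back = _apply("times", _ci("Kb"),
                  *[_power(_ci(sid_of[p]), n) for p, n in rxn.products])
    math = _mml("math")
    math.append(_apply("minus", fwd, back))
    return math


def _mm_math(enz: Enzyme, sid_of: dict[str, str]) -> etree._Element:
    num = _apply("times", _ci("kcat"), _ci(sid_of[enz.enzymePool]),
                 _ci(sid_of[enz.substrate]))
    den = _apply("plus", _ci("Km"), _ci(sid_of[enz.substrate]))
    math = _mml("math")
    math.append(_apply("divide", num, den))
    return math


# --------------------------------------------------------------------------
# Writer
# --------------------------------------------------------------------------

def write_sbml(model: ReactionModel, dest: str | Path,
               stimuli=None) -> None:
    """Serialize *model* as SBML L3V1 with the groups package.

    ``stimuli``, when given, is a sequence of timed assignment events
    ``(time_s, pool_path, field, value)``; concentration assignments are
    written as SBML events.  Buffered pools become boundary-condition
    species, so dose clamps need no event machinery.
    """
    if isinstance(model, HHCompartment):
        raise ModelError("HH membrane models have no SBML representation; "
                         "use the native dialect")
    sid_of = {p: _sid(p) for p in model.entity_paths()}
    if len(set(sid_of.values())) != len(sid_of):
        # disambiguate sanitization collisions deterministically
        seen: dict[str, int] = {}
        for p in sorted(sid_of):
            base = sid_of[p]
            if base in seen:
                seen[base] += 1
                sid_of[p] = f"{base}_{seen[base]}"
            else:
                seen[base] = 0

    sbml = etree.Element(_q("sbml"), nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required", GROUPS_NS), "false")
    mdl = etree.SubElement(sbml, _q("model"))
    mdl.set("id", "model")

    locomp = etree.SubElement(mdl, _q("listOfCompartments"))
    for comp in sorted(model.compartments.values(), key=lambda c: c.name):
        c = etree.SubElement(locomp, _q("compartment"))
        c.set("id", _sid("/" + comp.name))
        c.set("name", comp.name)
        c.set("size", _fmt(comp.volume))
        c.set("spatialDimensions", "3")
        c.set("constant", "true")

    lospec = etree.SubElement(mdl, _q("listOfSpecies"))
    for pool in sorted(model.pools.values(), key=lambda p: p.path):
        s = etree.SubElement(lospec, _q("species"))
        s.set("id", sid_of[pool.path])
        s.set("name", pool.path)
        s.set("compartment", _sid("/" + pool.compartment))
        s.set("initialConcentration", _fmt(pool.concInit))
        s.set("boundaryCondition", "true" if pool.buffered else "false")
        s.set("constant", "false")
        s.set("hasOnlySubstanceUnits", "false")

    lorxn = etree.SubElement(mdl, _q("listOfReactions"))

    def _species_refs(parent, tag, side):
        lo = etree.SubElement(parent, _q(tag))
        for p, n in side:
            ref = etree.SubElement(lo, _q("speciesReference"))
            ref.set("species", sid_of[p])
            ref.set("stoichiometry", _fmt(float(n)))
            ref.set("constant", "true")

    def _local_params(kl, params):
        lo = etree.SubElement(kl, _q("listOfLocalParameters"))
        for pid, val in params:
            lp = etree.SubElement(lo, _q("localParameter"))
            lp.set("id", pid)
            lp.set("value", _fmt(val))

    for rxn in sorted(model.reactions.values(), key=lambda r: r.path):
        r = etree.SubElement(lorxn, _q("reaction"))
        r.set("id", sid_of[rxn.path])
        r.set("name", rxn.path)
        r.set("reversible", "true")
        r.set("fast", "false")
        _species_refs(r, "listOfReactants", rxn.substrates)
        _species_refs(r, "listOfProducts", rxn.products)
        kl = etree.SubElement(r, _q("kineticLaw"))
        kl.append(_mass_action_math(rxn, sid_of))
        _local_params(kl, [("Kf", rxn.Kf), ("Kb", rxn.Kb)])

    for enz in sorted(model.enzymes.values(), key=lambda e: e.path):
        r = etree.SubElement(lorxn, _q("reaction"))
        r.set("id", sid_of[enz.path])
        r.set("name", enz.path)
        r.set("reversible", "false")
        r.set("fast", "false")
        _species_refs(r, "listOfReactants", [(enz.substrate, 1)])
        _species_refs(r, "listOfProducts", [(enz.product, 1)])
        lom = etree.SubElement(r, _q("listOfModifiers"))
        mod = etree.SubElement(lom, _q("modifierSpeciesReference"))
        mod.set("species", sid_of[enz.enzymePool])
        kl = etree.SubElement(r, _q("kineticLaw"))
        kl.append(_mm_math(enz, sid_of))
        _local_params(kl, [("Km", enz.Km), ("kcat", enz.kcat)])

    events = [(t, p, f, v) for (t, p, f, v) in (stimuli or [])
              if f in ("conc", "concInit")]
    if events:
        loev = etree.SubElement(mdl, _q("listOfEvents"))
        for i, (t, path, _field, value) in enumerate(events):
            ev = etree.SubElement(loev, _q("event"))
            ev.set("id", f"stim_{i}")
            ev.set("useValuesFromTriggerTime", "true")
            trig = etree.SubElement(ev, _q("trigger"))
            trig.set("initialValue", "false")
            trig.set("persistent", "true")
            math = _mml("math")
            tsym = _mml("csymbol")
            tsym.set("definitionURL", _TIME_CSYMBOL)
            tsym.text = " time "
            math.append(_apply("geq", tsym, _cn(t)))
            trig.append(math)
            loea = etree.SubElement(ev, _q("listOfEventAssignments"))
            ea = etree.SubElement(loea, _q("eventAssignment"))
            ea.set("variable", sid_of[path])
            math = _mml("math")
            math.append(_cn(value))
            ea.append(math)

    if model.groups:
        log = etree.SubElement(mdl, _q("listOfGroups", GROUPS_NS))
        for i, g in enumerate(sorted(model.groups)):
            ge = etree.SubElement(log, _q("group", GROUPS_NS))
            ge.set(_q("id", GROUPS_NS), f"grp_{i}")
            ge.set(_q("name", GROUPS_NS), g)
            ge.set(_q("kind", GROUPS_NS), "collection")
            members = [p for p in sorted(model.entity_paths())
                       if parent_path(p) == g]
            if members:
                lom = etree.SubElement(ge, _q("listOfMembers", GROUPS_NS))
                for m in members:
                    me = etree.SubElement(lom, _q("member", GROUPS_NS))
                    me.set(_q("idRef", GROUPS_NS), sid_of[m])

    tree = etree.ElementTree(sbml)
    tree.write(str(dest), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# --------------------------------------------------------------------------
# Reader
# --------------------------------------------------------------------------

def _path_of(el: etree._Element) -> str:
    name = el.get("name", "")
    if name.startswith("/"):
        return name
    return "/" + el.get("id")


def read_sbml(source: str | Path) -> ReactionModel:
    """Load an SBML L3 file into a :class:`ReactionModel`.

    Raises :class:`ModelError` on parse failure or on a kinetic law that is
    neither mass action nor Michaelis-Menten (the offending reaction is
    named in the message).
    """
    try:
        tree = etree.parse(str(source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ModelError(f"cannot parse SBML file {source}: {exc}") from None
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ModelError(f"{source}: not an SBML document")
    ns = etree.QName(root).namespace
    mdl = root.find(_q("model", ns))
    if mdl is None:
        raise ModelError(f"{source}: no <model> element")

    model = ReactionModel()
    comp_name_of_id: dict[str, str] = {}
    for c in mdl.findall(f"{_q('listOfCompartments', ns)}/{_q('compartment', ns)}"):
        name = c.get("name") or c.get("id")
        comp_name_of_id[c.get("id")] = name
        model.add_compartment(Compartment(name, float(c.get("size", "1e-15"))))

    path_of_id: dict[str, str] = {}
    species = mdl.findall(f"{_q('listOfSpecies', ns)}/{_q('species', ns)}")
    for s in species:
        path = _path_of(s)
        path_of_id[s.get("id")] = path
    reactions = mdl.findall(f"{_q('listOfReactions', ns)}/{_q('reaction', ns)}")
    for r in reactions:
        path_of_id[r.get("id")] = _path_of(r)

    # groups define the hierarchy; entity paths already embed it when the
    # writer was ours, but honor explicit groups for foreign files too
    for g in mdl.findall(f"{_q('listOfGroups', GROUPS_NS)}/{_q('group', GROUPS_NS)}"):
        gname = g.get(_q("name", GROUPS_NS)) or g.get(_q("id", GROUPS_NS))
        if gname and gname.startswith("/"):
            model.add_group(gname)

    for s in species:
        path = path_of_id[s.get("id")]
        conc = float(s.get("initialConcentration", "0"))
        comp = comp_name_of_id.get(s.get("compartment"), "default")
        buffered = s.get("boundaryCondition", "false") == "true"
        model.add_pool(Pool(path, comp, conc, buffered))

    for r in reactions:
        rid = r.get("id")
        path = path_of_id[rid]
        kl = r.find(_q("kineticLaw", ns))
        params: dict[str, float] = {}
        if kl is not None:
            for tag in ("listOfLocalParameters", "listOfParameters"):
                for lp in kl.findall(f"{_q(tag, ns)}/*"):
                    params[lp.get("id")] = float(lp.get("value", "0"))

        def _side(tag):
            out = []
            for ref in r.findall(f"{_q(tag, ns)}/{_q('speciesReference', ns)}"):
                out.append((path_of_id[ref.get("species")],
                            int(float(ref.get("stoichiometry", "1")))))
            return out

        subs, prods = _side("listOfReactants"), _side("listOfProducts")
        mods = [path_of_id[m.get("species")] for m in
                r.findall(f"{_q('listOfModifiers', ns)}/"
                          f"{_q('modifierSpeciesReference', ns)}")]
        if {"Km", "kcat"} <= set(params) and mods:
            if len(subs) != 1 or len(prods) != 1:
                raise ModelError(f"{source}: enzymatic reaction {rid!r} must "
                                 "have one substrate and one product")
            model.add_enzyme(Enzyme(path, mods[0], subs[0][0], prods[0][0],
                                    params["Km"], params["kcat"]))
        elif "Kf" in params or "k1" in params:
            kf = params.get("Kf", params.get("k1", 0.0))
            kb = params.get("Kb", params.get("k2", 0.0))
            model.add_reaction(Reaction(path, subs, prods, kf, kb))
        else:
            raise ModelError(
                f"{source}: reaction {rid!r} has an unsupported kinetic law "
                "(expected mass-action Kf/Kb or Michaelis-Menten Km/kcat "
                "local parameters)")
    return model
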
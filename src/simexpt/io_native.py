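"""Line-oriented native text dialect for reaction-network and HH models.

The dialect is deliberately diffable and hand-writable: UTF-8, one entity per
record, hard-tab field separator, ``#`` comment lines.  Floats are written
with ``repr`` so a write/read cycle is bit-exact.  Record kinds:

    compartment <tab> name <tab> volume_litres
    group       <tab> /path
    pool        <tab> /path <tab> compartment <tab> concInit_mM <tab> buffered(0|1)
    reaction    <tab> /path <tab> subs <tab> prods <tab> Kf <tab> Kb
    enzyme      <tab> /path <tab> /enzPool <tab> /substrate <tab> /product <tab> Km <tab> kcat
    hh          <tab> Cm <tab> gNa <tab> gK <tab> gLeak <tab> ENa <tab> EK <tab> ELeak <tab> Vm

``subs``/``prods`` join participants with ``+``, each as ``/pool/path:stoich``.
A file containing an ``hh`` record describes a Hodgkin-Huxley membrane and
may not also contain chemical records.
"""

from __future__ import annotations

from pathlib import Path

from .model import (Compartment, Enzyme, HHCompartment, ModelError, Pool,
                    Reaction, ReactionModel)

__all__ = ["read_native", "write_native"]

_HEADER = "# simexpt native model v1"


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_side(text: str, where: str) -> list[tuple[str, int]]:
    out = []
    for term in text.split("+"):
        path, sep, stoich = term.rpartition(":")
        if not sep:
            raise ModelError(f"{where}: malformed participant {term!r} "
                             "(expected /path:stoich)")
        out.append((path, int(stoich)))
    return out


def read_native(source: str | Path):
    """Parse a native-dialect file.

    Returns a :class:`ReactionModel`, or an :class:`HHCompartment` when the
    file holds an ``hh`` record.
    """
    model = ReactionModel()
    hh: HHCompartment | None = None
    n_chem = 0
    for lineno, raw in enumerate(Path(source).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        kind, args = fields[0], fields[1:]
        where = f"{source}:{lineno}"
        try:
            if kind == "compartment":
                model.add_compartment(Compartment(args[0], float(args[1])))
                n_chem += 1
            elif kind == "group":
                model.add_group(args[0])
                n_chem += 1
            elif kind == "pool":
                model.add_pool(Pool(args[0], args[1], float(args[2]),
                                    bool(int(args[3]))))
                n_chem += 1
            elif kind == "reaction":
                model.add_reaction(Reaction(
                    args[0],
                    _parse_side(args[1], where),
                    _parse_side(args[2], where),
                    float(args[3]), float(args[4])))
                n_chem += 1
            elif kind == "enzyme":
                model.add_enzyme(Enzyme(args[0], args[1], args[2], args[3],
                                        float(args[4]), float(args[5])))
                n_chem += 1
            elif kind == "hh":
                if hh is not None:
                    raise ModelError("multiple hh records")
                hh = HHCompartment(*(float(a) for a in args))
            else:
                raise ModelError(f"unknown record kind {kind!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ModelError):
                raise ModelError(f"{where}: {exc}") from None
            raise ModelError(f"{where}: bad {kind!r} record: {exc}") from None
    if hh is not None:
        if n_chem:
            raise ModelError(f"{source}: hh record mixed with chemical records")
        return hh
    return model


def _side(parts: list[tuple[str, int]]) -> str:
    return "+".join(f"{p}:{n}" for p, n in parts)


def write_native(model, dest: str | Path) -> None:
    """Write a :class:`ReactionModel` or :class:`HHCompartment` to *dest*."""
    lines = [_HEADER]
    if isinstance(model, HHCompartment):
        lines.append("\t".join(["hh"] + [_fmt(getattr(model, f)) for f in
                     ("Cm", "gNa", "gK", "gLeak", "ENa", "EK", "ELeak", "Vm")]))
    else:
        for comp in sorted(model.compartments.values(), key=lambda c: c.name):
            lines.append(f"compartment\t{comp.name}\t{_fmt(comp.volume)}")
        for g in sorted(model.groups):
            lines.append(f"group\t{g}")
        for pool in sorted(model.pools.values(), key=lambda p: p.path):
            lines.append("\t".join(["pool", pool.path, pool.compartment,
                                    _fmt(pool.concInit),
                                    str(int(pool.buffered))]))
        for rxn in sorted(model.reactions.values(), key=lambda r: r.path):
            lines.append("\t".join(["reaction", rxn.path, _side(rxn.substrates),
                                    _side(rxn.products), _fmt(rxn.Kf),
                                    _fmt(rxn.Kb)]))
        for enz in sorted(model.enzymes.values(), key=lambda e: e.path):
            lines.append("\t".join(["enzyme", enz.path, enz.enzymePool,
                                    enz.substrate, enz.product,
                                    _fmt(enz.Km), _fmt(enz.kcat)]))
    Path(dest).write_text("\n".join(lines) + "\n")
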
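"""Hierarchical reaction-network model representation.

A :class:`ReactionModel` is a tree of pathway groups containing molecular
pools, mass-action reactions and Michaelis-Menten enzymes, addressed by
rooted '/'-separated path strings (``/kinetics/MAPK/MAPK_p``).  The canonical
internal unit frame is millimolar, seconds and litres; every reader converts
on ingest and every writer converts on demand.

Buffered pools are held at their initial concentration throughout any
simulation; they model species clamped by the experimental preparation.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

__all__ = [
    "Compartment",
    "Pool",
    "Reaction",
    "Enzyme",
    "ReactionModel",
    "ModelError",
    "PathError",
    "resolve_paths",
    "validate_model",
    "parent_path",
    "is_under",
]


class ModelError(ValueError):
    """Raised when a model is structurally invalid for the requested use."""


class PathError(KeyError):
    """Raised when a path selector resolves to nothing."""

    def __str__(self) -> str:  # KeyError quotes its payload; we want prose
        return self.args[0] if self.args else ""


def parent_path(path: str) -> str:
    """Parent group of a rooted path (``/a/b/c`` -> ``/a/b``; ``/a`` -> ``/``)."""
    if path == "/":
        return "/"
    head, _, _ = path.rpartition("/")
    return head or "/"


def is_under(path: str, group: str) -> bool:
    """True if *path* lies in the subtree rooted at *group* (inclusive)."""
    if group == "/":
        return True
    return path == group or path.startswith(group + "/")


def _check_path(path: str) -> str:
    if not path.startswith("/") or path == "/" or path.endswith("/") or "//" in path:
        raise ModelError(f"malformed entity path {path!r}: must be rooted, "
                         "'/'-separated, non-empty segments")
    return path


@dataclass
class Compartment:
    """A well-stirred volume. ``volume`` is in litres and must be positive."""

    name: str
    volume: float = 1e-15

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ModelError(f"compartment {self.name}: volume must be > 0")


@dataclass
class Pool:
    """A molecular species with a concentration (mM).

    ``buffered`` pools hold ``concInit`` constant during integration.
    """

    path: str
    compartment: str = "default"
    concInit: float = 0.0
    buffered: bool = False

    def __post_init__(self) -> None:
        _check_path(self.path)


@dataclass
class Reaction:
    """Reversible mass-action reaction.

    ``substrates`` / ``products`` are lists of ``(pool path, stoichiometry)``.
    Kf has units 1/s * (1/mM)^(sum of substrate stoichiometries - 1); Kb the
    analogous units over products.  Flux = Kf*prod([S]^n) - Kb*prod([P]^m).
    """

    path: str
    substrates: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    Kf: float = 0.0
    Kb: float = 0.0

    def __post_init__(self) -> None:
        _check_path(self.path)

    def participants(self) -> list[str]:
        return [p for p, _ in self.substrates] + [p for p, _ in self.products]


@dataclass
class Enzyme:
    """Michaelis-Menten catalytic step: v = kcat*[E]*[S]/(Km + [S])."""

    path: str
    enzymePool: str = ""
    substrate: str = ""
    product: str = ""
    Km: float = 1.0       # mM
    kcat: float = 1.0     # 1/s

    def __post_init__(self) -> None:
        _check_path(self.path)

    def participants(self) -> list[str]:
        return [self.enzymePool, self.substrate, self.product]


@dataclass
class HHCompartment:
    """Single-compartment Hodgkin-Huxley membrane (squid-axon defaults).

    Units: Cm uF/cm^2, conductances mS/cm^2, potentials mV, current uA/cm^2.
    """

    Cm: float = 1.0
    gNa: float = 120.0
    gK: float = 36.0
    gLeak: float = 0.3
    ENa: float = 50.0
    EK: float = -77.0
    ELeak: float = -54.387
    Vm: float = -65.0

    def __post_init__(self) -> None:
        for name in ("Cm", "gNa", "gK", "gLeak"):
            if getattr(self, name) < 0:
                raise ModelError(f"HH compartment: {name} must be >= 0")


class ReactionModel:
    """A hierarchical reaction network.

    Groups form a tree rooted at ``/``; every entity's parent group is the
    directory part of its path.  Intermediate groups are created implicitly
    when entities are added.
    """

    def __init__(self) -> None:
        self.compartments: dict[str, Compartment] = {}
        self.groups: set[str] = set()          # excludes the root "/"
        self.pools: dict[str, Pool] = {}
        self.reactions: dict[str, Reaction] = {}
        self.enzymes: dict[str, Enzyme] = {}

    # -- construction -----------------------------------------------------
    def add_compartment(self, comp: Compartment) -> Compartment:
        if comp.name in self.compartments:
            raise ModelError(f"duplicate compartment name {comp.name!r}")
        self.compartments[comp.name] = comp
        return comp

    def add_group(self, path: str) -> None:
        _check_path(path)
        p = path
        while p != "/":
            self.groups.add(p)
            p = parent_path(p)

    def _claim_path(self, path: str) -> None:
        if path in self.pools or path in self.reactions or path in self.enzymes \
                or path in self.groups:
            raise ModelError(f"duplicate path {path!r}")
        if parent_path(path) != "/":
            self.add_group(parent_path(path))

    def add_pool(self, pool: Pool) -> Pool:
        if pool.compartment not in self.compartments:
            if not self.compartments and pool.compartment == "default":
                self.add_compartment(Compartment("default"))
            else:
                raise ModelError(
                    f"pool {pool.path}: unknown compartment {pool.compartment!r}")
        self._claim_path(pool.path)
        self.pools[pool.path] = pool
        return pool

    def add_reaction(self, rxn: Reaction) -> Reaction:
        self._claim_path(rxn.path)
        self.reactions[rxn.path] = rxn
        return rxn

    def add_enzyme(self, enz: Enzyme) -> Enzyme:
        self._claim_path(enz.path)
        self.enzymes[enz.path] = enz
        return enz

    # -- queries ----------------------------------------------------------
    def entity_paths(self) -> set[str]:
        return set(self.pools) | set(self.reactions) | set(self.enzymes)

    def entity(self, path: str):
        for table in (self.pools, self.reactions, self.enzymes):
            if path in table:
                return table[path]
        raise PathError(f"no entity at path {path!r}")

    def copy(self) -> "ReactionModel":
        return _copy.deepcopy(self)

    def structurally_equal(self, other: "ReactionModel") -> bool:
        """Field-for-field equality of compartments, groups and entities."""
        return (
            self.compartments == other.compartments
            and self.groups == other.groups
            and self.pools == other.pools
            and self.reactions == other.reactions
            and self.enzymes == other.enzymes
        )

    def __repr__(self) -> str:
        return (f"<ReactionModel pools={len(self.pools)} "
                f"reactions={len(self.reactions)} enzymes={len(self.enzymes)} "
                f"groups={len(self.groups)}>")


def resolve_paths(model: ReactionModel, selectors: list[str]) -> set[str]:
    """Resolve path selectors to the set of matching entity paths.

    A selector naming a group returns every entity in that group's subtree;
    a selector naming a leaf entity returns just that entity.  The result is
    the union over selectors.  A selector that matches nothing raises
    :class:`PathError` naming it.
    """
    out: set[str] = set()
    entities = model.entity_paths()
    for sel in selectors:
        if sel == "/" or sel in model.groups:
            hits = {p for p in entities if is_under(p, sel)}
        elif sel in entities:
            hits = {sel}
        else:
            raise PathError(f"selector {sel!r} matches no group or entity")
        out |= hits
    return out


def validate_model(model: ReactionModel) -> list[str]:
    """Check every model invariant; return one diagnostic string per violation.

    An empty list means the model is valid.  Diagnostics name the offending
    entity and the rule broken; no exception is raised.
    """
    diags: list[str] = []
    for comp in model.compartments.values():
        if comp.volume <= 0:
            diags.append(f"compartment {comp.name}: volume must be > 0")
    for pool in model.pools.values():
        if pool.concInit < 0:
            diags.append(f"pool {pool.path}: concInit must be >= 0 "
                         f"(got {pool.concInit})")
        if pool.compartment not in model.compartments:
            diags.append(f"pool {pool.path}: unknown compartment "
                         f"{pool.compartment!r}")
    for rxn in model.reactions.values():
        if rxn.Kf < 0:
            diags.append(f"reaction {rxn.path}: Kf must be >= 0")
        if rxn.Kb < 0:
            diags.append(f"reaction {rxn.path}: Kb must be >= 0")
        if not rxn.substrates or not rxn.products:
            diags.append(f"reaction {rxn.path}: needs at least one substrate "
                         "and one product")
        for p, n in rxn.substrates + rxn.products:
            if n < 1:
                diags.append(f"reaction {rxn.path}: stoichiometry for {p} "
                             "must be >= 1")
            if p not in model.pools:
                diags.append(f"reaction {rxn.path}: participant {p} is not a "
                             "pool in the model")
    for enz in model.enzymes.values():
        if enz.Km <= 0:
            diags.append(f"enzyme {enz.path}: Km must be > 0")
        if enz.kcat < 0:
            diags.append(f"enzyme {enz.path}: kcat must be >= 0")
        for p in enz.participants():
            if p not in model.pools:
                diags.append(f"enzyme {enz.path}: participant {p} is not a "
                             "pool in the model")
    return diags
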
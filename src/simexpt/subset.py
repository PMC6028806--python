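"""Experiment-specific sub-model extraction.

An experiment usually touches a few pathways of a large composite model.
:func:`extract_subset` selects those pathways, removes entities absent from
the experimental preparation, detects reactions left "dangling" (missing a
substrate, product or enzyme after extraction), applies condition overrides
(buffering, clamped concentrations, altered rate constants), and re-targets
the experiment's name map onto the extracted model.

Deleting a pool that a kept reaction consumes creates a dangling reaction;
the default policy is *strict* — extraction fails, carrying the full report —
because a silently pruned reaction hides a modelling error.  The *prune*
policy removes dangling reactions but always reports every one.  Loss of
regulatory inputs (signals that now build up uncontrolled) is NOT detected
automatically; it needs human inspection of the extracted model.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field

from .model import (Enzyme, ModelError, PathError, Pool, Reaction,
                    ReactionModel, is_under, resolve_paths, validate_model)

__all__ = ["SubsetSpec", "DanglingReport", "DanglingError",
           "extract_subset", "find_dangling", "apply_condition",
           "OVERRIDABLE_FIELDS"]

log = logging.getLogger(__name__)

# (entity class, field) pairs a condition override may touch
OVERRIDABLE_FIELDS = {
    Pool: {"concInit", "buffered"},
    Reaction: {"Kf", "Kb"},
    Enzyme: {"Km", "kcat"},
}


@dataclass
class SubsetSpec:
    """What to extract and how to rename.

    ``includePaths`` select pathways/entities (group selectors take whole
    subtrees); ``deletePaths`` remove entities or whole groups from the
    selection; ``parameterOverrides`` are ``(path, field, value)`` condition
    changes applied after extraction; ``entityMap`` maps experiment-domain
    names to one or more model pool paths (many-to-one readouts are summed).
    """

    includePaths: list[str] = field(default_factory=list)
    deletePaths: list[str] = field(default_factory=list)
    parameterOverrides: list[tuple[str, str, object]] = field(default_factory=list)
    entityMap: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class DanglingReport:
    """Reactions/enzymes whose participants fail to resolve, with the
    missing pool paths for each."""

    entries: list[tuple[str, list[str]]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def paths(self) -> set[str]:
        return {p for p, _ in self.entries}


class DanglingError(ModelError):
    """Strict extraction refused: dangling reactions present."""

    def __init__(self, report: DanglingReport):
        self.report = report
        detail = "; ".join(f"{p} missing {', '.join(m)}"
                           for p, m in report.entries)
        super().__init__(f"extraction leaves dangling reactions: {detail}")


def find_dangling(model: ReactionModel) -> DanglingReport:
    """Report every reaction/enzyme with >= 1 participant not in the model."""
    entries = []
    for table in (model.reactions, model.enzymes):
        for path in sorted(table):
            missing = [p for p in table[path].participants()
                       if p not in model.pools]
            if missing:
                entries.append((path, missing))
    return DanglingReport(entries)


def _set_field(model: ReactionModel, path: str, fieldname: str, value) -> None:
    if fieldname == "volume":
        if path.lstrip("/") in model.compartments:
            comp = model.compartments[path.lstrip("/")]
        elif path in model.compartments:
            comp = model.compartments[path]
        else:
            raise PathError(f"override target {path!r}: no such compartment")
        if float(value) <= 0:
            raise ModelError(f"override {path}.volume: must be > 0")
        comp.volume = float(value)
        return
    entity = model.entity(path)
    allowed = OVERRIDABLE_FIELDS.get(type(entity), set())
    if fieldname not in allowed:
        raise ModelError(f"override {path}.{fieldname}: field not overridable "
                         f"on {type(entity).__name__} (allowed: {sorted(allowed)})")
    if fieldname == "buffered":
        entity.buffered = _as_bool(value)
        return
    val = float(value)
    if val < 0:
        raise ModelError(f"override {path}.{fieldname}: must be >= 0 (got {val})")
    if fieldname == "Km" and val == 0:
        raise ModelError(f"override {path}.Km: must be > 0")
    setattr(entity, fieldname, val)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("1", "true", "yes"):
            return True
        if low in ("0", "false", "no"):
            return False
        raise ModelError(f"cannot read {value!r} as a boolean")
    return bool(value)


def apply_condition(model: ReactionModel, overrides) -> ReactionModel:
    """Return a copy of *model* with condition overrides applied.

    Each override is ``(entity path, field, value)``.  Setting
    ``buffered=true`` freezes the pool at its (possibly overridden)
    concInit.  Overrides on disjoint entities commute.
    """
    out = model.copy()
    for path, fieldname, value in overrides:
        _set_field(out, path, fieldname, value)
    return out


def extract_subset(model: ReactionModel, spec: SubsetSpec,
                   policy: str = "strict") -> tuple[ReactionModel, DanglingReport]:
    """Extract the experiment's sub-model.

    Keeps ``resolve_paths(includePaths)`` minus ``deletePaths`` (a delete
    path naming a group removes its whole subtree); then handles dangling
    reactions per *policy* (``strict`` raises :class:`DanglingError`,
    ``prune`` removes and logs them); then applies the overrides and checks
    the entity map resolves.  Extraction is idempotent.
    """
    if policy not in ("strict", "prune"):
        raise ValueError(f"unknown extraction policy {policy!r}")
    keep = resolve_paths(model, spec.includePaths)

    for d in spec.deletePaths:
        if d in model.groups or d == "/":
            doomed = {p for p in keep if is_under(p, d)}
        elif d in keep:
            doomed = {d}
        else:
            # absent or never-selected target: no-op, so that re-extracting
            # an already-extracted model with the same spec is idempotent
            if d not in model.entity_paths():
                log.warning("delete path %s matches nothing; ignored", d)
            doomed = set()
        keep -= doomed

    sub = ReactionModel()
    for name, comp in model.compartments.items():
        sub.add_compartment(type(comp)(name, comp.volume))
    for path in sorted(keep):
        entity = _copy.deepcopy(model.entity(path))
        if isinstance(entity, Pool):
            sub.add_pool(entity)
    for path in sorted(keep):
        entity = _copy.deepcopy(model.entity(path))
        if isinstance(entity, Reaction):
            sub.add_reaction(entity)
        elif isinstance(entity, Enzyme):
            sub.add_enzyme(entity)

    report = find_dangling(sub)
    if report:
        if policy == "strict":
            raise DanglingError(report)
        for path, missing in report.entries:
            log.warning("pruning dangling reaction %s (missing %s)",
                        path, ", ".join(missing))
            sub.reactions.pop(path, None)
            sub.enzymes.pop(path, None)

    for path, fieldname, value in spec.parameterOverrides:
        _set_field(sub, path, fieldname, value)

    for name, targets in spec.entityMap.items():
        for t in targets:
            if t not in sub.pools:
                raise PathError(
                    f"entity map {name!r} -> {t!r}: not a pool in the "
                    "extracted model")

    diags = [d for d in validate_model(sub)]
    if diags:
        raise ModelError("extracted model invalid: " + "; ".join(diags))
    return sub, report
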
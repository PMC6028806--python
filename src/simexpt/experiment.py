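"""Structured experiment definitions: parse, validate, write.

An experiment file has five blocks — metadata (who/where the data came
from), biological context (species, preparation, temperature, pH), stimuli
(what was done to the preparation), readouts (what was measured), and the
model mapping (which pathways of the reference model participate, what to
delete or override to match the experimental conditions, and how experiment
entity names map onto model paths).  The first four blocks are purely in
the experimental domain; only the mapping block knows about the model.

Three experiment classes are supported:

* **TimeSeries** — stimuli are time/value assignment pairs; readout
  coordinates are times.
* **DoseResponse** — exactly one stimulus entity whose table enumerates the
  doses (the dose is clamped for each measurement); readout coordinates are
  those doses.
* **MultiStimulus** — named combinations of clamped settings (control,
  +drug A, +drug B, A+B, ...), one readout bar per combination after a
  stated settle time.

An electrical time-series (field ``current`` in, ``Vm`` out, solver ``hh``)
uses the identical TimeSeries layout.

File dialect: UTF-8, hard-tab separated, ``#`` comment lines, block headers
are reserved first-column keywords.  Values are converted to the canonical
frame (mM, s, mV, uA/cm^2) on ingest; the writer emits the declared units.
A JSON mirror of the same schema is read and written by file extension.
See ``docs/experiment-format.md`` for the full schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

from .model import HHCompartment, ReactionModel
from .scoring import FormulaError, parse_formula
from .subset import DanglingError, SubsetSpec, extract_subset
from .units import UnitError, from_canonical, kind_of, to_canonical

__all__ = ["ExperimentMetadata", "ExperimentContext", "StimulusEntry",
           "Combination", "ReadoutEntry", "ModelMap", "ExperimentDoc",
           "ExperimentFormatError", "parse_experiment_tsv",
           "write_experiment_tsv", "load_experiment", "save_experiment",
           "validate_experiment"]

EXPT_TYPES = ("TimeSeries", "DoseResponse", "MultiStimulus")
EXPT_SOURCES = ("paperReference", "inHouse", "database")
STIM_FIELDS = ("conc", "concInit", "buffered", "current")
READOUT_FIELDS = ("conc", "Vm")
NORMALIZATIONS = ("absolute", "foldChange", "percentOfMax")
SOLVERS = ("ode_stiff", "ode_nonstiff", "hh")

_BLOCKS = ("Experiment metadata", "Experiment context", "Stimuli",
           "Readouts", "Model mapping")


class ExperimentFormatError(ValueError):
    pass


@dataclass
class ExperimentMetadata:
    transcriber: str = ""
    organization: str = ""
    exptSource: str = "inHouse"
    citationId: str = ""
    authors: str = ""
    journal: str = ""


@dataclass
class ExperimentContext:
    species: str = ""
    cellType: str = ""
    preparation: str = ""
    temperature: float | None = None   # degrees Celsius
    pH: float | None = None
    notes: str = ""


@dataclass
class StimulusEntry:
    """One manipulated entity.  ``points`` are (coordinate, value) pairs in
    canonical units; for time-series the coordinate is time in seconds, for
    dose-response coordinate and value coincide (the dose)."""

    entityName: str
    field: str = "conc"
    unit: str = "mM"
    points: list[tuple[float, float]] = dc_field(default_factory=list)


@dataclass
class Combination:
    """A named multi-stimulus setting: the listed entities are clamped at
    the given values (canonical units) at t=0."""

    label: str
    settings: list[tuple[str, float]] = dc_field(default_factory=list)


@dataclass
class ReadoutEntry:
    """One monitored entity.  ``points`` are (coordinate, value, stderr)
    triples; stderr is None when not reported.  For MultiStimulus the
    coordinate is the combination label."""

    entityName: str
    field: str = "conc"
    unit: str = "mM"
    normalization: str = "absolute"
    points: list[tuple[object, float, float | None]] = dc_field(default_factory=list)
    settle: float | None = None   # s; settle time for bar/dose readouts


@dataclass
class ModelMap:
    refModel: str = ""
    subset: SubsetSpec = dc_field(default_factory=SubsetSpec)
    solver: str = "ode_stiff"
    scoringFormula: str = ""      # empty -> package default formula
    weight: float = 1.0
    settleBeforeStart: bool = True


@dataclass
class ExperimentDoc:
    exptType: str = "TimeSeries"
    metadata: ExperimentMetadata = dc_field(default_factory=ExperimentMetadata)
    context: ExperimentContext = dc_field(default_factory=ExperimentContext)
    stimuli: list[StimulusEntry] = dc_field(default_factory=list)
    combinations: list[Combination] = dc_field(default_factory=list)
    readouts: list[ReadoutEntry] = dc_field(default_factory=list)
    modelMap: ModelMap = dc_field(default_factory=ModelMap)

    def equivalent(self, other: "ExperimentDoc", rel: float = 1e-12) -> bool:
        """Field-for-field equality with floats compared to 12 significant
        digits (unit conversion is multiplicative, so a write/parse cycle
        reproduces values to rounding, not bit-exactly)."""
        def close(a, b):
            if isinstance(a, float) and isinstance(b, (float, int)):
                return a == b or abs(a - b) <= rel * max(abs(a), abs(b))
            if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
                return len(a) == len(b) and all(close(x, y)
                                                for x, y in zip(a, b))
            if isinstance(a, dict) and isinstance(b, dict):
                return a.keys() == b.keys() and all(close(a[k], b[k])
                                                    for k in a)
            return a == b
        return close(_doc_to_dict(self), _doc_to_dict(other))


# --------------------------------------------------------------------------
# TSV parsing
# --------------------------------------------------------------------------

def _split_blocks(lines: list[str], source) -> dict[str, list[tuple[int, list[str]]]]:
    blocks: dict[str, list[tuple[int, list[str]]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] in _BLOCKS:
            current = fields[0]
            blocks.setdefault(current, [])
            continue
        if current is None:
            raise ExperimentFormatError(
                f"{source}:{lineno}: content before any block header")
        blocks[current].append((lineno, fields))
    for b in _BLOCKS:
        if b not in blocks:
            raise ExperimentFormatError(
                f"{source}: missing mandatory block {b!r}")
    return blocks


def _err(source, lineno, msg):
    raise ExperimentFormatError(f"{source}:{lineno}: {msg}")


def _get(fields, i, default=""):
    return fields[i] if i < len(fields) and fields[i] != "" else default


def _parse_float(source, lineno, text, what):
    try:
        return float(text)
    except ValueError:
        _err(source, lineno, f"cannot read {text!r} as a number for {what}")


def _kv_block(rows, source) -> dict[str, tuple[int, str]]:
    out = {}
    for lineno, fields in rows:
        out[fields[0]] = (lineno, _get(fields, 1))
    return out


def _check_unit(source, lineno, unit, allowed_kinds):
    try:
        kind = kind_of(unit)
    except UnitError as exc:
        _err(source, lineno, str(exc))
    if kind not in allowed_kinds:
        _err(source, lineno, f"unit {unit!r} ({kind}) not valid here; "
             f"expected one of kinds {sorted(allowed_kinds)}")


_FIELD_UNIT_KINDS = {
    "conc": {"conc", "dimensionless"},
    "concInit": {"conc", "dimensionless"},
    "buffered": {"dimensionless"},
    "current": {"current"},
    "Vm": {"volt"},
}


def _parse_stimuli(rows, expt_type, source):
    stimuli: list[StimulusEntry] = []
    combos: list[Combination] = []
    entry: StimulusEntry | None = None
    combo: Combination | None = None
    combo_header = False
    table_header: list[str] | None = None
    last_coord = None
    for lineno, fields in rows:
        key = fields[0]
        if key == "stimulus":
            name = _get(fields, 1)
            fld = _get(fields, 2, "conc")
            unit = _get(fields, 3, "mM")
            if fld not in STIM_FIELDS:
                _err(source, lineno, f"unknown stimulus field {fld!r} "
                     f"(allowed: {STIM_FIELDS})")
            _check_unit(source, lineno, unit, _FIELD_UNIT_KINDS[fld])
            entry = StimulusEntry(name, fld, unit)
            stimuli.append(entry)
            table_header, last_coord = None, None
        elif key == "combination":
            combo = Combination(_get(fields, 1))
            if not combo.label:
                _err(source, lineno, "combination needs a label")
            combos.append(combo)
            combo_header = False
        elif combo is not None and key == "entity":
            combo_header = True      # header row: entity / value / unit
        elif combo is not None:
            if not combo_header:
                _err(source, lineno, "combination rows must follow an "
                     "'entity\\tvalue\\tunit' header")
            unit = _get(fields, 2, "mM")
            _check_unit(source, lineno, unit, {"conc", "dimensionless"})
            val = _parse_float(source, lineno, _get(fields, 1, "nan"),
                               f"combination setting {key!r}")
            if val < 0:
                _err(source, lineno, "clamp values must be >= 0")
            combo.settings.append((key, to_canonical(val, unit)))
        elif entry is not None:
            if table_header is None:
                if key not in ("time", "dose"):
                    _err(source, lineno, "stimulus table header must start "
                         "with 'time' or 'dose'")
                table_header = fields
                continue
            if table_header[0] == "dose":
                dose = to_canonical(
                    _parse_float(source, lineno, key, "dose"), entry.unit)
                if dose < 0:
                    _err(source, lineno, "doses must be >= 0")
                if last_coord is not None and dose <= last_coord:
                    _err(source, lineno, "doses must be strictly increasing")
                last_coord = dose
                entry.points.append((dose, dose))
            else:
                t = _parse_float(source, lineno, key, "time")
                if last_coord is not None and t <= last_coord:
                    _err(source, lineno, "times must be strictly increasing")
                last_coord = t
                v = _parse_float(source, lineno, _get(fields, 1, "nan"),
                                 "stimulus value")
                if entry.field != "buffered" and v < 0 \
                        and kind_of(entry.unit) == "conc":
                    _err(source, lineno, "concentration values must be >= 0")
                entry.points.append((t, to_canonical(v, entry.unit)))
        else:
            _err(source, lineno, f"unexpected row {key!r} in Stimuli block")
    if expt_type == "MultiStimulus":
        if not combos:
            _err(source, rows[0][0] if rows else 0,
                 "MultiStimulus experiment needs at least one combination")
    elif not stimuli:
        _err(source, rows[0][0] if rows else 0,
             "experiment needs at least one stimulus entry")
    return stimuli, combos


def _parse_readouts(rows, expt_type, source):
    readouts: list[ReadoutEntry] = []
    entry: ReadoutEntry | None = None
    table_header = None
    last_coord = None
    for lineno, fields in rows:
        key = fields[0]
        if key == "readout":
            name = _get(fields, 1)
            fld = _get(fields, 2, "conc")
            unit = _get(fields, 3, "mM")
            norm = _get(fields, 4, "absolute")
            if fld not in READOUT_FIELDS:
                _err(source, lineno, f"unknown readout field {fld!r} "
                     f"(allowed: {READOUT_FIELDS})")
            if norm not in NORMALIZATIONS:
                _err(source, lineno, f"unknown normalization {norm!r} "
                     f"(allowed: {NORMALIZATIONS})")
            _check_unit(source, lineno, unit, _FIELD_UNIT_KINDS[fld])
            entry = ReadoutEntry(name, fld, unit, norm)
            readouts.append(entry)
            table_header, last_coord = None, None
        elif entry is None:
            _err(source, lineno, "readout rows must follow a 'readout' line")
        elif key == "settle":
            entry.settle = _parse_float(source, lineno, _get(fields, 1, "nan"),
                                        "settle time")
            if entry.settle <= 0:
                _err(source, lineno, "settle time must be > 0")
        elif table_header is None:
            if key not in ("time", "dose", "label"):
                _err(source, lineno, "readout table header must start with "
                     "'time', 'dose' or 'label'")
            if expt_type == "MultiStimulus" and key != "label":
                _err(source, lineno, "MultiStimulus readouts are labelled "
                     "by combination")
            table_header = fields
        else:
            stderr_txt = _get(fields, 2)
            stderr = None
            if stderr_txt:
                stderr = to_canonical(
                    _parse_float(source, lineno, stderr_txt, "stderr"),
                    entry.unit)
                if stderr < 0:
                    _err(source, lineno, "stderr must be >= 0")
            value = to_canonical(
                _parse_float(source, lineno, _get(fields, 1, "nan"),
                             "readout value"), entry.unit)
            if table_header[0] == "label":
                entry.points.append((key, value, stderr))
            else:
                coord = _parse_float(source, lineno, key,
                                     table_header[0])
                if table_header[0] == "dose":
                    coord = to_canonical(coord, entry.unit)
                if last_coord is not None and coord <= last_coord:
                    _err(source, lineno,
                         f"{table_header[0]} column must be strictly "
                         "increasing")
                last_coord = coord
                entry.points.append((coord, value, stderr))
    if not readouts or not any(e.points for e in readouts):
        _err(source, rows[0][0] if rows else 0,
             "experiment needs at least one readout point")
    return readouts


def _parse_modelmap(rows, source) -> ModelMap:
    mm = ModelMap()
    for lineno, fields in rows:
        key = fields[0]
        if key == "refModel":
            mm.refModel = _get(fields, 1)
        elif key == "solver":
            mm.solver = _get(fields, 1)
            if mm.solver not in SOLVERS:
                _err(source, lineno, f"unknown solver {mm.solver!r} "
                     f"(allowed: {SOLVERS})")
        elif key == "weight":
            mm.weight = _parse_float(source, lineno, _get(fields, 1, "nan"),
                                     "weight")
            if mm.weight < 0:
                _err(source, lineno, "weight must be >= 0")
        elif key == "scoringFormula":
            mm.scoringFormula = _get(fields, 1)
            if mm.scoringFormula:
                try:
                    parse_formula(mm.scoringFormula)
                except FormulaError as exc:
                    _err(source, lineno, f"bad scoring formula: {exc}")
        elif key == "settleBeforeStart":
            mm.settleBeforeStart = _get(fields, 1, "1").strip().lower() \
                in ("1", "true", "yes")
        elif key == "include":
            mm.subset.includePaths.extend(f for f in fields[1:] if f)
        elif key == "delete":
            mm.subset.deletePaths.extend(f for f in fields[1:] if f)
        elif key == "override":
            if len(fields) < 4:
                _err(source, lineno, "override needs path, field, value")
            mm.subset.parameterOverrides.append(
                (fields[1], fields[2], fields[3]))
        elif key == "map":
            targets = [f for f in fields[2:] if f]
            if not targets:
                _err(source, lineno, "map needs at least one model path")
            mm.subset.entityMap.setdefault(_get(fields, 1), []).extend(targets)
        else:
            _err(source, lineno, f"unknown model-mapping key {key!r}")
    return mm


def parse_experiment_tsv(source: str | Path) -> ExperimentDoc:
    """Parse a five-block experiment tsv file into a validated
    :class:`ExperimentDoc` (canonical units).  Errors name the file, line
    and field."""
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    blocks = _split_blocks(lines, source)

    meta_kv = _kv_block(blocks["Experiment metadata"], source)
    expt_type = meta_kv.pop("exptType", (0, ""))[1]
    if expt_type not in EXPT_TYPES:
        raise ExperimentFormatError(
            f"{source}: exptType must be one of {EXPT_TYPES}, "
            f"got {expt_type!r}")
    meta = ExperimentMetadata()
    for key, (lineno, val) in meta_kv.items():
        if not hasattr(meta, key):
            _err(source, lineno, f"unknown metadata field {key!r}")
        setattr(meta, key, val)
    if meta.exptSource not in EXPT_SOURCES:
        raise ExperimentFormatError(
            f"{source}: exptSource must be one of {EXPT_SOURCES}, "
            f"got {meta.exptSource!r}")

    ctx = ExperimentContext()
    for key, (lineno, val) in _kv_block(blocks["Experiment context"],
                                        source).items():
        if not hasattr(ctx, key):
            _err(source, lineno, f"unknown context field {key!r}")
        if key in ("temperature", "pH"):
            if val == "":
                continue
            num = _parse_float(source, lineno, val, key)
            lo, hi = (0.0, 60.0) if key == "temperature" else (0.0, 14.0)
            if not lo <= num <= hi:
                _err(source, lineno, f"{key} {num:g} outside [{lo:g}, {hi:g}]")
            setattr(ctx, key, num)
        else:
            setattr(ctx, key, val)

    stimuli, combos = _parse_stimuli(blocks["Stimuli"], expt_type, source)
    readouts = _parse_readouts(blocks["Readouts"], expt_type, source)
    mm = _parse_modelmap(blocks["Model mapping"], source)

    doc = ExperimentDoc(expt_type, meta, ctx, stimuli, combos, readouts, mm)
    _check_doc_invariants(doc, source)
    return doc


def _check_doc_invariants(doc: ExperimentDoc, source) -> None:
    if doc.exptType == "DoseResponse":
        if len(doc.stimuli) != 1:
            raise ExperimentFormatError(
                f"{source}: DoseResponse needs exactly one stimulus entity "
                f"(got {len(doc.stimuli)})")
        doses = [p[0] for p in doc.stimuli[0].points]
        for r in doc.readouts:
            coords = [p[0] for p in r.points]
            if len(coords) != len(doses) or any(
                    abs(a - b) > 1e-9 * max(1.0, abs(a), abs(b))
                    for a, b in zip(coords, doses)):
                raise ExperimentFormatError(
                    f"{source}: readout {r.entityName!r} coordinates must "
                    "equal the stimulus dose list")
    if doc.exptType == "MultiStimulus":
        labels = {c.label for c in doc.combinations}
        for r in doc.readouts:
            for coord, _, _ in r.points:
                if coord not in labels:
                    raise ExperimentFormatError(
                        f"{source}: readout point labelled {coord!r} has no "
                        "matching combination")


# --------------------------------------------------------------------------
# TSV writing
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def write_experiment_tsv(doc: ExperimentDoc, dest: str | Path) -> None:
    """Serialize *doc*; ``parse_experiment_tsv`` of the result reproduces it
    field-for-field (floats to 12 significant digits)."""
    L: list[str] = ["# simexpt experiment v1", "Experiment metadata",
                    f"exptType\t{doc.exptType}"]
    for key in ("transcriber", "organization", "exptSource", "citationId",
                "authors", "journal"):
        L.append(f"{key}\t{getattr(doc.metadata, key)}")
    L.append("")
    L.append("Experiment context")
    for key in ("species", "cellType", "preparation", "temperature", "pH",
                "notes"):
        val = getattr(doc.context, key)
        L.append(f"{key}\t{'' if val is None else val}")
    L.append("")
    L.append("Stimuli")
    if doc.exptType == "MultiStimulus":
        for combo in doc.combinations:
            L.append(f"combination\t{combo.label}")
            L.append("entity\tvalue\tunit")
            for name, value in combo.settings:
                L.append(f"{name}\t{_fmt(value)}\tmM")
    else:
        for s in doc.stimuli:
            L.append(f"stimulus\t{s.entityName}\t{s.field}\t{s.unit}")
            if doc.exptType == "DoseResponse":
                L.append("dose")
                for dose, _ in s.points:
                    L.append(_fmt(from_canonical(dose, s.unit)))
            else:
                L.append("time\tvalue")
                for t, v in s.points:
                    L.append(f"{_fmt(t)}\t{_fmt(from_canonical(v, s.unit))}")
    L.append("")
    L.append("Readouts")
    coord_head = {"TimeSeries": "time", "DoseResponse": "dose",
                  "MultiStimulus": "label"}[doc.exptType]
    for r in doc.readouts:
        L.append(f"readout\t{r.entityName}\t{r.field}\t{r.unit}\t"
                 f"{r.normalization}")
        if r.settle is not None:
            L.append(f"settle\t{_fmt(r.settle)}")
        L.append(f"{coord_head}\tvalue\tstderr")
        for coord, value, stderr in r.points:
            if coord_head == "label":
                c = coord
            elif coord_head == "dose":
                c = _fmt(from_canonical(coord, r.unit))
            else:
                c = _fmt(coord)
            s = "" if stderr is None else _fmt(from_canonical(stderr, r.unit))
            L.append(f"{c}\t{_fmt(from_canonical(value, r.unit))}\t{s}")
    L.append("")
    L.append("Model mapping")
    mm = doc.modelMap
    L.append(f"refModel\t{mm.refModel}")
    L.append(f"solver\t{mm.solver}")
    L.append(f"weight\t{_fmt(mm.weight)}")
    L.append(f"scoringFormula\t{mm.scoringFormula}")
    L.append(f"settleBeforeStart\t{int(mm.settleBeforeStart)}")
    if mm.subset.includePaths:
        L.append("include\t" + "\t".join(mm.subset.includePaths))
    if mm.subset.deletePaths:
        L.append("delete\t" + "\t".join(mm.subset.deletePaths))
    for path, fieldname, value in mm.subset.parameterOverrides:
        L.append(f"override\t{path}\t{fieldname}\t{value}")
    for name, targets in mm.subset.entityMap.items():
        L.append(f"map\t{name}\t" + "\t".join(targets))
    Path(dest).write_text("\n".join(L) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# JSON mirror
# --------------------------------------------------------------------------

def _doc_to_dict(doc: ExperimentDoc) -> dict:
    d = asdict(doc)
    d["modelMap"]["subset"]["parameterOverrides"] = [
        list(t) for t in doc.modelMap.subset.parameterOverrides]
    return d


def _doc_from_dict(d: dict) -> ExperimentDoc:
    doc = ExperimentDoc(
        exptType=d.get("exptType", "TimeSeries"),
        metadata=ExperimentMetadata(**d.get("metadata", {})),
        context=ExperimentContext(**d.get("context", {})),
        stimuli=[StimulusEntry(s["entityName"], s.get("field", "conc"),
                               s.get("unit", "mM"),
                               [tuple(p) for p in s.get("points", [])])
                 for s in d.get("stimuli", [])],
        combinations=[Combination(c["label"],
                                  [tuple(s) for s in c.get("settings", [])])
                      for c in d.get("combinations", [])],
        readouts=[ReadoutEntry(r["entityName"], r.get("field", "conc"),
                               r.get("unit", "mM"),
                               r.get("normalization", "absolute"),
                               [tuple(p) for p in r.get("points", [])],
                               r.get("settle"))
                  for r in d.get("readouts", [])],
    )
    mmd = d.get("modelMap", {})
    sub = mmd.get("subset", {})
    doc.modelMap = ModelMap(
        refModel=mmd.get("refModel", ""),
        subset=SubsetSpec(
            includePaths=list(sub.get("includePaths", [])),
            deletePaths=list(sub.get("deletePaths", [])),
            parameterOverrides=[tuple(t) for t in
                                sub.get("parameterOverrides", [])],
            entityMap={k: list(v) for k, v in
                       sub.get("entityMap", {}).items()}),
        solver=mmd.get("solver", "ode_stiff"),
        scoringFormula=mmd.get("scoringFormula", ""),
        weight=mmd.get("weight", 1.0),
        settleBeforeStart=mmd.get("settleBeforeStart", True),
    )
    return doc


def load_experiment(source: str | Path) -> ExperimentDoc:
    """Load an experiment file; dispatches on extension (.json vs tsv)."""
    if Path(source).suffix.lower() == ".json":
        doc = _doc_from_dict(json.loads(Path(source).read_text()))
        _check_doc_invariants(doc, source)
        return doc
    return parse_experiment_tsv(source)


def save_experiment(doc: ExperimentDoc, dest: str | Path) -> None:
    if Path(dest).suffix.lower() == ".json":
        Path(dest).write_text(json.dumps(_doc_to_dict(doc), indent=1))
    else:
        write_experiment_tsv(doc, dest)


# --------------------------------------------------------------------------
# Cross validation against a model
# --------------------------------------------------------------------------

def validate_experiment(doc: ExperimentDoc, model=None) -> list[str]:
    """Diagnostics for document-internal invariants and, when a model is
    given, for the experiment/model mapping (every named entity must map to
    pools that survive subset extraction)."""
    diags: list[str] = []
    if doc.exptType not in EXPT_TYPES:
        diags.append(f"exptType {doc.exptType!r} not in {EXPT_TYPES}")
    if doc.metadata.exptSource not in EXPT_SOURCES:
        diags.append(f"exptSource {doc.metadata.exptSource!r} not in "
                     f"{EXPT_SOURCES}")
    elif doc.metadata.exptSource == "paperReference" \
            and not doc.metadata.citationId:
        diags.append("exptSource is paperReference but citationId is empty")
    if doc.context.temperature is not None \
            and not 0 <= doc.context.temperature <= 60:
        diags.append(f"temperature {doc.context.temperature:g} outside "
                     "[0, 60] C")
    if doc.context.pH is not None and not 0 <= doc.context.pH <= 14:
        diags.append(f"pH {doc.context.pH:g} outside [0, 14]")

    for s in doc.stimuli:
        coords = [p[0] for p in s.points]
        if any(b <= a for a, b in zip(coords, coords[1:])):
            diags.append(f"stimulus {s.entityName!r}: coordinates not "
                         "strictly increasing")
        if s.field != "buffered" and kind_of(s.unit) == "conc" \
                and any(p[1] < 0 for p in s.points):
            diags.append(f"stimulus {s.entityName!r}: negative concentration")
    for r in doc.readouts:
        if any(p[2] is not None and p[2] < 0 for p in r.points):
            diags.append(f"readout {r.entityName!r}: negative stderr")
        coords = [p[0] for p in r.points]
        if doc.exptType != "MultiStimulus" \
                and any(b <= a for a, b in zip(coords, coords[1:])):
            diags.append(f"readout {r.entityName!r}: coordinates not "
                         "strictly increasing (duplicate dose/time?)")
    if doc.exptType == "DoseResponse":
        if len(doc.stimuli) != 1:
            diags.append("DoseResponse needs exactly one stimulus entity")
        else:
            doses = [p[0] for p in doc.stimuli[0].points]
            if len(set(doses)) != len(doses):
                diags.append("duplicate dose in dose list")
            for r in doc.readouts:
                if [p[0] for p in r.points] != doses:
                    diags.append(f"readout {r.entityName!r} coordinates do "
                                 "not equal the dose list")
    if doc.exptType == "MultiStimulus":
        labels = {c.label for c in doc.combinations}
        for r in doc.readouts:
            missing = [p[0] for p in r.points if p[0] not in labels]
            if missing:
                diags.append(f"readout {r.entityName!r}: labels {missing} "
                             "have no matching combination")
        if any(r.settle is None for r in doc.readouts):
            diags.append("MultiStimulus readouts need a settle time")

    if model is None:
        return diags
    if doc.modelMap.solver == "hh":
        if not isinstance(model, HHCompartment):
            diags.append("solver is hh but the model is not an HH membrane")
        for s in doc.stimuli:
            if s.field != "current":
                diags.append(f"stimulus {s.entityName!r}: HH experiments "
                             "take 'current' stimuli")
        for r in doc.readouts:
            if r.field != "Vm":
                diags.append(f"readout {r.entityName!r}: HH experiments "
                             "read out 'Vm'")
        return diags
    if not isinstance(model, ReactionModel):
        diags.append("chemical experiment paired with a non-chemical model")
        return diags
    spec = doc.modelMap.subset
    try:
        sub, _report = extract_subset(model, spec, policy="prune")
    except DanglingError as exc:    # prune never raises this; defensive
        diags.append(str(exc))
        return diags
    except Exception as exc:
        diags.append(f"subset extraction failed: {exc}")
        return diags
    names = [s.entityName for s in doc.stimuli] \
        + [r.entityName for r in doc.readouts] \
        + [name for c in doc.combinations for name, _ in c.settings]
    for name in names:
        targets = spec.entityMap.get(name)
        if not targets:
            diags.append(f"entity {name!r} has no model mapping")
            continue
        for t in targets:
            if t not in sub.pools:
                diags.append(f"entity {name!r} maps to {t!r}, absent from "
                             "the extracted model")
    return diags
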
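"""Format-dispatching model loader/saver.

``load_model`` understands the native text dialect and SBML Level 3; format
is inferred from the file extension (``.xml``/``.sbml`` -> SBML, anything
else native) unless given explicitly.
"""

from __future__ import annotations

from pathlib import Path

from .io_native import read_native, write_native
from .io_sbml import read_sbml, write_sbml
from .model import ModelError, ReactionModel, validate_model

__all__ = ["load_model", "save_model", "export_sbml"]


def _infer_format(path: str | Path) -> str:
    return "sbml" if Path(path).suffix.lower() in (".xml", ".sbml") else "native"


def load_model(source: str | Path, format: str | None = None):
    """Load a model file; returns a ReactionModel (or HHCompartment).

    Chemical models are validated on ingest; a model violating a structural
    invariant raises :class:`ModelError` listing the diagnostics.
    """
    fmt = format or _infer_format(source)
    if fmt == "native":
        model = read_native(source)
    elif fmt == "sbml":
        model = read_sbml(source)
    else:
        raise ModelError(f"unknown model format {fmt!r}")
    if isinstance(model, ReactionModel):
        diags = validate_model(model)
        if diags:
            raise ModelError(f"{source}: invalid model: " + "; ".join(diags))
    return model


def save_model(model, dest: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(dest)
    if fmt == "native":
        write_native(model, dest)
    elif fmt == "sbml":
        write_sbml(model, dest)
    else:
        raise ModelError(f"unknown model format {fmt!r}")


def export_sbml(model, dest: str | Path, stimuli=None) -> None:
    """Write SBML L3; timed concentration stimuli are emitted as events."""
    write_sbml(model, dest, stimuli=stimuli)
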
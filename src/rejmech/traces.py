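"""Force-extension trace data model and plain-text readers/writers.

A trace file is a two-column tab-separated table (``extension_nm``,
``force_pN``) whose metadata travels either as ``# key=value`` header lines
or in an adjacent ``<stem>.meta.json`` sidecar. Units are fixed by the
format: nanometres and piconewtons, no autodetection. A dataset is a
directory of trace files plus a ``manifest.json`` (and, for simulated data,
a ``truth.csv`` ground-truth event table).

Writers are byte-deterministic: identical traces produce identical files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULT_TEMPERATURE

logger = logging.getLogger(__name__)

__all__ = [
    "TraceMetadata",
    "ForceExtensionTrace",
    "TraceValidationError",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "MANIFEST_SCHEMA_VERSION",
]

MANIFEST_SCHEMA_VERSION = "1"

_META_DEFAULTS = {
    "pulling_speed": 0.6,  # nm/ms
    "temperature": DEFAULT_TEMPERATURE,
    "spring_constant": 50.0,  # pN/nm
}


class TraceValidationError(ValueError):
    """A trace violates a structural invariant."""


class TraceParseError(ValueError):
    """A trace file could not be parsed."""


@dataclass
class TraceMetadata:
    """Acquisition metadata for one pulling recording.

    pulling_speed is in nm/ms, spring_constant in pN/nm, temperature in K.
    ``sample_interval`` is the nominal tip-position grid step in nm.
    """

    trace_id: str
    pulling_speed: float = _META_DEFAULTS["pulling_speed"]
    temperature: float = _META_DEFAULTS["temperature"]
    spring_constant: float = _META_DEFAULTS["spring_constant"]
    sample_interval: float | None = None
    construct_name: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pulling_speed <= 0:
            raise TraceValidationError(
                f"pulling_speed must be positive, got {self.pulling_speed}"
            )
        if self.spring_constant <= 0:
            raise TraceValidationError(
                f"spring_constant must be positive, got {self.spring_constant}"
            )


@dataclass
class ForceExtensionTrace:
    """One AFM pulling recording: extension (nm) and force (pN) samples.

    Extension is non-decreasing and starts at 0 at the tip-surface contact
    point (the zero-length convention of the analysis).
    """

    extension: np.ndarray
    force: np.ndarray
    metadata: TraceMetadata

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape or self.extension.ndim != 1:
            raise TraceValidationError("extension and force must be equal-length 1-D arrays")
        if self.extension.size < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        diffs = np.diff(self.extension)
        bad = np.nonzero(diffs < 0)[0]
        if bad.size:
            raise TraceValidationError(
                f"extension decreases at row {int(bad[0]) + 1} "
                f"({self.extension[bad[0]]:g} -> {self.extension[bad[0] + 1]:g} nm)"
            )
        if abs(self.extension[0]) > 1e-9:
            raise TraceValidationError(
                f"extension must start at 0 (contact point), got {self.extension[0]:g} nm"
            )

    def __len__(self) -> int:
        return int(self.extension.size)


def _meta_to_dict(meta: TraceMetadata) -> dict:
    d = asdict(meta)
    return {k: v for k, v in d.items() if v is not None}


def _meta_from_dict(d: dict, trace_id: str) -> TraceMetadata:
    known = {f for f in TraceMetadata.__dataclass_fields__}
    clean = {k: v for k, v in d.items() if k in known}
    unknown = set(d) - known
    if unknown:
        logger.warning("ignoring unknown metadata keys %s", sorted(unknown))
    missing = {"pulling_speed", "temperature", "spring_constant"} - set(clean)
    if missing:
        logger.warning(
            "trace %s: metadata keys %s missing, using config defaults",
            trace_id, sorted(missing),
        )
    clean.setdefault("trace_id", trace_id)
    return TraceMetadata(**clean)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trace(trace: ForceExtensionTrace, path: str | Path) -> Path:
    """Write a trace as TSV plus a JSON metadata sidecar.

    Float columns use the shortest round-trippable representation (%.17g),
    so a read-back reproduces the arrays bit-exactly; key order in the
    sidecar is fixed, so two writes of the same trace are byte-identical.
    """
    path = Path(path)
    try:
        lines = ["extension_nm\tforce_pN"]
        for x, f in zip(trace.extension, trace.force):
            lines.append(f"{x:.17g}\t{f:.17g}")
        path.write_text("\n".join(lines) + "\n")
        meta = _meta_to_dict(trace.metadata)
        _sidecar_path(path).write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
    except OSError as exc:
        raise OSError(f"failed writing trace to {path}: {exc}") from exc
    return path


def read_trace(path: str | Path) -> ForceExtensionTrace:
    """Read a TSV trace file (with '#' header metadata or a JSON sidecar)."""
    path = Path(path)
    meta_dict: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta_dict.update(json.loads(sidecar.read_text()))
    xs: list[float] = []
    fs: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                try:
                    meta_dict.setdefault(key, json.loads(val))
                except json.JSONDecodeError:
                    meta_dict.setdefault(key, val)
            continue
        if line.lower().startswith("extension_nm"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TraceParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            xs.append(float(parts[0]))
            fs.append(float(parts[1]))
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: unparsable number ({exc})") from exc
    meta = _meta_from_dict(meta_dict, trace_id=path.stem)
    return ForceExtensionTrace(np.array(xs), np.array(fs), meta)


def write_manifest(directory: str | Path, manifest: dict) -> Path:
    directory = Path(directory)
    payload = {"schema_version": MANIFEST_SCHEMA_VERSION, **manifest}
    out = directory / "manifest.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out


def read_manifest(directory: str | Path) -> dict:
    path = Path(directory) / "manifest.json"
    manifest = json.loads(path.read_text())
    version = manifest.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        warnings.warn(
            f"manifest schema version {version!r} != supported {MANIFEST_SCHEMA_VERSION!r}"
        )
    return manifest
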
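"""Versioned static JSON match layout: writer, reader and validator.

Match metadata is served as a REST-like tree of plain JSON documents under
a root ("bucket") directory:

.. code-block:: text

    <root>/current.txt                       # name of the current version
    <root>/<VER>/config.json                 # DataConfig document
    <root>/<VER>/schemas/*.json              # versioned JSON schemas
    <root>/<VER>/metadata/by_body/<id>.json  # EM neuron image lookup
    <root>/<VER>/metadata/by_line/<id>.json  # driver-line image lookup
    <root>/<VER>/metadata/cdsresults/<image_id>.json  # pixel-search matches

Image metadata is denormalized into every match document so a client fetches
one file per query.  Long common values (alignment space and library names)
are stored as short ``$key`` constants resolved through the config's
constants table.  Every image carries a content-derived GUID that is stable
across runs and data versions.  Older versions are never modified: writing
version N+1 leaves every byte under N untouched.

Result documents for other match algorithms (e.g. patch-based matchers) are
representable by pointing ``kind`` at a sibling directory; only pixel-search
results are computed here.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Any

if TYPE_CHECKING:  # pragma: no cover
    from .precompute import LibraryEntry, MatchTable

__all__ = [
    "NeuronImageMeta",
    "DataConfig",
    "BucketError",
    "NotFoundError",
    "ValidationError",
    "make_guid",
    "compress_constants",
    "expand_constants",
    "load_schema",
    "validate_doc",
    "write_bucket_layout",
    "lookup",
    "current_version",
]

SCHEMA_NAMES = ("ImageLookup", "PrecomputedMatches", "DataConfig")


class BucketError(ValueError):
    """The requested bucket write would violate layout invariants."""


class NotFoundError(KeyError):
    """A bucket lookup did not resolve."""


class ValidationError(ValueError):
    """A document failed schema validation."""


def make_guid(*parts: str) -> str:
    """Deterministic content-derived GUID: stable across runs and versions."""
    h = hashlib.sha1("\x1f".join(parts).encode("utf-8")).hexdigest()
    return str(int(h[:16], 16))


@dataclass
class NeuronImageMeta:
    """Denormalizable metadata for one CDM image."""

    id: str
    modality: str  # "EM" | "LM"
    alignment_space: str
    library_name: str
    published_name: str  # body id (EM) or driver line (LM)
    files: dict[str, str] = field(default_factory=dict)
    variant: str = "original"
    sample_id: str = ""
    attributes: dict[str, Any] = field(default_factory=dict)

    def to_doc(self) -> dict:
        return {
            "id": self.id,
            "modality": self.modality,
            "alignmentSpace": self.alignment_space,
            "libraryName": self.library_name,
            "publishedName": self.published_name,
            "variant": self.variant,
            "sampleId": self.sample_id,
            "files": dict(self.files),
            "attributes": dict(self.attributes),
        }

    @classmethod
    def from_entry(
        cls, entry: "LibraryEntry", library_name: str,
        files: dict[str, str] | None = None,
    ) -> "NeuronImageMeta":
        return cls(
            id=entry.image_id,
            modality=entry.modality,
            alignment_space=entry.cdm.space.name,
            library_name=library_name,
            published_name=entry.neuron_or_line_id,
            files=files or {},
            variant=entry.cdm.variant,
            sample_id=entry.sample_id,
        )


@dataclass
class DataConfig:
    """Bucket-level configuration: areas, constants table, path prefixes."""

    anatomical_areas: list[str] = field(default_factory=lambda: ["Brain"])
    constants: dict[str, str] = field(default_factory=dict)
    prefixes: dict[str, str] = field(default_factory=dict)
    schema_version: str = "1.0"

    def to_doc(self) -> dict:
        return {
            "anatomicalAreas": list(self.anatomical_areas),
            "constants": dict(self.constants),
            "prefixes": dict(self.prefixes),
            "schemaVersion": self.schema_version,
        }


# ---------------------------------------------------------------------------
# Constant interpolation
# ---------------------------------------------------------------------------

def _map_strings(doc, fn):
    if isinstance(doc, str):
        return fn(doc)
    if isinstance(doc, list):
        return [_map_strings(v, fn) for v in doc]
    if isinstance(doc, dict):
        return {k: _map_strings(v, fn) for k, v in doc.items()}
    return doc


def compress_constants(doc, config: DataConfig):
    """Replace string values equal to a constant's long value by ``$key``."""
    inverse = {v: f"${k}" for k, v in config.constants.items()}
    return _map_strings(doc, lambda s: inverse.get(s, s))


def expand_constants(doc, config: DataConfig):
    """Replace every ``$key`` string by its long value from the constants
    table.  Strings that are not known keys pass through unchanged, so
    expansion is the exact inverse of compression for documents that do not
    themselves contain ``$key`` literals."""
    consts = config.constants

    def fn(s: str) -> str:
        if s.startswith("$") and s[1:] in consts:
            return consts[s[1:]]
        return s

    return _map_strings(doc, fn)


# ---------------------------------------------------------------------------
# Schema validation (self-contained JSON-Schema subset)
# ---------------------------------------------------------------------------

def load_schema(schema_name: str, version_dir: str | os.PathLike | None = None) -> dict:
    """Load a shipped schema by name, or a versioned copy from a bucket."""
    if version_dir is not None:
        path = Path(version_dir) / "schemas" / f"{schema_name}.json"
        with open(path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    ref = resources.files("cdmip") / "schemas" / f"{schema_name}.json"
    return json.loads(ref.read_text(encoding="utf-8"))


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def _validate(doc, schema: dict, path: str, errors: list[str]) -> None:
    typ = schema.get("type")
    if typ is not None:
        py = _TYPES[typ]
        ok = isinstance(doc, py)
        if typ in ("integer", "number") and isinstance(doc, bool):
            ok = False
        if not ok:
            errors.append(f"{path or '$'}: expected {typ}, got {type(doc).__name__}")
            return
    if "enum" in schema and doc not in schema["enum"]:
        errors.append(f"{path or '$'}: {doc!r} not in enum {schema['enum']}")
    if isinstance(doc, dict):
        for req in schema.get("required", ()):
            if req not in doc:
                errors.append(f"{path or '$'}: missing required property '{req}'")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in doc:
                _validate(doc[key], sub, f"{path}.{key}", errors)
        if schema.get("additionalProperties") is False:
            for key in doc:
                if key not in props:
                    errors.append(f"{path or '$'}: unexpected property '{key}'")
    if isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            _validate(item, schema["items"], f"{path}[{i}]", errors)


def validate_doc(
    doc, schema_name: str, version_dir: str | os.PathLike | None = None,
) -> list[str]:
    """Validate a document against a named schema.

    Returns the (possibly empty) list of human-readable errors; an empty
    list means the document is valid.
    """
    schema = load_schema(schema_name, version_dir)
    errors: list[str] = []
    _validate(doc, schema, "", errors)
    return errors


# ---------------------------------------------------------------------------
# Bucket writer / reader
# ---------------------------------------------------------------------------

def _dump(doc, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _match_to_doc(rec, images: dict[str, NeuronImageMeta]) -> dict:
    doc = {
        "image": images[rec.target_id].to_doc(),
        "mirrored": bool(rec.used_flip),
        "matchedPixels": int(rec.matched_pixels),
        "matchingShift": [int(rec.best_shift[0]), int(rec.best_shift[1])],
        "normalizedScore": float(rec.normalized_score),
    }
    if rec.shape_score is not None:
        doc["shapePositive"] = int(rec.shape_positive)
        doc["shapeNegative"] = int(rec.shape_negative)
        doc["shapeScore"] = float(rec.shape_score)
    return doc


def write_bucket_layout(
    tables: "list[MatchTable]",
    images: list[NeuronImageMeta],
    config: DataConfig,
    root: str | os.PathLike,
    version: str,
) -> Path:
    """Write a complete versioned bucket tree.

    Every image referenced by any match record must appear in ``images``
    (dangling references are an error), ids must be collision-free, and the
    version directory must not already exist — existing versions are
    immutable.  Documents are written with sorted keys so the tree is
    byte-deterministic.  Returns the version directory path.
    """
    root = Path(root)
    vdir = root / version
    if vdir.exists():
        raise BucketError(f"version '{version}' already exists and is immutable")

    by_id: dict[str, NeuronImageMeta] = {}
    for im in images:
        if im.id in by_id:
            raise BucketError(f"GUID collision on image id {im.id}")
        by_id[im.id] = im
    for table in tables:
        for qid, recs in table.matches.items():
            for ref in [qid] + [r.target_id for r in recs]:
                if ref not in by_id:
                    raise BucketError(f"dangling image reference {ref}")

    # schemas (versioned copies of the shipped ones)
    for name in SCHEMA_NAMES:
        _dump(load_schema(name), vdir / "schemas" / f"{name}.json")

    cfg_doc = config.to_doc()
    errs = validate_doc(cfg_doc, "DataConfig")
    if errs:
        raise ValidationError("; ".join(errs))
    _dump(cfg_doc, vdir / "config.json")

    meta = vdir / "metadata"
    # image lookups, grouped by published name per modality
    lookups: dict[tuple[str, str], list[NeuronImageMeta]] = {}
    for im in images:
        kind = "by_body" if im.modality == "EM" else "by_line"
        lookups.setdefault((kind, im.published_name), []).append(im)
    for (kind, name), ims in sorted(lookups.items()):
        doc = {"results": [im.to_doc() for im in ims]}
        errs = validate_doc(doc, "ImageLookup")
        if errs:
            raise ValidationError("; ".join(errs))
        _dump(compress_constants(doc, config), meta / kind / f"{name}.json")

    # match result documents, one per query image
    for table in tables:
        for qid, recs in sorted(table.matches.items()):
            doc = {
                "inputImage": by_id[qid].to_doc(),
                "algorithm": "cdmip-pixel-search",
                "results": [_match_to_doc(r, by_id) for r in recs],
            }
            errs = validate_doc(doc, "PrecomputedMatches")
            if errs:
                raise ValidationError("; ".join(errs))
            _dump(compress_constants(doc, config), meta / "cdsresults" / f"{qid}.json")

    with open(root / "current.txt", "w", encoding="utf-8") as fh:
        fh.write(version + "\n")
    return vdir


def current_version(root: str | os.PathLike) -> str:
    try:
        with open(Path(root) / "current.txt", "r", encoding="utf-8") as fh:
            return fh.read().strip()
    except FileNotFoundError as exc:
        raise NotFoundError(f"no current.txt under {root}") from exc


def lookup(
    root: str | os.PathLike,
    kind: str,
    id: str,
    version: str | None = None,
    expand: bool = True,
) -> dict:
    """Resolve a document by kind and id.

    ``kind`` is one of ``by_body``, ``by_line`` or ``cdsresults``.  The
    current version (from ``current.txt``) is used unless an explicit
    ``version`` requests older, preserved data.  Constants are expanded
    through the version's config unless ``expand=False``.
    """
    if kind not in ("by_body", "by_line", "cdsresults"):
        raise ValueError(f"unknown lookup kind '{kind}'")
    root = Path(root)
    ver = version or current_version(root)
    path = root / ver / "metadata" / kind / f"{id}.json"
    if not path.exists():
        raise NotFoundError(f"{kind}/{id} not found in version {ver}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if expand:
        with open(root / ver / "config.json", "r", encoding="utf-8") as fh:
            cfg = json.load(fh)
        doc = expand_constants(doc, DataConfig(constants=cfg["constants"]))
    return doc
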
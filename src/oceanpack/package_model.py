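"""Data model and I/O for ontology-enriched tabular data packages.

A *data package* is a directory holding a ``datapackage.json`` descriptor
plus one or more TSV resource files.  The descriptor follows the
Frictionless Data Package dialect with extension properties under the
``pm:`` prefix that attach a triad of OBO ontology terms to each column:

* ``rdfType`` — what the column is about (e.g. an ENVO concentration term),
* ``pm:unitRdfType`` — the unit of measure (a UO term),
* ``pm:measurementSourceRdfType`` — the measuring device (an OBI term).

This module parses and serializes descriptors, loads resources into typed
tables, converts between CURIEs and OBO PURLs, and enumerates the
annotation triads so the validator and the harmonizer can audit and query
them.
"""

from __future__ import annotations

import csv
import io
import json
import re
import warnings
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from pathlib import Path

from .errors import (
    CurieFormatError,
    DescriptorParseError,
    HeaderMismatchError,
    MissingResourceError,
    SchemaError,
    UnsupportedNamespaceError,
)

OBO_PURL_BASE = "http://purl.obolibrary.org/obo/"

#: Closed set of declared column types.
DECLARED_TYPES = frozenset({"string", "number", "integer", "datetime"})

#: Accepted spellings of the device-annotation key.  The figure in the
#: original portal's documentation printed a misspelled variant, so both
#: are read; only the canonical key is ever written.
DEVICE_KEYS = ("pm:measurementSourceRdfType", "pm:measurmentSourceRdfType")

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*:[A-Za-z0-9_.\-]+$")


def curie_to_purl(curie: str) -> str:
    """Convert a compact identifier like ``ENVO:01000253`` to its OBO PURL.

    The OBO rule replaces the first ``:`` with ``_`` and prepends the
    shared PURL base.
    """
    if not isinstance(curie, str) or not _CURIE_RE.match(curie):
        raise CurieFormatError(f"malformed CURIE: {curie!r}")
    return OBO_PURL_BASE + curie.replace(":", "_", 1)


def purl_to_curie(purl: str) -> str:
    """Inverse of :func:`curie_to_purl`; only OBO-base IRIs are supported."""
    if not isinstance(purl, str) or not purl.startswith(OBO_PURL_BASE):
        raise UnsupportedNamespaceError(
            f"IRI is not under the OBO PURL base {OBO_PURL_BASE!r}: {purl!r}"
        )
    local = purl[len(OBO_PURL_BASE):]
    if "_" not in local:
        raise CurieFormatError(f"OBO PURL without PREFIX_LOCALID tail: {purl!r}")
    curie = local.replace("_", ":", 1)
    if not _CURIE_RE.match(curie):
        raise CurieFormatError(f"OBO PURL yields malformed CURIE: {purl!r}")
    return curie


@dataclass(frozen=True)
class OntologyTermRef:
    """Reference to an ontology term by CURIE, with an optional label."""

    curie: str
    label: str = ""

    def __post_init__(self):
        if not self.curie:
            raise CurieFormatError("OntologyTermRef requires a non-empty CURIE")
        if not _CURIE_RE.match(self.curie):
            raise CurieFormatError(f"malformed CURIE: {self.curie!r}")

    @property
    def purl(self) -> str:
        return curie_to_purl(self.curie)

    @property
    def prefix(self) -> str:
        return self.curie.split(":", 1)[0]

    @classmethod
    def from_purl(cls, purl: str, label: str = "") -> "OntologyTermRef":
        return cls(purl_to_curie(purl), label)

    @classmethod
    def parse(cls, text: str, label: str = "") -> "OntologyTermRef":
        """Accept either a CURIE or an OBO PURL."""
        if text.startswith("http://") or text.startswith("https://"):
            return cls.from_purl(text, label)
        return cls(text, label)


@dataclass
class FieldSpec:
    """Declared schema for one column, including its annotation triad."""

    name: str
    declared_type: str = "string"
    format: str | None = None
    missing_values: list[str] = dc_field(default_factory=list)
    constraints: dict | None = None
    rdf_type: OntologyTermRef | None = None
    unit_rdf_type: OntologyTermRef | None = None
    measurement_source_rdf_type: OntologyTermRef | None = None
    searchable: bool = False
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.declared_type not in DECLARED_TYPES:
            raise SchemaError(
                f"field {self.name!r}: unknown declared type {self.declared_type!r} "
                f"(expected one of {sorted(DECLARED_TYPES)})"
            )
        if self.constraints:
            if self.declared_type not in ("number", "integer"):
                raise SchemaError(
                    f"field {self.name!r}: numeric constraints on non-numeric type "
                    f"{self.declared_type!r}"
                )
            lo = self.constraints.get("minimum")
            hi = self.constraints.get("maximum")
            if lo is not None and hi is not None and lo > hi:
                raise SchemaError(
                    f"field {self.name!r}: constraint minimum {lo} > maximum {hi}"
                )


@dataclass
class ResourceSpec:
    """One tabular resource file declared in a descriptor."""

    name: str
    path: str
    md5: str | None = None
    delimiter: str = "\t"
    fields: list[FieldSpec] = dc_field(default_factory=list)
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        p = Path(self.path)
        if p.is_absolute() or ".." in p.parts:
            raise SchemaError(
                f"resource {self.name!r}: path must be relative with no parent "
                f"escapes, got {self.path!r}"
            )
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"resource {self.name!r}: duplicate field names {dupes}")

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class PackageDescriptor:
    """Parsed ``datapackage.json`` with resources and their field schemas."""

    name: str
    title: str = ""
    resources: list[ResourceSpec] = dc_field(default_factory=list)
    licenses: list[dict] = dc_field(default_factory=list)
    sources: list[dict] = dc_field(default_factory=list)
    homepage: str | None = None
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not self.resources:
            raise SchemaError(f"package {self.name!r}: at least one resource required")
        names = [r.name for r in self.resources]
        if len(names) != len(set(names)):
            raise SchemaError(f"package {self.name!r}: duplicate resource names")

    def resource(self, name: str) -> ResourceSpec:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class TypedCellError:
    """In-table marker for a cell whose raw text failed to parse.

    Loading never silently coerces or drops bad cells: the marker keeps
    the raw string so the validator can report exact coordinates.
    ``kind`` is ``"type"`` for type failures and ``"format"`` for datetime
    cells that do not match their declared pattern.
    """

    raw: str
    expected_type: str
    kind: str = "type"


@dataclass
class ParsedTable:
    """A loaded resource: typed cells, null mask, and source line numbers."""

    resource_name: str
    columns: list[str]
    rows: list[tuple]
    row_provenance: list[int]

    @property
    def null_mask(self) -> list[tuple]:
        return [tuple(c is None for c in row) for row in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        i = self.columns.index(name)
        return [row[i] for row in self.rows]


# ---------------------------------------------------------------------------
# descriptor JSON <-> model


def _term_from_json(value, key: str) -> OntologyTermRef:
    if not isinstance(value, str) or not value:
        raise SchemaError(f"annotation {key!r} must be a non-empty string")
    try:
        return OntologyTermRef.parse(value)
    except (CurieFormatError, UnsupportedNamespaceError) as exc:
        raise SchemaError(f"annotation {key!r}: {exc}") from exc


_FIELD_KNOWN_KEYS = {
    "name", "type", "format", "missingValues", "constraints",
    "rdfType", "pm:rdfType", "pm:unitRdfType", "pm:searchable",
    *DEVICE_KEYS,
}


def _field_from_json(obj: dict, schema_missing: list[str]) -> FieldSpec:
    if "name" not in obj:
        raise SchemaError("field without required key 'name'")
    rdf = obj.get("rdfType", obj.get("pm:rdfType"))
    unit = obj.get("pm:unitRdfType")
    device = None
    for k in DEVICE_KEYS:
        if k in obj:
            device = obj[k]
            break
    constraints = obj.get("constraints")
    if constraints is not None and not isinstance(constraints, dict):
        raise SchemaError(f"field {obj['name']!r}: constraints must be an object")
    return FieldSpec(
        name=obj["name"],
        declared_type=obj.get("type", "string"),
        format=obj.get("format"),
        missing_values=list(obj.get("missingValues", schema_missing)),
        constraints=dict(constraints) if constraints else None,
        rdf_type=_term_from_json(rdf, "rdfType") if rdf is not None else None,
        unit_rdf_type=_term_from_json(unit, "pm:unitRdfType") if unit is not None else None,
        measurement_source_rdf_type=(
            _term_from_json(device, "pm:measurementSourceRdfType")
            if device is not None else None
        ),
        searchable=bool(obj.get("pm:searchable", False)),
        extra={k: v for k, v in obj.items() if k not in _FIELD_KNOWN_KEYS},
    )


_RESOURCE_KNOWN_KEYS = {"name", "path", "md5", "hash", "dialect", "schema"}


def _resource_from_json(obj: dict) -> ResourceSpec:
    for key in ("name", "path"):
        if key not in obj:
            raise SchemaError(f"resource without required key {key!r}")
    md5 = obj.get("md5")
    if md5 is None and isinstance(obj.get("hash"), str):
        h = obj["hash"]
        md5 = h[4:] if h.startswith("md5:") else h
    if md5 is not None:
        if not re.fullmatch(r"[0-9a-fA-F]{32}", md5):
            raise SchemaError(
                f"resource {obj['name']!r}: md5 must be 32 hex digits, got {md5!r}"
            )
        md5 = md5.lower()
    schema = obj.get("schema", {})
    schema_missing = list(schema.get("missingValues", []))
    fields = [_field_from_json(f, schema_missing) for f in schema.get("fields", [])]
    delimiter = obj.get("dialect", {}).get("delimiter", "\t")
    return ResourceSpec(
        name=obj["name"],
        path=obj["path"],
        md5=md5,
        delimiter=delimiter,
        fields=fields,
        extra={k: v for k, v in obj.items() if k not in _RESOURCE_KNOWN_KEYS},
    )


_PACKAGE_KNOWN_KEYS = {"name", "title", "resources", "licenses", "sources", "homepage"}


def load_descriptor(json_text: str) -> PackageDescriptor:
    """Parse descriptor JSON text into a :class:`PackageDescriptor`.

    Unknown keys at every level are preserved in ``extra`` for lossless
    round-tripping.  A UTF-8 BOM, if present, is stripped.
    """
    if json_text.startswith("\ufeff"):
        json_text = json_text[1:]
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise DescriptorParseError(
            f"malformed descriptor JSON at offset {exc.pos}: {exc.msg}", offset=exc.pos
        ) from exc
    if not isinstance(obj, dict):
        raise SchemaError("descriptor root must be a JSON object")
    for key in ("name", "resources"):
        if key not in obj:
            raise SchemaError(f"descriptor missing required key {key!r}")
    resources = [_resource_from_json(r) for r in obj["resources"]]
    return PackageDescriptor(
        name=obj["name"],
        title=obj.get("title", ""),
        resources=resources,
        licenses=list(obj.get("licenses", [])),
        sources=list(obj.get("sources", [])),
        homepage=obj.get("homepage"),
        extra={k: v for k, v in obj.items() if k not in _PACKAGE_KNOWN_KEYS},
    )


def _field_to_json(f: FieldSpec) -> dict:
    out: dict = {"name": f.name, "type": f.declared_type}
    if f.format is not None:
        out["format"] = f.format
    if f.missing_values:
        out["missingValues"] = list(f.missing_values)
    if f.constraints:
        out["constraints"] = dict(sorted(f.constraints.items()))
    if f.rdf_type is not None:
        out["rdfType"] = f.rdf_type.purl
    if f.unit_rdf_type is not None:
        out["pm:unitRdfType"] = f.unit_rdf_type.purl
    if f.measurement_source_rdf_type is not None:
        # always the canonical spelling, regardless of what was read
        out["pm:measurementSourceRdfType"] = f.measurement_source_rdf_type.purl
    if f.searchable:
        out["pm:searchable"] = True
    for k in sorted(f.extra):
        out[k] = f.extra[k]
    return out


def _resource_to_json(r: ResourceSpec) -> dict:
    out: dict = {"name": r.name, "path": r.path}
    if r.md5 is not None:
        out["md5"] = r.md5
    if r.delimiter != "\t":
        out["dialect"] = {"delimiter": r.delimiter}
    out["schema"] = {"fields": [_field_to_json(f) for f in r.fields]}
    for k in sorted(r.extra):
        out[k] = r.extra[k]
    return out


def save_descriptor(pkg: PackageDescriptor) -> str:
    """Serialize to canonical JSON: stable key order and indentation.

    Structurally equal descriptors serialize to byte-identical text, and
    ``load_descriptor(save_descriptor(p)) == p`` up to the canonical
    device-key spelling.
    """
    out: dict = {"name": pkg.name}
    if pkg.title:
        out["title"] = pkg.title
    if pkg.homepage is not None:
        out["homepage"] = pkg.homepage
    if pkg.licenses:
        out["licenses"] = pkg.licenses
    if pkg.sources:
        out["sources"] = pkg.sources
    for k in sorted(pkg.extra):
        out[k] = pkg.extra[k]
    out["resources"] = [_resource_to_json(r) for r in pkg.resources]
    return json.dumps(out, indent=2, ensure_ascii=False) + "\n"


def load_package_dir(base_dir) -> PackageDescriptor:
    """Read ``<base_dir>/datapackage.json``."""
    path = Path(base_dir) / "datapackage.json"
    if not path.is_file():
        raise MissingResourceError(f"no datapackage.json in {base_dir}")
    return load_descriptor(path.read_text(encoding="utf-8-sig"))


# ---------------------------------------------------------------------------
# resource loading

def _parse_cell(raw: str, spec: FieldSpec):
    if raw in spec.missing_values:
        return None
    t = spec.declared_type
    if t == "string":
        return raw
    if t == "number":
        try:
            return float(raw)
        except ValueError:
            return TypedCellError(raw, t)
    if t == "integer":
        try:
            return int(raw)
        except ValueError:
            return TypedCellError(raw, t)
    # datetime: a non-conforming value is a format failure, not a type one
    fmt = spec.format or "%Y-%m-%dT%H:%M:%SZ"
    try:
        return datetime.strptime(raw, fmt)
    except ValueError:
        return TypedCellError(raw, t, kind="format")


def load_resource(pkg: PackageDescriptor, resource_name: str, base_dir) -> ParsedTable:
    """Load one TSV resource into a :class:`ParsedTable`.

    Cells whose raw string is exactly in the field's missing-value list
    become null; everything else is parsed to the declared type.  Parse
    failures become :class:`TypedCellError` cells so the validator can
    report their coordinates — loading itself never raises for bad cells.
    """
    res = pkg.resource(resource_name)
    path = Path(base_dir) / res.path
    try:
        text = path.read_text(encoding="utf-8-sig")
    except OSError as exc:
        raise MissingResourceError(f"cannot read resource file {path}: {exc}") from exc

    reader = csv.reader(io.StringIO(text), delimiter=res.delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise HeaderMismatchError(
            f"resource {resource_name!r}: file is empty, expected a header row",
            expected=[f.name for f in res.fields], found=[],
        )
    declared = [f.name for f in res.fields]
    if header != declared:
        raise HeaderMismatchError(
            f"resource {resource_name!r}: header mismatch; "
            f"missing {sorted(set(declared) - set(header))}, "
            f"unexpected {sorted(set(header) - set(declared))}",
            expected=declared, found=header,
        )

    rows, prov = [], []
    for lineno, raw_row in enumerate(reader, start=2):
        if len(raw_row) != len(declared):
            # ragged row: pad/truncate markers so coordinates stay valid
            raw_row = (raw_row + [""] * len(declared))[: len(declared)]
        rows.append(tuple(_parse_cell(c, f) for c, f in zip(raw_row, res.fields)))
        prov.append(lineno)
    return ParsedTable(resource_name, declared, rows, prov)


# ---------------------------------------------------------------------------
# annotation enumeration

@dataclass(frozen=True)
class AnnotationTriad:
    """One field's annotation triad; absent members are ``None``."""

    resource: str
    field: str
    rdf_type: OntologyTermRef | None
    unit: OntologyTermRef | None
    device: OntologyTermRef | None

    @property
    def complete(self) -> bool:
        return None not in (self.rdf_type, self.unit, self.device)


def list_annotation_triads(pkg: PackageDescriptor) -> list[AnnotationTriad]:
    """One entry per declared field, in descriptor order."""
    out = []
    for res in pkg.resources:
        for f in res.fields:
            out.append(AnnotationTriad(
                res.name, f.name, f.rdf_type, f.unit_rdf_type,
                f.measurement_source_rdf_type,
            ))
    return out


class NoAccessionColumnWarning(UserWarning):
    """Emitted when a package declares no sequence-accession column."""


#: Column-name pattern used to spot INSDC accession columns when no field
#: is annotated as one.
ACCESSION_NAME_RE = re.compile(r"(accession|run_id|sra_id)", re.IGNORECASE)


def list_sequence_links(
    pkg: PackageDescriptor,
    table: ParsedTable,
    deduplicate: bool = False,
) -> list[str]:
    """Non-null accession values from the accession column, in row order.

    The accession column is found by name pattern (``accession`` and
    friends).  If none exists, an empty list is returned and a
    :class:`NoAccessionColumnWarning` is emitted.
    """
    res = pkg.resource(table.resource_name)
    acc_field = None
    for f in res.fields:
        if f.name in table.columns and ACCESSION_NAME_RE.search(f.name):
            acc_field = f.name
            break
    if acc_field is None:
        warnings.warn(
            f"package {pkg.name!r}: no accession column in resource "
            f"{table.resource_name!r}", NoAccessionColumnWarning,
        )
        return []
    values = [v for v in table.column(acc_field)
              if v is not None and not isinstance(v, TypedCellError)]
    if deduplicate:
        seen, out = set(), []
        for v in values:
            if v not in seen:
                seen.add(v)
                out.append(v)
        return out
    return values
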
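"""Cross-package semantic discovery and harmonization.

Once columns are annotated with ontology terms, datasets from different
projects can be queried and merged *by meaning* rather than by column
name: a search for "concentration of nitrate in liquid water" finds every
nitrate column regardless of what its project called it, unit annotations
drive automatic conversion into one target unit per attribute, and each
harmonized cell keeps full provenance (source package, field, original
unit, measuring device).

Unit conversion is deliberately conservative.  Molar concentrations
(micromolar) and mass-based ones (micromole per kilogram) live in
disjoint dimension groups and are only convertible through an explicit
seawater-density bridge the caller must opt into — silently equating
them would over-harmonize.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from importlib import resources as importlib_resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import (
    ColumnError,
    DuplicateSampleError,
    IncompatibleUnitsError,
    UnknownTermError,
)
from .ontology import TermGraph
from .package_model import (
    OntologyTermRef,
    PackageDescriptor,
    ParsedTable,
    TypedCellError,
    load_package_dir,
    load_resource,
    purl_to_curie,
)

#: ENVO context roots: broad-scale biome, local feature, material.
BIOME_ROOT = "ENVO:00000428"
FEATURE_ROOT = "ENVO:00002297"
MATERIAL_ROOT = "ENVO:00010483"

#: Default seawater density (kg/L) for the optional molar <-> per-kg bridge.
SEAWATER_DENSITY_KG_PER_L = 1.025

MICROMOLAR = "UO:0000064"
MICROMOLE_PER_KG = "UO:0010004"


# ---------------------------------------------------------------------------
# units

class UnitRegistry:
    """Affine unit conversions over a graph of registered unit pairs.

    Each registered edge ``a -> b`` is a map ``x * factor + offset``;
    the inverse edge is derived automatically, and chains compose, so
    any two units in the same connected dimension group are convertible.
    """

    def __init__(self):
        self._g = nx.DiGraph()

    def add_unit(self, curie: str):
        self._g.add_node(curie)

    def add(self, from_unit: str, to_unit: str, factor: float, offset: float = 0.0):
        if factor == 0:
            raise ValueError("conversion factor must be non-zero")
        self._g.add_edge(from_unit, to_unit, factor=float(factor), offset=float(offset))
        self._g.add_edge(to_unit, from_unit,
                         factor=1.0 / factor, offset=-offset / factor)

    def __contains__(self, curie: str) -> bool:
        return curie in self._g

    def dimension_group(self, curie: str) -> frozenset:
        if curie not in self._g:
            raise IncompatibleUnitsError(f"unit {curie!r} not registered")
        return frozenset(nx.node_connected_component(self._g.to_undirected(), curie))

    def convertible(self, a: str, b: str) -> bool:
        return a == b or (a in self._g and b in self._g
                          and b in self.dimension_group(a))

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        if from_unit == to_unit:
            return value
        for u in (from_unit, to_unit):
            if u not in self._g:
                raise IncompatibleUnitsError(f"unit {u!r} not registered")
        try:
            path = nx.shortest_path(self._g, from_unit, to_unit)
        except nx.NetworkXNoPath:
            raise IncompatibleUnitsError(
                f"units {from_unit!r} and {to_unit!r} are in disjoint dimension "
                f"groups; no conversion without an explicit bridge"
            )
        out = value
        for a, b in zip(path, path[1:]):
            e = self._g.edges[a, b]
            out = out * e["factor"] + e["offset"]
        return out

    def add_density_bridge(self, density_kg_per_l: float = SEAWATER_DENSITY_KG_PER_L):
        """Bridge micromolar to micromole-per-kilogram assuming a fixed
        water density: value[µmol/kg] = value[µmol/L] / density."""
        self.add(MICROMOLAR, MICROMOLE_PER_KG, 1.0 / density_kg_per_l)

    @classmethod
    def from_tsv(cls, path) -> "UnitRegistry":
        reg = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1 or not parts[1]:
                reg.add_unit(parts[0])
            else:
                factor = float(parts[2]) if len(parts) > 2 else 1.0
                offset = float(parts[3]) if len(parts) > 3 else 0.0
                reg.add(parts[0], parts[1], factor, offset)
        return reg


def default_unit_registry() -> UnitRegistry:
    ref = importlib_resources.files("oceanpack") / "data" / "units.tsv"
    with importlib_resources.as_file(ref) as path:
        return UnitRegistry.from_tsv(path)


def convert_value(value: float, from_unit: str, to_unit: str,
                  registry: UnitRegistry) -> float:
    """Convert ``value`` between two registered units."""
    return registry.convert(value, from_unit, to_unit)


# ---------------------------------------------------------------------------
# discovery

@dataclass
class AttributeQuery:
    """Search request for columns by their semantic type."""

    term: str
    include_descendants: bool = False
    required_units: tuple[str, ...] = ()


@dataclass(frozen=True)
class AttributeMatch:
    package: str
    resource: str
    field: str
    rdf_type: str
    exact: bool


def search_attributes(
    packages: list[PackageDescriptor], graph: TermGraph, query: AttributeQuery
) -> list[AttributeMatch]:
    """Find fields whose rdfType equals the query term, or descends from
    it when ``include_descendants`` is set.  Deterministically ordered by
    (package, resource, field)."""
    if query.term not in graph:
        raise UnknownTermError(f"unknown query term {query.term!r}")
    accepted = {query.term}
    if query.include_descendants:
        accepted |= graph.descendants(query.term)
    out = []
    for pkg in packages:
        for res in pkg.resources:
            for f in res.fields:
                if f.rdf_type is None or f.rdf_type.curie not in accepted:
                    continue
                if query.required_units and (
                    f.unit_rdf_type is None
                    or f.unit_rdf_type.curie not in query.required_units
                ):
                    continue
                out.append(AttributeMatch(
                    pkg.name, res.name, f.name, f.rdf_type.curie,
                    exact=f.rdf_type.curie == query.term,
                ))
    out.sort(key=lambda m: (m.package, m.resource, m.field))
    return out


# ---------------------------------------------------------------------------
# harmonization

@dataclass
class LoadedPackage:
    """A descriptor together with its parsed resource tables."""

    descriptor: PackageDescriptor
    tables: dict[str, ParsedTable]

    @classmethod
    def from_dir(cls, base_dir) -> "LoadedPackage":
        pkg = load_package_dir(base_dir)
        tables = {r.name: load_resource(pkg, r.name, base_dir)
                  for r in pkg.resources}
        return cls(pkg, tables)


@dataclass(frozen=True)
class CellProvenance:
    """Where one harmonized value came from."""

    package: str
    resource: str
    field: str
    original_unit: str | None
    device: str | None
    original_value: float | None


@dataclass
class ConflictRecord:
    """A value that lost a cell conflict, kept for the audit trail."""

    sample: str
    attribute: str
    losing: CellProvenance
    reason: str


@dataclass
class HarmonizedTable:
    """Sample x semantic-attribute matrix with per-cell provenance.

    ``values`` is indexed by sample identifier with one column per
    attribute CURIE, every column in a single unit (``units``).
    """

    values: pd.DataFrame
    units: dict = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)
    context: pd.DataFrame | None = None
    context_flags: list = dc_field(default_factory=list)
    conflicts: list = dc_field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.values.columns)

    def device_summary(self) -> dict:
        """Distinct device CURIEs observed per attribute column.

        Mixed instrumentation is surfaced here rather than blocking the
        merge; downstream users decide comparability.
        """
        out: dict[str, set] = {a: set() for a in self.attributes}
        for (sample, attr), prov in self.provenance.items():
            if prov.device:
                out[attr].add(prov.device)
        return {a: sorted(devs) for a, devs in out.items()}


def _find_sample_id_field(res, sample_id_field: str) -> str | None:
    names = [f.name for f in res.fields]
    if sample_id_field in names:
        return sample_id_field
    for f in res.fields:
        if f.rdf_type is not None and f.rdf_type.curie == "TEMP:0000010":
            return f.name
    return None


def build_harmonized_table(
    packages: list[LoadedPackage],
    graph: TermGraph,
    attributes: list[str],
    registry: UnitRegistry,
    sample_id_field: str = "sample_id",
    target_units: dict | None = None,
    strict_units: bool = True,
) -> HarmonizedTable:
    """Merge the requested attributes across packages into one table.

    For every data row carrying a sample identifier, each requested
    attribute is filled from the best matching annotated field: an
    exact-term field beats a descendant-term one, then a device-annotated
    field beats an unannotated one, then the earlier package wins.
    Losing values are logged as conflicts, never silently dropped.

    Each attribute column ends up in one unit — the target from
    ``target_units`` when given, else the unit of the first contributing
    field.  Unconvertible units raise under ``strict_units``; otherwise
    the offending value is skipped and logged as a conflict.
    """
    for attr in attributes:
        if attr not in graph:
            raise UnknownTermError(f"unknown attribute term {attr!r}")

    target_units = dict(target_units or {})
    accepted = {a: {a} | graph.descendants(a) for a in attributes}

    # contributions[(sample, attr)] -> list of (priority, value, prov)
    contributions: dict[tuple, list] = {}
    sample_order: list[str] = []
    seen_samples: set[str] = set()

    for pkg_idx, lp in enumerate(packages):
        for res in lp.descriptor.resources:
            table = lp.tables[res.name]
            id_col = _find_sample_id_field(res, sample_id_field)
            if id_col is None:
                continue
            ids = table.column(id_col)
            clean_ids = [i for i in ids
                         if i is not None and not isinstance(i, TypedCellError)]
            if len(set(clean_ids)) != len(clean_ids):
                raise DuplicateSampleError(
                    f"duplicate sample identifiers in {lp.descriptor.name}/"
                    f"{res.name}"
                )
            for attr in attributes:
                for f in res.fields:
                    if f.rdf_type is None or f.rdf_type.curie not in accepted[attr]:
                        continue
                    exact = f.rdf_type.curie == attr
                    unit = f.unit_rdf_type.curie if f.unit_rdf_type else None
                    device = (f.measurement_source_rdf_type.curie
                              if f.measurement_source_rdf_type else None)
                    col = table.column(f.name)
                    for sid, val in zip(ids, col):
                        if sid is None or isinstance(sid, TypedCellError):
                            continue
                        if val is None or isinstance(val, TypedCellError):
                            continue
                        if sid not in seen_samples:
                            seen_samples.add(sid)
                            sample_order.append(sid)
                        prov = CellProvenance(
                            lp.descriptor.name, res.name, f.name, unit, device, val,
                        )
                        priority = (0 if exact else 1, 0 if device else 1, pkg_idx)
                        contributions.setdefault((sid, attr), []).append(
                            (priority, val, prov)
                        )

    values = pd.DataFrame(index=pd.Index(sample_order, name="sample"),
                          columns=list(attributes), dtype=float)
    provenance: dict = {}
    conflicts: list[ConflictRecord] = []
    units: dict = {}

    for (sid, attr), cands in sorted(contributions.items(),
                                     key=lambda kv: (kv[0][1], kv[0][0])):
        cands.sort(key=lambda c: c[0])
        target = target_units.get(attr) or units.get(attr)
        chosen = None
        for priority, val, prov in cands:
            if chosen is None:
                if target is None or prov.original_unit is None:
                    converted = val
                    if target is None and prov.original_unit is not None:
                        target = prov.original_unit
                elif registry.convertible(prov.original_unit, target):
                    converted = registry.convert(val, prov.original_unit, target)
                else:
                    msg = (f"unit {prov.original_unit} not convertible to "
                           f"column unit {target}")
                    if strict_units:
                        raise IncompatibleUnitsError(
                            f"{attr} from {prov.package}/{prov.field}: {msg}"
                        )
                    conflicts.append(ConflictRecord(sid, attr, prov, msg))
                    continue
                chosen = (converted, prov)
            else:
                conflicts.append(ConflictRecord(
                    sid, attr, prov, "lost cell conflict to higher-priority source"
                ))
        if chosen is not None:
            values.loc[sid, attr] = chosen[0]
            provenance[(sid, attr)] = chosen[1]
            if attr not in units and target is not None:
                units[attr] = target
    for attr in attributes:
        units.setdefault(attr, target_units.get(attr))

    return HarmonizedTable(values=values, units=units, provenance=provenance,
                           conflicts=conflicts)


# ---------------------------------------------------------------------------
# environmental context

_CONTEXT_SLOTS = (("biome", BIOME_ROOT), ("feature", FEATURE_ROOT),
                  ("material", MATERIAL_ROOT))


def _context_field(res, slot: str, root: str) -> str | None:
    for f in res.fields:
        if f.rdf_type is not None and f.rdf_type.curie == root:
            return f.name
    aliases = {"biome": ("biome",), "feature": ("env_feature", "feature"),
               "material": ("env_material", "material")}
    for f in res.fields:
        if f.name.lower() in aliases[slot]:
            return f.name
    return None


def attach_env_context(
    table: HarmonizedTable,
    packages: list[LoadedPackage],
    graph: TermGraph,
    sample_id_field: str = "sample_id",
) -> HarmonizedTable:
    """Attach per-sample biome/feature/material ENVO terms.

    Context cells may hold PURLs or CURIEs.  Terms missing from the graph
    are kept (as bare refs) and recorded in ``context_flags`` rather than
    dropped.
    """
    ctx = pd.DataFrame(index=table.values.index,
                       columns=[s for s, _ in _CONTEXT_SLOTS], dtype=object)
    flags: list[tuple] = []
    for lp in packages:
        for res in lp.descriptor.resources:
            t = lp.tables[res.name]
            id_col = _find_sample_id_field(res, sample_id_field)
            if id_col is None:
                continue
            ids = t.column(id_col)
            for slot, root in _CONTEXT_SLOTS:
                col_name = _context_field(res, slot, root)
                if col_name is None:
                    continue
                for sid, raw in zip(ids, t.column(col_name)):
                    if (sid is None or raw is None
                            or isinstance(raw, TypedCellError)
                            or sid not in ctx.index):
                        continue
                    try:
                        curie = (purl_to_curie(raw)
                                 if str(raw).startswith("http") else str(raw))
                    except Exception:
                        flags.append((sid, slot, raw, "unparseable term"))
                        continue
                    if curie in graph:
                        ref = graph.term(curie)
                    else:
                        ref = OntologyTermRef(curie)
                        flags.append((sid, slot, curie, "term not in graph"))
                    if pd.isna(ctx.loc[sid, slot]):
                        ctx.loc[sid, slot] = ref
    table.context = ctx
    table.context_flags = flags
    return table


# ---------------------------------------------------------------------------
# climate zones

class ClimateZone(enum.Enum):
    """Latitude band, each tied to its ENVO climate term."""

    TROPICAL = OntologyTermRef("ENVO:01000204", "tropical")
    TEMPERATE = OntologyTermRef("ENVO:01000206", "temperate")
    POLAR = OntologyTermRef("ENVO:01000238", "polar")

    @property
    def term(self) -> OntologyTermRef:
        return self.value


#: Astronomical tropic and polar circles; boundaries go poleward.
TROPIC_LATITUDE = 23.5
POLAR_LATITUDE = 66.5


def climate_zone(
    latitude: float,
    tropic: float = TROPIC_LATITUDE,
    polar: float = POLAR_LATITUDE,
) -> ClimateZone:
    """Bin a latitude into tropical / temperate / polar.

    ``|lat| < tropic`` is tropical, ``tropic <= |lat| < polar`` temperate,
    ``|lat| >= polar`` polar — so the three bins partition [-90, 90]
    exactly, boundary values going poleward.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    a = abs(latitude)
    if a < tropic:
        return ClimateZone.TROPICAL
    if a < polar:
        return ClimateZone.TEMPERATE
    return ClimateZone.POLAR


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class Predicate:
    """Row filter on one attribute column."""

    attribute: str
    minimum: float | None = None
    maximum: float | None = None
    non_null: bool = False

    def __post_init__(self):
        if (self.minimum is not None and self.maximum is not None
                and self.minimum > self.maximum):
            raise ColumnError(
                f"predicate on {self.attribute!r}: minimum {self.minimum} > "
                f"maximum {self.maximum}"
            )


def filter_samples(
    table: HarmonizedTable, predicates: list[Predicate]
) -> tuple[HarmonizedTable, int]:
    """Keep rows satisfying every predicate; returns (table, n_removed)."""
    keep = pd.Series(True, index=table.values.index)
    for p in predicates:
        if p.attribute not in table.values.columns:
            raise ColumnError(f"unknown attribute column {p.attribute!r}")
        col = table.values[p.attribute]
        if p.non_null:
            keep &= col.notna()
        if p.minimum is not None:
            keep &= col.notna() & (col >= p.minimum)
        if p.maximum is not None:
            keep &= col.notna() & (col <= p.maximum)
    kept_index = table.values.index[keep]
    out = HarmonizedTable(
        values=table.values.loc[kept_index].copy(),
        units=dict(table.units),
        provenance={k: v for k, v in table.provenance.items()
                    if k[0] in set(kept_index)},
        context=(table.context.loc[kept_index].copy()
                 if table.context is not None else None),
        context_flags=list(table.context_flags),
        conflicts=list(table.conflicts),
    )
    return out, int((~keep).sum())
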
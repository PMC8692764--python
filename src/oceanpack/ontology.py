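"""Lightweight ontology term graph for subsumption-aware discovery.

Rather than reasoning over full OWL releases, the package works from flat
term tables (``curie<TAB>label<TAB>parents``) holding just the is-a
hierarchy.  That is all that attribute discovery needs: a query for a
general concept (say, a chlorophyll concentration) should also find
columns annotated with more specific descendants (chlorophyll *a*).

The module also mints new chemical-concentration terms following the
"dead simple" design-pattern recipe: a label of the form
``concentration of <solute> in <material>`` plus an equivalence
expression tying together a PATO quality, a CHEBI solute and an ENVO
environmental material.  Minted terms get provisional ``TEMP:``
identifiers — real ontology IDs are assigned by the upstream ontology,
never fabricated here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from importlib import resources as importlib_resources
from pathlib import Path

import networkx as nx

from .errors import (
    AmbiguousTermError,
    CyclicHierarchyError,
    DuplicateTermError,
    UnknownTermError,
    UnsupportedNamespaceError,
)
from .package_model import OntologyTermRef

#: PATO quality used by every minted concentration term.
CONCENTRATION_QUALITY = OntologyTermRef("PATO:0000033", "concentration of")


@dataclass
class TermGraph:
    """Is-a term hierarchy with ancestor/descendant closure queries.

    Edges point child -> parent.  Parents referenced but never defined are
    kept in :attr:`dangling` and excluded from the graph proper.
    """

    _g: nx.DiGraph = dc_field(default_factory=nx.DiGraph)
    dangling: set[str] = dc_field(default_factory=set)

    def __contains__(self, curie: str) -> bool:
        return curie in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def curies(self) -> list[str]:
        return sorted(self._g.nodes)

    def add_term(self, curie: str, label: str = "", parents: tuple[str, ...] = ()):
        if curie in self._g and self._g.nodes[curie].get("defined"):
            raise DuplicateTermError(f"duplicate term {curie!r}")
        self._g.add_node(curie, label=label, defined=True)
        for p in parents:
            self._g.add_edge(curie, p)
            if p not in self._g or not self._g.nodes[p].get("defined"):
                self.dangling.add(p)

    def _finalize(self):
        """Resolve dangling parents and check acyclicity."""
        self.dangling = {
            n for n in self._g.nodes if not self._g.nodes[n].get("defined")
        }
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = [u for u, _ in nx.find_cycle(self._g)]
            raise CyclicHierarchyError(
                f"cyclic is-a hierarchy: {' -> '.join(cycle + cycle[:1])}",
                cycle=cycle,
            )

    def term(self, curie: str) -> OntologyTermRef:
        if curie not in self._g:
            raise UnknownTermError(f"unknown term {curie!r}")
        return OntologyTermRef(curie, self._g.nodes[curie].get("label", ""))

    def label(self, curie: str) -> str:
        return self.term(curie).label

    def parents(self, curie: str) -> set[str]:
        if curie not in self._g:
            raise UnknownTermError(f"unknown term {curie!r}")
        return set(self._g.successors(curie))

    def ancestors(self, curie: str) -> set[str]:
        """Transitive is-a closure above ``curie`` (excluding itself)."""
        if curie not in self._g:
            raise UnknownTermError(f"unknown term {curie!r}")
        return nx.descendants(self._g, curie)  # edges run child -> parent

    def descendants(self, curie: str) -> set[str]:
        """All terms that have ``curie`` among their ancestors."""
        if curie not in self._g:
            raise UnknownTermError(f"unknown term {curie!r}")
        return nx.ancestors(self._g, curie)

    def is_a(self, curie: str, ancestor: str) -> bool:
        """True when ``curie`` equals ``ancestor`` or descends from it."""
        return curie == ancestor or ancestor in self.ancestors(curie)

    def resolve(self, query: str) -> OntologyTermRef:
        """Look up a term by CURIE first, then by exact (case-insensitive)
        label.  Two terms sharing a label make the label query ambiguous."""
        if query in self._g:
            return self.term(query)
        wanted = query.strip().lower()
        hits = [
            n for n, d in self._g.nodes(data=True)
            if d.get("defined") and d.get("label", "").lower() == wanted
        ]
        if not hits:
            raise UnknownTermError(f"no term with CURIE or label {query!r}")
        if len(hits) > 1:
            raise AmbiguousTermError(
                f"label {query!r} matches {len(hits)} terms: {sorted(hits)}",
                candidates=sorted(hits),
            )
        return self.term(hits[0])


def load_term_table(rows) -> TermGraph:
    """Build a :class:`TermGraph` from (curie, label, parents) rows.

    ``rows`` is an iterable of 3-tuples; ``parents`` may be a
    pipe-separated string or an iterable of CURIEs.  Raises on duplicate
    CURIEs and on cycles; dangling parents are tolerated and recorded.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("term table is empty")
    graph = TermGraph()
    for curie, label, parents in rows:
        if isinstance(parents, str):
            parents = tuple(p for p in parents.split("|") if p)
        graph.add_term(curie, label, tuple(parents))
    graph._finalize()
    return graph


def load_term_table_tsv(path) -> TermGraph:
    """Read a TSV term table with header ``curie	label	parents``."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        parts = (line.split("\t") + ["", ""])[:3]
        rows.append((parts[0], parts[1], parts[2]))
    return load_term_table(rows)


def load_default_terms() -> TermGraph:
    """The term table bundled with the package (a small synthetic extract
    of ENVO/UO/OBI/CHEBI/PATO plus fixture-local ``TEMP:`` terms)."""
    ref = importlib_resources.files("oceanpack") / "data" / "pm_terms.tsv"
    with importlib_resources.as_file(ref) as path:
        return load_term_table_tsv(path)


@dataclass(frozen=True)
class MintedTerm:
    """A concentration term produced by the design-pattern recipe."""

    curie: str
    label: str
    solute: OntologyTermRef
    material: OntologyTermRef
    quality: OntologyTermRef

    @property
    def equivalence(self) -> dict:
        return {
            "quality": self.quality.curie,
            "inheres-in": {
                "solute": self.solute.curie,
                "part-of-or-in": self.material.curie,
            },
        }

    def render_equivalence(self) -> str:
        """Deterministic single-line rendering of the equivalence
        expression; identical inputs always yield identical text."""
        return (
            f"'{self.quality.label}' ({self.quality.curie}) and inheres_in some "
            f"('{self.solute.label}' ({self.solute.curie}) and part_of some "
            f"'{self.material.label}' ({self.material.curie}))"
        )


def mint_concentration_term(
    graph: TermGraph, solute: str, material: str
) -> MintedTerm:
    """Mint ``concentration of <solute> in <material>``.

    ``solute`` must be a CHEBI CURIE and ``material`` an ENVO term (in the
    environmental-material branch when the graph encodes one).  The minted
    identifier is a deterministic provisional ``TEMP:`` id derived from
    the input pair, so minting is a pure function.
    """
    solute_ref = graph.term(solute) if solute in graph else None
    if solute_ref is None:
        raise UnknownTermError(f"unknown solute term {solute!r}")
    if solute_ref.prefix != "CHEBI":
        raise UnsupportedNamespaceError(
            f"solute must be a CHEBI term, got {solute!r}"
        )
    material_ref = graph.term(material) if material in graph else None
    if material_ref is None:
        raise UnknownTermError(f"unknown material term {material!r}")
    if "ENVO:00010483" in graph and not graph.is_a(material, "ENVO:00010483"):
        raise UnsupportedNamespaceError(
            f"material {material!r} is not in the environmental-material branch"
        )
    label = f"concentration of {solute_ref.label} in {material_ref.label}"
    digest = hashlib.md5(f"{solute}+{material}".encode()).hexdigest()[:7]
    return MintedTerm(
        curie=f"TEMP:{digest}",
        label=label,
        solute=solute_ref,
        material=material_ref,
        quality=CONCENTRATION_QUALITY,
    )
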
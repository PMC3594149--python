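"""Gene Ontology graph: OBO parsing, level assignment, and navigation.

The ontology is held as a typed directed acyclic graph whose nodes are GO
terms and whose edges point from child to parent. All seven GO relation
types found in OBO files (``is_a``, ``part_of``, ``has_part``,
``regulates``, ``occurs_in``, ``positively_regulates``,
``negatively_regulates``) are retained as typed edges, but levels,
navigation and annotation propagation only traverse the true-path
relations ``is_a`` and ``part_of`` by default: ``has_part`` points in the
opposite part-whole direction and the regulation/occurrence relations do
not imply annotation inheritance. The traversal set is configurable.

Each of the three namespaces (molecular_function, biological_process,
cellular_component) forms an independent rooted graph. Every term gets a
*level*: its shortest-path edge distance from the namespace root, with the
root at level 0. Because terms may have several parents, leaves (terms
with no children) can sit at different levels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import DataError

logger = logging.getLogger(__name__)

#: All edge types retained from the OBO file.
RELATIONS = frozenset(
    {
        "is_a",
        "part_of",
        "has_part",
        "regulates",
        "occurs_in",
        "positively_regulates",
        "negatively_regulates",
    }
)

#: Relations that define the rooted DAG used for levels, navigation and
#: annotation propagation (the conventional true-path closure).
DEFAULT_TRAVERSAL = frozenset({"is_a", "part_of"})

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

_GO_ID = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class GOTerm:
    """A single GO term (non-obsolete once inside an :class:`OntologyGraph`)."""

    id: str
    name: str
    namespace: str
    is_obsolete: bool = False

    def __post_init__(self) -> None:
        if not _GO_ID.match(self.id):
            raise DataError(f"invalid GO accession: {self.id!r}")
        if self.namespace not in NAMESPACES:
            raise DataError(
                f"unknown namespace {self.namespace!r} for {self.id}"
            )


@dataclass
class OntologyGraph:
    """Typed GO DAG with per-namespace roots and level assignments.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edges run from
    child to parent, keyed by relation type. ``skipped`` records obsolete
    terms dropped at parse time.
    """

    terms: dict[str, GOTerm]
    graph: nx.MultiDiGraph
    traversal: frozenset[str] = DEFAULT_TRAVERSAL
    skipped: list[str] = field(default_factory=list)
    _levels: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)
    _roots: dict[str, str] = field(default_factory=dict, repr=False)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        terms: Iterable[GOTerm],
        edges: Iterable[tuple[str, str, str]],
        traversal: Iterable[str] = DEFAULT_TRAVERSAL,
    ) -> "OntologyGraph":
        """Build a graph from (child_id, parent_id, relation) triples."""
        term_map = {t.id: t for t in terms}
        g = nx.MultiDiGraph()
        g.add_nodes_from(term_map)
        for child, parent, rel in edges:
            if rel not in RELATIONS:
                raise DataError(f"unknown relation {rel!r} on edge {child}->{parent}")
            for end in (child, parent):
                if end not in term_map:
                    raise DataError(
                        f"edge {child} -{rel}-> {parent} references undeclared term {end}"
                    )
            g.add_edge(child, parent, key=rel)
        return cls(terms=term_map, graph=g, traversal=frozenset(traversal))

    # -- basic queries --------------------------------------------------

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        """All typed edges as (child_id, parent_id, relation) triples."""
        return set(self.graph.edges(keys=True))

    def _traversal_edges(self) -> Iterable[tuple[str, str]]:
        for child, parent, rel in self.graph.edges(keys=True):
            if rel in self.traversal:
                yield child, parent

    def traversal_graph(self) -> nx.DiGraph:
        """Child->parent digraph restricted to the traversal relations."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self._traversal_edges())
        return g

    def namespace_terms(self, namespace: str) -> set[str]:
        return {t.id for t in self.terms.values() if t.namespace == namespace}

    def root(self, namespace: str) -> str:
        """The unique parentless term of a namespace under traversal relations."""
        if namespace not in NAMESPACES:
            raise DataError(f"unknown namespace {namespace!r}")
        if namespace not in self._roots:
            tg = self.traversal_graph()
            candidates = sorted(
                t
                for t in self.namespace_terms(namespace)
                if tg.out_degree(t) == 0
            )
            if len(candidates) > 1:
                # terms tied to the graph only by non-traversal relations
                # (e.g. regulates) are not root candidates
                candidates = [
                    t for t in candidates if self.graph.out_degree(t) == 0
                ]
            if not candidates:
                raise DataError(f"namespace {namespace!r} has no terms or no root")
            if len(candidates) > 1:
                raise DataError(
                    f"namespace {namespace!r} has multiple parentless terms: "
                    + ", ".join(candidates)
                )
            self._roots[namespace] = candidates[0]
        return self._roots[namespace]

    # -- levels (Fig-3 style navigation) --------------------------------

    def assign_levels(self, namespace: str) -> dict[str, int]:
        """Shortest-path edge distance of every reachable term from the root.

        The root gets level 0, its children level 1, and so on; a
        multi-parent term takes the length of its *shortest* root path.
        Terms not reachable from the root get no level and are logged.
        """
        if namespace in self._levels:
            return self._levels[namespace]
        root = self.root(namespace)
        tg = self.traversal_graph()
        sub = tg.subgraph(self.namespace_terms(namespace))
        if not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            raise DataError(
                f"cycle among traversal relations involving {cycle[0][0]}"
            )
        # edges run child->parent; walk them backwards from the root
        down = sub.reverse(copy=False)
        levels = nx.single_source_shortest_path_length(down, root)
        unreachable = set(sub) - set(levels)
        if unreachable:
            logger.warning(
                "%d %s term(s) unreachable from root %s: %s",
                len(unreachable),
                namespace,
                root,
                ", ".join(sorted(unreachable)[:5]),
            )
        self._levels[namespace] = dict(levels)
        return self._levels[namespace]

    def children_at(self, term_id: str) -> set[str]:
        """Direct children of a term (one navigation step toward the leaves)."""
        if term_id not in self.terms:
            raise DataError(f"unknown term {term_id!r}")
        return {
            child
            for child, _parent, rel in self.graph.in_edges(term_id, keys=True)
            if rel in self.traversal
        }

    def leaves(self, namespace: str) -> set[str]:
        """Reachable terms with no children: the most specific GO terms.

        Leaves may sit at several different levels of the graph.
        """
        levels = self.assign_levels(namespace)
        return {t for t in levels if not self.children_at(t)}

    def nodes_at_level(self, namespace: str, level: int) -> set[str]:
        """All terms whose assigned level equals ``level`` (root at 0)."""
        if level < 0:
            raise DataError(f"level must be non-negative, got {level}")
        levels = self.assign_levels(namespace)
        return {t for t, l in levels.items() if l == level}

    def max_level(self, namespace: str) -> int:
        return max(self.assign_levels(namespace).values())

    def descendants(self, term_id: str) -> set[str]:
        """All terms below ``term_id`` under traversal relations (excl. itself)."""
        if term_id not in self.terms:
            raise DataError(f"unknown term {term_id!r}")
        return set(nx.ancestors(self.traversal_graph(), term_id))

    # -- export ---------------------------------------------------------

    def to_edge_tsv(self) -> str:
        """Two-column-plus-relation TSV export, for debugging."""
        lines = ["child_id\tparent_id\trelation"]
        for child, parent, rel in sorted(self.edges):
            lines.append(f"{child}\t{parent}\t{rel}")
        return "\n".join(lines) + "\n"

    def to_obo(self) -> str:
        """Serialize back to OBO 1.2 text (terms sorted by accession)."""
        blocks = ["format-version: 1.2", "ontology: comparego-export", ""]
        for tid in sorted(self.terms):
            term = self.terms[tid]
            lines = [
                "[Term]",
                f"id: {term.id}",
                f"name: {term.name}",
                f"namespace: {term.namespace}",
            ]
            for child, parent, rel in sorted(self.graph.out_edges(tid, keys=True)):
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks) + "\n"


def parse_obo(
    path: str,
    traversal: Iterable[str] = DEFAULT_TRAVERSAL,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are excluded from the graph and recorded in
    ``graph.skipped``; all seven relation types are kept as typed edges.
    Raises :class:`DataError` on malformed input or edges that reference
    terms never declared in the file.
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise DataError(f"failed to parse OBO file {path!r}: {exc}") from exc

    terms: dict[str, GOTerm] = {}
    skipped: list[str] = []
    for node, data in raw.nodes(data=True):
        if "name" not in data or "namespace" not in data:
            raise DataError(
                f"term {node} referenced but never declared (or missing "
                "name/namespace) in {path!r}"
            )
        if str(data.get("is_obsolete", "")).lower() == "true":
            skipped.append(node)
            continue
        terms[node] = GOTerm(id=node, name=data["name"], namespace=data["namespace"])
    if skipped:
        logger.warning("skipped %d obsolete term(s): %s", len(skipped), ", ".join(skipped))

    edges = []
    for child, parent, rel in raw.edges(keys=True):
        if child in terms and parent in terms:
            if rel not in RELATIONS:
                logger.warning("ignoring unsupported relation %r", rel)
                continue
            edges.append((child, parent, rel))

    graph = OntologyGraph.from_edges(terms.values(), edges, traversal=traversal)
    graph.skipped = skipped
    return graph
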
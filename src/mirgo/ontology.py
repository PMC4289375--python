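"""Ontology parsing and true-path-rule annotation propagation.

An ontology is a rooted directed acyclic graph of terms with typed
child-to-parent edges (``is_a``, ``part_of``, ``regulates``) and one root
per namespace (e.g. biological_process).  A gene annotated to a term is
implicitly annotated to every ancestor reachable via *propagating* edges —
by default ``is_a`` and ``part_of`` only; ``regulates`` edges are parsed and
kept for display but do not propagate annotations, following standard
true-path practice.

OBO files are ingested through :mod:`obonet`; the in-memory representation
is a :class:`networkx.MultiDiGraph` with child-to-parent edges keyed by the
relation type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "PROPAGATING_EDGES",
    "KNOWN_EDGE_TYPES",
    "OntologyGraph",
    "AnnotationTable",
    "CycleError",
    "parse_obo",
    "write_obo",
    "read_annotations",
    "write_annotations",
    "propagate",
]

PROPAGATING_EDGES = frozenset({"is_a", "part_of"})
KNOWN_EDGE_TYPES = frozenset({"is_a", "part_of", "regulates"})


class CycleError(ValueError):
    """The ontology contains a cycle (it must be a DAG)."""


class OntologyGraph:
    """A rooted DAG of ontology terms with typed edges.

    Parameters
    ----------
    graph : networkx.MultiDiGraph
        Directed child-to-parent edges keyed by relation type; node
        attributes ``name`` and ``namespace``.
    """

    def __init__(self, graph: nx.MultiDiGraph) -> None:
        self.graph = graph
        self._check_acyclic()
        self._ancestor_cache: dict[frozenset, dict[str, frozenset]] = {}

    def _check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            terms = sorted({u for u, *_ in cycle} | {v for _, v, *_ in cycle})
            raise CycleError(f"ontology contains a cycle through terms {terms}")

    # -- basic accessors --------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "default")

    @property
    def namespaces(self) -> list[str]:
        return sorted({self.namespace(t) for t in self.graph.nodes})

    def namespace_terms(self, namespace: str) -> set[str]:
        return {t for t in self.graph.nodes if self.namespace(t) == namespace}

    @property
    def roots(self) -> dict[str, str]:
        """One root term per namespace: the term without propagating parents."""
        out: dict[str, str] = {}
        for t in self.graph.nodes:
            has_parent = any(
                key in PROPAGATING_EDGES
                for _, _, key in self.graph.out_edges(t, keys=True)
            )
            if not has_parent:
                ns = self.namespace(t)
                if ns in out:
                    raise ValueError(f"multiple roots in namespace {ns!r}")
                out[ns] = t
        return out

    def edges(self, edge_types=None):
        """Iterate (child, parent, type) triples, optionally filtered."""
        for u, v, key in self.graph.edges(keys=True):
            if edge_types is None or key in edge_types:
                yield u, v, key

    # -- traversal --------------------------------------------------------
    def parents(self, term: str, edge_types=PROPAGATING_EDGES) -> set[str]:
        return {
            v for _, v, key in self.graph.out_edges(term, keys=True) if key in edge_types
        }

    def children(self, term: str, edge_types=PROPAGATING_EDGES) -> set[str]:
        return {
            u for u, _, key in self.graph.in_edges(term, keys=True) if key in edge_types
        }

    def ancestors(self, term: str, edge_types=PROPAGATING_EDGES) -> frozenset:
        """All proper ancestors of ``term`` along the given edge types."""
        return self.ancestor_closure(edge_types)[term]

    def descendants(self, term: str, edge_types=PROPAGATING_EDGES) -> set[str]:
        out: set[str] = set()
        stack = list(self.children(term, edge_types))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.children(t, edge_types))
        return out

    def ancestor_closure(self, edge_types=PROPAGATING_EDGES) -> dict[str, frozenset]:
        """Proper-ancestor sets for every term, computed once and cached."""
        key = frozenset(edge_types)
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return cached
        parents = {t: self.parents(t, key) for t in self.graph.nodes}
        closure: dict[str, frozenset] = {}
        for term in TopologicalSorter(parents).static_order():
            anc: set[str] = set()
            for p in parents[term]:
                anc.add(p)
                anc |= closure[p]
            closure[term] = frozenset(anc)
        self._ancestor_cache[key] = closure
        return closure


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2-style file into an :class:`OntologyGraph`.

    Obsolete terms are dropped (obonet's default); relationship types other
    than ``part_of``/``regulates`` are ignored with a warning; a cycle in
    the term graph raises :class:`CycleError` naming the offending terms.
    """
    raw = obonet.read_obo(path)
    graph = nx.MultiDiGraph()
    for node, data in raw.nodes(data=True):
        graph.add_node(
            node,
            name=data.get("name", node),
            namespace=data.get("namespace", "default"),
        )
    unknown: set[str] = set()
    for u, v, key in raw.edges(keys=True):
        if key in KNOWN_EDGE_TYPES:
            graph.add_edge(u, v, key=key)
        else:
            unknown.add(key)
    if unknown:
        warnings.warn(
            f"ignoring unknown relationship types: {sorted(unknown)}", stacklevel=2
        )
    return OntologyGraph(graph)


def write_obo(ontology: OntologyGraph, path, ontology_name: str = "synthetic-go") -> None:
    """Write an :class:`OntologyGraph` as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(ontology.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.name(term)}")
        lines.append(f"namespace: {ontology.namespace(term)}")
        for _, parent, key in sorted(ontology.graph.out_edges(term, keys=True)):
            if key == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {key} {parent}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


@dataclass
class AnnotationTable:
    """Gene-to-term annotations, direct and (after propagation) per-term.

    ``direct`` maps gene -> set of directly annotated term ids.
    ``propagated`` maps term -> set of genes annotated at or below it
    (filled by :func:`propagate`).
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)
    _ns_background: dict[str, frozenset] = field(default_factory=dict, repr=False)

    def annotate(self, gene: str, term: str) -> None:
        gene = gene.strip().upper()
        self.direct.setdefault(gene, set()).add(term)

    @property
    def genes(self) -> set[str]:
        return set(self.direct)

    def term_genes(self, term: str) -> set[str]:
        return self.propagated.get(term, set())

    def background(self, ontology: OntologyGraph, namespace: str) -> frozenset:
        """Genes with at least one propagated annotation in the namespace."""
        if namespace not in self._ns_background:
            root = ontology.roots.get(namespace)
            genes = self.propagated.get(root, set()) if root else set()
            self._ns_background[namespace] = frozenset(genes)
        return self._ns_background[namespace]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "term": t}
            for g in sorted(self.direct)
            for t in sorted(self.direct[g])
        ]
        return pd.DataFrame(rows, columns=["gene", "term"])


def read_annotations(path) -> AnnotationTable:
    """Read a GAF-like annotation TSV: gene symbol, term id, evidence code.

    Headerless, tab-separated; lines starting with ``!`` are comments.
    Evidence codes are read but not filtered.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed annotation line: {line!r}")
            gene = parts[0].strip().upper()
            term = parts[1].strip()
            if gene and term:
                table.annotate(gene, term)
    return table


def write_annotations(table: AnnotationTable, path, evidence_code: str = "IEA") -> None:
    with open(path, "w") as fh:
        fh.write("! gene\tterm\tevidence_code\n")
        for gene in sorted(table.direct):
            for term in sorted(table.direct[gene]):
                fh.write(f"{gene}\t{term}\t{evidence_code}\n")


def propagate(
    ontology: OntologyGraph,
    annotations: AnnotationTable,
    edge_types=PROPAGATING_EDGES,
) -> AnnotationTable:
    """Close annotations under ancestor traversal (true-path rule).

    Returns a new :class:`AnnotationTable` whose ``propagated`` field maps
    every term to the deduplicated set of genes annotated at the term or any
    of its descendants via ``edge_types``.  Annotations to terms absent from
    the ontology are dropped with a warning.  Idempotent: propagating an
    already propagated table changes nothing.
    """
    closure = ontology.ancestor_closure(edge_types)
    out = AnnotationTable()
    dropped: set[str] = set()
    for gene, terms in annotations.direct.items():
        expanded: set[str] = set()
        for term in terms:
            if term not in ontology:
                dropped.add(term)
                continue
            expanded.add(term)
            expanded |= closure[term]
        if expanded:
            out.direct[gene] = expanded
            for term in expanded:
                out.propagated.setdefault(term, set()).add(gene)
    if dropped:
        warnings.warn(
            f"dropped annotations to {len(dropped)} unknown terms", stacklevel=2
        )
    return out
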
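import warnings

import networkx as nx
import pytest

from mirgo.ontology import AnnotationTable, OntologyGraph, propagate
from mirgo.synthetic import simulate


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="requested fold enrichments")
        warnings.filterwarnings("ignore", message="no interactions left")
        yield


@pytest.fixture(scope="session")
def desk_bundle():
    """One desk-scale synthetic study shared across tests (seed 1)."""
    return simulate(preset="desk", seed=1)


def build_ontology(edges, namespaces=None):
    """Small helper: OntologyGraph from (child, parent, type) triples."""
    g = nx.MultiDiGraph()
    nodes = {n for c, p, _ in edges for n in (c, p)}
    for n in nodes:
        g.add_node(n, name=f"name of {n}", namespace=(namespaces or {}).get(n, "bp"))
    for c, p, t in edges:
        g.add_edge(c, p, key=t)
    return OntologyGraph(g)


@pytest.fixture
def chain_ontology():
    """root <- a <- b (is_a chain)."""
    return build_ontology([("a", "root", "is_a"), ("b", "a", "is_a")])


@pytest.fixture
def diamond_ontology():
    """d is_a b, d is_a c, b is_a a, c is_a a."""
    return build_ontology(
        [
            ("d", "b", "is_a"),
            ("d", "c", "is_a"),
            ("b", "a", "is_a"),
            ("c", "a", "is_a"),
        ]
    )


def annotate(pairs):
    table = AnnotationTable()
    for gene, term in pairs:
        table.annotate(gene, term)
    return table


@pytest.fixture
def tiny_corpus(diamond_ontology):
    """Diamond DAG with a handful of genes, propagated."""
    table = annotate(
        [("G1", "d"), ("G2", "b"), ("G3", "c"), ("G4", "a"), ("G5", "d"), ("G6", "b")]
    )
    return propagate(diamond_ontology, table)
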
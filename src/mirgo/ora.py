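"""Gene Ontology over-representation analysis (ORA).

For a query gene set of size n (annotated members only) drawn against a
background of N annotated genes, a term with K background genes and k query
genes is scored with the one-sided hypergeometric tail — equivalently the
one-sided Fisher exact test on the 2x2 table — and the raw p-value is
Bonferroni-adjusted by the number m of terms actually tested in the
namespace.  Terms with adjusted p at or below the threshold t_p (default
1e-5) form the significant sub-DAG, whose *leaves* (significant terms with
no significant descendant) are the most specific significant findings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from mirgo.ontology import PROPAGATING_EDGES, AnnotationTable, OntologyGraph

__all__ = [
    "ORAConfig",
    "EnrichmentRecord",
    "SignificantDAG",
    "ORAResult",
    "hypergeom_tail",
    "expected_count",
    "bonferroni",
    "run_ora",
    "export_dag",
]


@dataclass
class ORAConfig:
    """Configuration of an ORA run.

    ``p_threshold`` is t_p, the significance threshold on the adjusted
    p-value (1e-5 for main analyses, 0.05 for null controls).
    """

    p_threshold: float = 1.0e-5
    correction: str = "bonferroni"
    direction: str = "over"
    min_term_size: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.direction not in ("over", "under", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class EnrichmentRecord:
    """Per-term ORA result.

    ``observed`` is k, ``expected`` n*K/N, ``fraction_percent`` the share of
    the annotated query set annotated to the term.  ``hit_genes`` is filled
    for significant terms only (used downstream by functional abstraction).
    """

    term: str
    name: str
    namespace: str
    observed: int
    expected: float
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    direction: str
    fraction_percent: float
    significant: bool = False
    is_leaf: bool = False
    is_functional_area: bool = False
    hit_genes: frozenset = frozenset()

    @property
    def minus_log10_p_adj(self) -> float:
        return float(-np.log10(max(self.p_adj, 5e-324)))


@dataclass
class SignificantDAG:
    """The sub-DAG induced by significant terms of one namespace.

    ``edges`` connect each significant term to its *nearest* significant
    ancestors (transitive reduction of the ancestry relation restricted to
    significant terms), so every significant ancestor of a significant term
    is reachable by an induced path.  ``leaves`` are significant terms with
    no significant descendant.
    """

    namespace: str
    nodes: dict[str, EnrichmentRecord] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)  # (child, parent)
    leaves: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class ORAResult:
    """Full output of :func:`run_ora`: records and per-namespace DAGs."""

    records: list[EnrichmentRecord]
    dags: dict[str, SignificantDAG]
    meta: dict[str, dict]
    n_unannotated: int

    def significant(self, namespace: str | None = None) -> list[EnrichmentRecord]:
        return [
            r
            for r in self.records
            if r.significant and (namespace is None or r.namespace == namespace)
        ]


def hypergeom_tail(k: int, n: int, K: int, N: int, direction: str = "over") -> float:
    """One-sided hypergeometric tail probability.

    With X ~ Hypergeometric(N, K, n): ``over`` returns P(X >= k), ``under``
    P(X <= k).  Equals the one-sided Fisher exact p-value of the 2x2 table
    [[k, n-k], [K-k, N-K-n+k]].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: n={n}, K={K}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"count k={k} outside support for n={n}, K={K}, N={N}")
    if direction == "over":
        return float(hypergeom.sf(k - 1, N, K, n))
    if direction == "under":
        return float(hypergeom.cdf(k, N, K, n))
    raise ValueError(f"unknown direction {direction!r}")


def expected_count(n: int, K: int, N: int) -> float:
    """Expected number of query genes at a term: n*K/N."""
    if N <= 0:
        raise ValueError("background size N must be positive")
    return n * K / N


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m*p)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return min(1.0, m * p)


def _tail_probs(k: np.ndarray, K: np.ndarray, n: int, N: int, direction: str):
    if direction == "over":
        return hypergeom.sf(k - 1, N, K, n)
    return hypergeom.cdf(k, N, K, n)


def run_ora(
    gene_set,
    annotations: AnnotationTable,
    ontology: OntologyGraph,
    config: ORAConfig | None = None,
    edge_types=PROPAGATING_EDGES,
) -> ORAResult:
    """Test every ontology term for over-/under-representation of a gene set.

    The query set is intersected with each namespace's annotated background
    before testing (n counts annotated members only; unannotated query genes
    are tallied in ``n_unannotated``).  m for the Bonferroni correction is
    the number of terms actually tested in the namespace (background count
    >= ``min_term_size``).
    """
    if config is None:
        config = ORAConfig()
    gene_set = {str(g).strip().upper() for g in gene_set}
    if not gene_set:
        raise ValueError("empty gene set")
    all_background: set[str] = set()
    records: list[EnrichmentRecord] = []
    dags: dict[str, SignificantDAG] = {}
    meta: dict[str, dict] = {}
    directions = ["over", "under"] if config.direction == "both" else [config.direction]

    for namespace in ontology.namespaces:
        background = annotations.background(ontology, namespace)
        all_background |= background
        query = gene_set & background
        n = len(query)
        N = len(background)
        if n == 0:
            continue
        ns_terms = sorted(ontology.namespace_terms(namespace))
        tested = [
            t
            for t in ns_terms
            if len(annotations.term_genes(t) & background) >= config.min_term_size
        ]
        m = len(tested)
        if m == 0:
            continue
        term_genes = {t: annotations.term_genes(t) & background for t in tested}
        k_arr = np.array([len(term_genes[t] & query) for t in tested])
        K_arr = np.array([len(term_genes[t]) for t in tested])

        sig_terms: set[str] = set()
        for direction in directions:
            p_raw = np.clip(_tail_probs(k_arr, K_arr, n, N, direction), 0.0, 1.0)
            if config.correction == "bonferroni":
                p_adj = np.minimum(1.0, m * p_raw)
            else:
                p_adj = p_raw
            for i, t in enumerate(tested):
                sig = bool(p_adj[i] <= config.p_threshold)
                rec = EnrichmentRecord(
                    term=t,
                    name=ontology.name(t),
                    namespace=namespace,
                    observed=int(k_arr[i]),
                    expected=expected_count(n, int(K_arr[i]), N),
                    K=int(K_arr[i]),
                    n=n,
                    N=N,
                    p_raw=float(p_raw[i]),
                    p_adj=float(p_adj[i]),
                    direction=direction,
                    fraction_percent=100.0 * int(k_arr[i]) / n,
                    significant=sig,
                    hit_genes=frozenset(term_genes[t] & query) if sig else frozenset(),
                )
                records.append(rec)
                if sig:
                    sig_terms.add(t)

        dags[namespace] = _build_significant_dag(
            namespace, records, sig_terms, ontology, edge_types
        )
        meta[namespace] = {"m": m, "n": n, "N": N}

    if not all_background & gene_set:
        raise ValueError("gene set has empty intersection with the annotated background")
    n_unannotated = len(gene_set - all_background)
    return ORAResult(records=records, dags=dags, meta=meta, n_unannotated=n_unannotated)


def _build_significant_dag(
    namespace: str,
    records: list[EnrichmentRecord],
    sig_terms: set[str],
    ontology: OntologyGraph,
    edge_types,
) -> SignificantDAG:
    dag = SignificantDAG(namespace=namespace)
    # keep the best (smallest adjusted p) record per significant term
    for rec in records:
        if rec.namespace != namespace or rec.term not in sig_terms:
            continue
        best = dag.nodes.get(rec.term)
        if best is None or rec.p_adj < best.p_adj:
            dag.nodes[rec.term] = rec
    closure = ontology.ancestor_closure(edge_types)
    for term in dag.nodes:
        sig_anc = closure[term] & sig_terms
        nearest = {
            a for a in sig_anc if not any(a in closure[b] for b in sig_anc if b != a)
        }
        for parent in sorted(nearest):
            dag.edges.append((term, parent))
    has_sig_descendant = {p for _, p in dag.edges}
    dag.leaves = set(dag.nodes) - has_sig_descendant
    for term in dag.leaves:
        dag.nodes[term].is_leaf = True
    return dag


def export_dag(
    dag: SignificantDAG,
    annotate_with=("observed", "expected", "minus_log10_p"),
) -> str:
    """Render a significant sub-DAG as Graphviz DOT text.

    One node per significant term, labeled with its name and the requested
    statistics; leaves are drawn blue, functional areas filled yellow.
    """
    if len(dag) == 0:
        warnings.warn("empty significant DAG", stacklevel=2)
        return "digraph significant_terms {\n}\n"
    lines = [
        "digraph significant_terms {",
        "  rankdir=BT;",
        '  node [shape=ellipse, color=red];',
    ]
    for term in sorted(dag.nodes):
        rec = dag.nodes[term]
        label = [rec.name, term]
        if "observed" in annotate_with:
            label.append(f"observed: {rec.observed}")
        if "expected" in annotate_with:
            label.append(f"expected: {rec.expected:.2f}")
        if "minus_log10_p" in annotate_with:
            label.append(f"-log10 p: {rec.minus_log10_p_adj:.2f}")
        text = "\\n".join(label)
        attrs = [f'label="{text}"']
        if rec.is_functional_area:
            attrs.append('style=filled, fillcolor=yellow')
        elif rec.is_leaf:
            attrs.append("color=blue")
        lines.append(f'  "{term}" [{", ".join(attrs)}];')
    for child, parent in sorted(dag.edges):
        lines.append(f'  "{child}" -> "{parent}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
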
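"""Functional abstraction: condensing a significant-term DAG into areas.

The complete DAG of significant terms is summarized by a small set of
*functional areas* chosen to jointly maximize four desiderata: coverage (the
fraction of the query set's annotated genes under the selected terms),
certainty (each area is significant at the run's threshold), information
value (term specificity, -log2 of the term's background annotation
frequency) and conciseness (few areas, none related by ancestry).

The selector is greedy: candidates are the significant terms with
information value at or above a floor; each is statically scored by
coverage x information value; at every step the best-scoring candidate that
is not an ancestor or descendant of an already selected area and whose
*marginal* gene-coverage gain meets a minimum is selected, until the area
budget is reached or no candidate qualifies.  Ties break toward higher
information value, then lexicographically smaller term id, so selection is
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from mirgo.ontology import PROPAGATING_EDGES, OntologyGraph
from mirgo.ora import EnrichmentRecord, SignificantDAG

__all__ = [
    "AbstractionParams",
    "FunctionalArea",
    "select_functional_areas",
    "apply_topic_map",
    "areas_frame",
]


@dataclass
class AbstractionParams:
    """Tunables of the greedy area selector.

    ``min_coverage_gain`` is the minimum marginal fraction of the query set a
    new area must add; ``min_information_value`` is in bits.
    """

    min_coverage_gain: float = 0.02
    max_areas: int = 25
    min_information_value: float = 1.0


@dataclass
class FunctionalArea:
    """A selected significant term summarizing part of the enrichment DAG."""

    term: str
    name: str
    namespace: str
    coverage: float
    information_value: float
    certainty: float  # -log10 adjusted p
    observed: int
    expected: float
    fraction_percent: float
    p_adj: float
    topic: str | None = None


def _information_value(rec: EnrichmentRecord) -> float:
    if rec.K <= 0:
        return 0.0
    return -math.log2(rec.K / rec.N)


def select_functional_areas(
    dag: SignificantDAG,
    ontology: OntologyGraph,
    params: AbstractionParams | None = None,
    edge_types=PROPAGATING_EDGES,
) -> list[FunctionalArea]:
    """Greedily select functional areas from a significant sub-DAG.

    Returns an empty list for an empty DAG.  Selected areas are flagged
    ``is_functional_area`` on their enrichment records.
    """
    if params is None:
        params = AbstractionParams()
    if len(dag) == 0:
        return []
    closure = ontology.ancestor_closure(edge_types)
    n = next(iter(dag.nodes.values())).n

    candidates = {
        t: rec
        for t, rec in dag.nodes.items()
        if _information_value(rec) >= params.min_information_value
    }
    scores = {
        t: (rec.observed / n) * _information_value(rec) for t, rec in candidates.items()
    }

    selected: list[str] = []
    covered: set[str] = set()
    while len(selected) < params.max_areas:
        best = None
        best_key = None
        for t, rec in candidates.items():
            if t in selected:
                continue
            related = any(
                t in closure[s] or s in closure[t] for s in selected
            )
            if related:
                continue
            gain = len(rec.hit_genes - covered) / n
            if gain < params.min_coverage_gain:
                continue
            key = (scores[t], _information_value(rec), _NegStr(t))
            if best_key is None or key > best_key:
                best, best_key = t, key
        if best is None:
            break
        selected.append(best)
        covered |= set(candidates[best].hit_genes)

    areas = []
    for t in selected:
        rec = dag.nodes[t]
        rec.is_functional_area = True
        areas.append(
            FunctionalArea(
                term=t,
                name=rec.name,
                namespace=rec.namespace,
                coverage=len(rec.hit_genes) / n,
                information_value=_information_value(rec),
                certainty=rec.minus_log10_p_adj,
                observed=rec.observed,
                expected=rec.expected,
                fraction_percent=rec.fraction_percent,
                p_adj=rec.p_adj,
            )
        )
    return areas


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def apply_topic_map(
    areas: list[FunctionalArea], topic_map: dict[str, str]
) -> list[FunctionalArea]:
    """Attach user-supplied topic labels to areas; unmapped -> "unassigned".

    Map entries whose term id matches no area are ignored with a warning.
    """
    known = {a.term for a in areas}
    unknown = sorted(set(topic_map) - known)
    if unknown:
        warnings.warn(
            f"topic map refers to {len(unknown)} unknown term ids: {unknown[:5]}",
            stacklevel=2,
        )
    for a in areas:
        a.topic = topic_map.get(a.term, "unassigned")
    return areas


def areas_frame(areas: list[FunctionalArea]) -> pd.DataFrame:
    """Tabulate areas in the report column layout."""
    rows = [
        {
            "term_id": a.term,
            "name": a.name,
            "namespace": a.namespace,
            "observed": a.observed,
            "expected": round(a.expected, 2),
            "fraction_percent": round(a.fraction_percent, 1),
            "minus_log10_p_adj": round(a.certainty, 2),
            "information_value": round(a.information_value, 3),
            "coverage": round(a.coverage, 4),
            "topic": a.topic or "",
        }
        for a in areas
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "name",
            "namespace",
            "observed",
            "expected",
            "fraction_percent",
            "minus_log10_p_adj",
            "information_value",
            "coverage",
            "topic",
        ],
    )
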
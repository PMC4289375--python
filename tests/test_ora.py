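"""Exact-test oracle agreement, Bonferroni, full ORA runs and DOT export."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirgo.ontology import propagate
from mirgo.ora import (
    ORAConfig,
    bonferroni,
    expected_count,
    export_dag,
    hypergeom_tail,
    run_ora,
)
from mirgo.synthetic import SyntheticSpec, make_corpus, make_interactions, make_ontology

from conftest import annotate, build_ontology


def exact_tail(k, n, K, N, direction="over"):
    """Independent oracle: exact rational enumeration of hypergeometric terms."""
    denom = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    if direction == "over":
        ks = range(k, hi + 1)
    else:
        ks = range(lo, k + 1)
    total = sum(Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom) for j in ks)
    return float(total)


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,n,K,N,expect",
        [
            (0, 10, 5, 20, 1.0),  # P(X >= 0) = 1
            (5, 10, 5, 20, 3003 / 184756),
            (3, 5, 4, 10, 66 / 252),
        ],
    )
    def test_known_values(self, k, n, K, N, expect):
        assert hypergeom_tail(k, n, K, N, "over") == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_agrees_with_exact_enumeration(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        for direction in ("over", "under"):
            got = hypergeom_tail(k, n, K, N, direction)
            assert got == pytest.approx(exact_tail(k, n, K, N, direction), abs=1e-12)

    def test_monotone_in_k(self):
        N, K, n = 40, 12, 15
        over = [hypergeom_tail(k, n, K, N, "over") for k in range(0, 13)]
        under = [hypergeom_tail(k, n, K, N, "under") for k in range(0, 13)]
        assert all(a >= b for a, b in zip(over, over[1:]))
        assert all(a <= b for a, b in zip(under, under[1:]))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(1, 5, 30, 20)
        with pytest.raises(ValueError):
            hypergeom_tail(6, 5, 10, 20)


class TestScalarHelpers:
    def test_expected_count(self):
        assert expected_count(10, 5, 20) == 2.5
        assert expected_count(10, 0, 20) == 0.0
        assert expected_count(2954, 831, 17794) == pytest.approx(137.96, abs=0.01)

    def test_bonferroni(self):
        assert bonferroni(0.001, 50) == pytest.approx(0.05)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(1e-40, 10**4) == pytest.approx(1e-36)


def flat_corpus(n_terms=5, genes_per_term=(), n_genes=20):
    """Star ontology: every term child of one root; explicit gene lists."""
    edges = [(f"t{i}", "root", "is_a") for i in range(n_terms)]
    ont = build_ontology(edges)
    pairs = []
    for i, genes in enumerate(genes_per_term):
        pairs += [(g, f"t{i}") for g in genes]
    # genes with no term annotation still need membership in the background
    annotated = {g for genes in genes_per_term for g in genes}
    for j in range(n_genes - len(annotated)):
        pairs.append((f"BG{j}", "t0"))
    return ont, propagate(ont, annotate(pairs))


class TestRunOra:
    def test_saturated_query_never_significant(self, desk_bundle):
        ont = desk_bundle["ontology"]
        prop = desk_bundle["propagated"]
        result = run_ora(prop.genes, prop, ont, ORAConfig(p_threshold=0.05))
        for rec in result.records:
            assert rec.observed == rec.K
            assert rec.p_raw == pytest.approx(1.0)
        assert not result.significant()

    def test_planted_term_has_minimal_p(self):
        spec = SyntheticSpec(seed=3, n_terms=300, depth=5, n_genes=3000, set_size=200)
        ont = make_ontology(spec)
        corpus, _ = make_corpus(ont, spec)
        prop = propagate(ont, corpus)
        sizes = {t: len(prop.term_genes(t)) for t in ont.terms}
        target = min(sizes, key=lambda t: abs(sizes[t] - 150))
        spec.planted_terms = {target: 5.0}
        iset, _ = make_interactions(ont, prop, spec)
        result = run_ora(iset.genes(), prop, ont, ORAConfig())
        best = min(result.records, key=lambda r: (r.p_adj, r.term))
        assert best.term == target or best.term in ont.ancestors(target)
        assert best.p_adj <= 1e-5

    def test_under_direction_on_depleted_term(self):
        ont, prop = flat_corpus(
            n_terms=3,
            genes_per_term=[[f"A{i}" for i in range(10)], [f"B{i}" for i in range(10)]],
            n_genes=20,
        )
        result = run_ora(
            [f"B{i}" for i in range(8)],
            prop,
            ont,
            ORAConfig(p_threshold=1.0, direction="both", correction="none"),
        )
        unders = [r for r in result.records if r.direction == "under" and r.term == "t0"]
        # t0 holds the 10 A-genes plus backgrounds; none queried -> depleted
        assert unders and unders[0].p_raw < 0.05

    def test_empty_background_intersection_raises(self, desk_bundle):
        with pytest.raises(ValueError, match="background"):
            run_ora(["NOT_A_GENE"], desk_bundle["propagated"], desk_bundle["ontology"])

    def test_significant_dag_closure_and_leaves(self, desk_bundle):
        ont = desk_bundle["ontology"]
        prop = desk_bundle["propagated"]
        result = run_ora(desk_bundle["empirical_a"].genes(), prop, ont, ORAConfig())
        for ns, dag in result.dags.items():
            sig = set(dag.nodes)
            for term in sig:
                for anc in ont.ancestors(term) & sig:
                    # significant ancestor reachable via induced edges
                    reached, frontier = set(), {term}
                    while frontier:
                        nxt = {
                            p for (c, p) in dag.edges if c in frontier
                        } - reached
                        reached |= nxt
                        frontier = nxt
                    assert anc in reached
            for leaf in dag.leaves:
                assert not (ont.descendants(leaf) & sig)

    def test_bonferroni_m_is_tested_term_count(self, desk_bundle):
        prop = desk_bundle["propagated"]
        ont = desk_bundle["ontology"]
        result = run_ora(
            desk_bundle["empirical_a"].genes(), prop, ont, ORAConfig(min_term_size=10)
        )
        ns = ont.namespaces[0]
        m = result.meta[ns]["m"]
        assert m == sum(
            1 for t in ont.namespace_terms(ns) if len(prop.term_genes(t)) >= 10
        )
        for rec in result.records:
            assert rec.p_adj == pytest.approx(min(1.0, m * rec.p_raw))


class TestExportDag:
    def test_single_node(self, desk_bundle):
        result = run_ora(
            desk_bundle["empirical_a"].genes(),
            desk_bundle["propagated"],
            desk_bundle["ontology"],
            ORAConfig(),
        )
        ns = desk_bundle["ontology"].namespaces[0]
        dag = result.dags[ns]
        dot = export_dag(dag)
        assert dot.count("[label=") == len(dag.nodes)
        assert dot.count("->") == len(dag.edges)
        for leaf in dag.leaves:
            assert f'"{leaf}"' in dot

    def test_empty_dag_warns(self):
        from mirgo.ora import SignificantDAG

        with pytest.warns(UserWarning, match="empty"):
            dot = export_dag(SignificantDAG(namespace="bp"))
        assert "digraph" in dot
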
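"""Generator ground-truth guarantees: reproducibility, laws, calibration."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from mirgo.ontology import parse_obo, propagate, read_annotations
from mirgo.prediction_filter import fit_score_model, read_predictions
from mirgo.synthetic import (
    SyntheticSpec,
    make_corpus,
    make_interactions,
    make_ontology,
    make_scores,
    simulate,
)


class TestOntologyGeneration:
    def test_chain_when_terms_equal_depth(self):
        spec = SyntheticSpec(seed=0, n_terms=3, depth=3, n_genes=10)
        ont = make_ontology(spec)
        assert len(ont) == 3
        root = ont.roots[ont.namespaces[0]]
        assert len(ont.descendants(root)) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_acyclic_and_rooted_across_seeds(self, seed):
        spec = SyntheticSpec(seed=seed, n_terms=120, depth=5, n_genes=50)
        ont = make_ontology(spec)  # OntologyGraph raises on cycles
        root = ont.roots[ont.namespaces[0]]
        for t in ont.terms:
            assert t == root or root in ont.ancestors(t)

    def test_multiple_namespaces(self):
        spec = SyntheticSpec(
            seed=1, n_terms=150, depth=4, n_genes=100,
            namespaces=("biological_process", "molecular_function"),
        )
        ont = make_ontology(spec)
        assert set(ont.roots) == {"biological_process", "molecular_function"}

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=0, n_terms=2, depth=6, n_genes=10)


class TestCorpusGeneration:
    def test_chain_all_annotated_at_leaf_fills_root(self):
        spec = SyntheticSpec(seed=0, n_terms=3, depth=3, n_genes=10,
                             mean_annotations=1.0)
        ont = make_ontology(spec)
        corpus, _ = make_corpus(ont, spec)
        prop = propagate(ont, corpus)
        root = ont.roots[ont.namespaces[0]]
        assert prop.term_genes(root) == prop.genes
        assert len(prop.genes) == 10

    def test_term_sizes_track_power_law(self):
        # enough draws per term that rank noise does not swamp the law
        spec = SyntheticSpec(seed=2, n_terms=150, depth=6, n_genes=20_000,
                             mean_annotations=1.0)
        ont = make_ontology(spec)
        corpus, truth = make_corpus(ont, spec)
        counts = {}
        for gene, terms in corpus.direct.items():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        weights = truth["term_weights"]
        terms = sorted(weights)
        rho = spearmanr(
            [weights[t] for t in terms], [counts.get(t, 0) for t in terms]
        ).statistic
        assert rho >= 0.9

    def test_background_is_distinct_annotated_genes(self, desk_bundle):
        prop = desk_bundle["propagated"]
        assert len(prop.genes) == desk_bundle["spec"].n_genes


class TestInteractionGeneration:
    def test_uniform_when_no_planting(self):
        # chi-square goodness of fit of per-gene selection counts vs uniform
        spec = SyntheticSpec(seed=0, n_terms=100, depth=4, n_genes=400, set_size=200)
        ont = make_ontology(spec)
        corpus, _ = make_corpus(ont, spec)
        prop = propagate(ont, corpus)
        hits = np.zeros(spec.n_genes)
        genes = sorted(prop.genes)
        index = {g: i for i, g in enumerate(genes)}
        n_seeds = 20
        for seed in range(n_seeds):
            spec.seed = seed
            iset, truth = make_interactions(ont, prop, spec)
            for g in truth["sampled_genes"]:
                hits[index[g]] += 1
        expected = n_seeds * spec.set_size / spec.n_genes
        stat, p = chisquare(hits, f_exp=np.full(spec.n_genes, expected))
        assert p > 0.01

    def test_fold_calibration(self):
        ratios = []
        for seed in range(10):
            spec = SyntheticSpec(
                seed=seed, n_terms=400, depth=6, n_genes=10_000, set_size=300
            )
            ont = make_ontology(spec)
            corpus, _ = make_corpus(ont, spec)
            prop = propagate(ont, corpus)
            sizes = {t: len(prop.term_genes(t)) for t in ont.terms}
            target = min(sizes, key=lambda t: abs(sizes[t] - 500))
            spec.planted_terms = {target: 5.0}
            iset, _ = make_interactions(ont, prop, spec)
            K, N, n = sizes[target], spec.n_genes, spec.set_size
            observed = len(prop.term_genes(target) & iset.genes())
            ratios.append(observed / (n * K / N))
        assert abs(np.mean(ratios) - 5.0) <= 1.0  # within 20% of the fold

    def test_degree_law_order_statistic(self, desk_bundle):
        degrees = sorted(
            desk_bundle["truth"]["empirical_a"]["degrees"].values(), reverse=True
        )
        assert degrees[0] >= degrees[1] >= 1
        assert degrees[0] <= desk_bundle["spec"].max_degree

    def test_planted_term_without_genes_rejected(self):
        spec = SyntheticSpec(seed=0, n_terms=50, depth=4, n_genes=100, set_size=50,
                             planted_terms={"GO:9999999": 2.0})
        ont = make_ontology(spec)
        corpus, _ = make_corpus(ont, spec)
        prop = propagate(ont, corpus)
        with pytest.raises(ValueError, match="zero background genes"):
            make_interactions(ont, prop, spec)


class TestScoreGeneration:
    def test_prior_zero_all_background(self):
        spec = SyntheticSpec(seed=0, n_genes=10, n_terms=10, depth=3,
                             prior_valid=0.0, n_predicted=500)
        _, preds = make_scores(spec)
        assert all(p.label == "background" for p in preds)

    def test_class_means_recovered(self):
        spec = SyntheticSpec(seed=5, n_genes=10, n_terms=10, depth=3,
                             n_validated=2000, n_predicted=10_000)
        validated, preds = make_scores(spec)
        model = fit_score_model(validated, [p.score for p in preds])
        assert model.valid_mean_ == pytest.approx(spec.valid_mean, abs=0.02)
        assert model.bg_mean_ == pytest.approx(spec.bg_mean, abs=0.02)

    def test_class_proportions_match_prior(self):
        spec = SyntheticSpec(seed=9, n_genes=10, n_terms=10, depth=3,
                             n_predicted=10_000)
        _, preds = make_scores(spec)
        frac = np.mean([p.label == "valid" for p in preds])
        se = np.sqrt(0.2 * 0.8 / len(preds))
        assert abs(frac - spec.prior_valid) <= 3 * se


class TestSimulateBundle:
    def test_bit_for_bit_reproducible(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate(preset="desk", seed=3, out_dir=a)
        simulate(preset="desk", seed=3, out_dir=b)
        for f in sorted(a.iterdir()):
            assert f.read_bytes() == (b / f.name).read_bytes()

    def test_written_files_reread_without_loss(self, tmp_path):
        bundle = simulate(preset="desk", seed=2, out_dir=tmp_path)
        ont = parse_obo(tmp_path / "ontology.obo")
        assert ont.terms == bundle["ontology"].terms
        ann = read_annotations(tmp_path / "annotations.tsv")
        assert ann.direct == bundle["corpus"].direct
        preds = read_predictions(tmp_path / "predicted.tsv")
        assert len(preds) == len(bundle["predictions"])
        scores = {(p.mirna, p.gene): p.score for p in bundle["predictions"]}
        assert all(
            scores[(p.mirna, p.gene)] == pytest.approx(p.score, abs=1e-9)
            for p in preds[:100]
        )
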
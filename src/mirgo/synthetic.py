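"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical shape of the real inputs without any
sequence-level realism:

* a layered, multi-parent ontology DAG with one root per namespace, acyclic
  by construction;
* an annotation corpus whose per-term direct-annotation frequencies follow a
  power law, so propagated term sizes span orders of magnitude;
* miRNA-gene interaction sets with heavy-tailed (Zipf) miRNA out-degrees —
  a few hub miRNAs with hundreds of targets, many with a single target —
  and target genes sampled with a planted enrichment: genes annotated under
  designated terms are over-sampled so the term's realized
  observed/expected ratio matches a requested fold change;
* two-component prediction scores (a "valid" and a "background" Gaussian)
  with class labels retained for precision evaluation.

Everything is reproducible bit-for-bit from (spec, seed); each stage draws
from its own deterministic sub-stream of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from mirgo.interactions import Interaction, InteractionSet, Source
from mirgo.ontology import (
    AnnotationTable,
    OntologyGraph,
    propagate,
    write_annotations,
    write_obo,
)
from mirgo.prediction_filter import ScoredPrediction, write_predictions

__all__ = [
    "SyntheticSpec",
    "DESK",
    "GENOME_SCALE",
    "make_ontology",
    "make_corpus",
    "make_interactions",
    "make_scores",
    "pick_branch_roots",
    "simulate",
]

_STAGE = {"ontology": 1, "corpus": 2, "interactions": 3, "scores": 4}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic data set.

    ``planted_terms`` maps term ids to fold enrichments (>= 1): the realized
    observed/expected ratio of a planted term in the sampled gene set is
    calibrated to the fold.  ``term_size_exponent`` shapes the power law of
    direct annotation frequencies; ``degree_exponent`` the Zipf law of miRNA
    out-degrees.  ``seed`` is mandatory.
    """

    seed: int
    n_terms: int = 500
    depth: int = 6
    n_genes: int = 2000
    namespaces: tuple = ("biological_process",)
    term_size_exponent: float = 1.0
    mean_annotations: float = 4.0
    planted_terms: dict = field(default_factory=dict)
    set_size: int = 300
    n_mirnas: int = 150
    degree_exponent: float = 2.0
    max_degree: int = 229
    valid_mean: float = -0.40
    valid_sd: float = 0.10
    bg_mean: float = -0.05
    bg_sd: float = 0.05
    prior_valid: float = 0.2
    n_validated: int = 1000
    n_predicted: int = 10000

    def __post_init__(self) -> None:
        if self.n_terms < self.depth:
            raise ValueError("need n_terms >= depth")
        if self.n_genes < 1 or self.set_size < 1 or self.n_mirnas < 1:
            raise ValueError("counts must be positive")
        for term, fold in self.planted_terms.items():
            if fold < 1:
                raise ValueError(f"fold_enrichment for {term} must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE[stage], self.seed])


#: desk-scale preset: a full pipeline run completes in seconds
DESK = dict(n_terms=500, depth=6, n_genes=2000, set_size=300, n_mirnas=150)
#: preset matching the annotated-genome scale of the real corpus
GENOME_SCALE = dict(
    n_terms=5000, depth=10, n_genes=17794, set_size=2954, n_mirnas=788
)


def make_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Build a layered multi-parent DAG, one root per namespace.

    Terms are numbered ``GO:0000001`` upward across namespaces.  Every
    non-root term has one ``is_a`` parent in the previous layer and, with
    probability 0.3, a second parent in an earlier layer of the *same
    top-level branch* (``part_of`` with probability 0.25, else ``is_a``) —
    so the polyhierarchy is genuine but the gene sets of the root's children
    stay disjoint.  A few ``regulates`` cross-links (which never propagate
    annotations) may cross branches.
    """
    rng = spec.rng("ontology")
    graph = nx.MultiDiGraph()
    counter = 1
    per_ns = [len(chunk) for chunk in np.array_split(np.arange(spec.n_terms), len(spec.namespaces))]
    for ns, n_terms in zip(spec.namespaces, per_ns):
        if n_terms < spec.depth:
            raise ValueError(f"namespace {ns}: need at least depth={spec.depth} terms")
        # geometric layer sizes: deeper layers hold more, rarer terms
        weights = np.array([1.6**d for d in range(spec.depth - 1)])
        sizes = np.maximum(1, np.round((n_terms - 1) * weights / weights.sum()).astype(int))
        while sizes.sum() > n_terms - 1:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < n_terms - 1:
            sizes[np.argmax(weights)] += 1

        layers: list[list[str]] = []
        branch_of: dict[str, str] = {}
        root = f"GO:{counter:07d}"
        counter += 1
        graph.add_node(root, name=f"{ns} root", namespace=ns)
        layers.append([root])
        for d, size in enumerate(sizes, start=1):
            layer: list[str] = []
            for _ in range(size):
                term = f"GO:{counter:07d}"
                counter += 1
                graph.add_node(term, name=f"term {counter - 1}", namespace=ns)
                parent = layers[d - 1][rng.integers(len(layers[d - 1]))]
                graph.add_edge(term, parent, key="is_a")
                branch_of[term] = term if d == 1 else branch_of[parent]
                if d > 1 and rng.random() < 0.3:
                    # second parent stays within the term's top-level branch
                    same_branch = [
                        t
                        for lvl in range(1, d)
                        for t in layers[lvl]
                        if branch_of[t] == branch_of[term]
                    ]
                    if same_branch:
                        extra = same_branch[rng.integers(len(same_branch))]
                        if extra != parent and not graph.has_edge(term, extra):
                            key = "part_of" if rng.random() < 0.25 else "is_a"
                            graph.add_edge(term, extra, key=key)
                elif d > 2 and rng.random() < 0.05:
                    lvl = int(rng.integers(1, d - 1))
                    target = layers[lvl][rng.integers(len(layers[lvl]))]
                    if not graph.has_edge(term, target):
                        graph.add_edge(term, target, key="regulates")
                layer.append(term)
            layers.append(layer)
    return OntologyGraph(graph)


def make_corpus(
    ontology: OntologyGraph, spec: SyntheticSpec
) -> tuple[AnnotationTable, dict]:
    """Draw direct gene annotations with power-law term frequencies.

    Genes are named ``G000001`` upward.  Each term carries a Zipf weight
    (random rank permutation, exponent ``term_size_exponent``).  A gene's
    annotations are correlated the way real genes' are: the gene first
    chooses a *home branch* (a child of a namespace root, proportionally to
    the branch's total term weight) and then draws its
    ``1 + Poisson(mean_annotations - 1)`` direct annotations from the terms
    of that branch, proportionally to their weights.  The marginal per-term
    annotation frequency is exactly the power law, while co-annotations of
    one gene stay thematically close.  Returns the (unpropagated) table and
    a truth dict with the per-term target weights.
    """
    rng = spec.rng("corpus")
    roots = set(ontology.roots.values())
    terms = sorted(t for t in ontology.terms if t not in roots)
    ranks = rng.permutation(len(terms)) + 1
    weights = ranks.astype(float) ** (-spec.term_size_exponent)
    weight_of = dict(zip(terms, weights))

    # branch = child of a namespace root; a term belongs to every branch
    # among its ancestors, and is drawn through one of them
    closure = ontology.ancestor_closure()
    branch_roots = sorted(
        {c for root in ontology.roots.values() for c in ontology.children(root)}
    )
    branch_terms: dict[str, list[str]] = {b: [] for b in branch_roots}
    for t in terms:
        homes = [b for b in branch_roots if b == t or b in closure[t]]
        if homes:
            # a multi-parent term is drawn through one branch only so the
            # marginal term frequency stays the target power law
            branch_terms[homes[rng.integers(len(homes))]].append(t)
    branch_mass = np.array([sum(weight_of[t] for t in branch_terms[b]) for b in branch_roots])
    branch_probs = branch_mass / branch_mass.sum()
    branch_term_probs = {
        b: np.array([weight_of[t] for t in branch_terms[b]]) / branch_mass[i]
        for i, b in enumerate(branch_roots)
        if branch_mass[i] > 0
    }

    table = AnnotationTable()
    n_ann = 1 + rng.poisson(max(spec.mean_annotations - 1.0, 0.0), size=spec.n_genes)
    homes = rng.choice(len(branch_roots), size=spec.n_genes, p=branch_probs)
    for i in range(spec.n_genes):
        gene = f"G{i + 1:06d}"
        b = branch_roots[homes[i]]
        pool = branch_terms[b]
        k = min(int(n_ann[i]), len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False, p=branch_term_probs[b])
        for j in chosen:
            table.annotate(gene, pool[j])
    truth = {"term_weights": {t: float(weight_of[t]) for t in terms}}
    return table, truth


def pick_branch_roots(
    ontology: OntologyGraph,
    propagated: AnnotationTable,
    n_branches: int,
    namespace: str | None = None,
    min_fraction: float = 0.04,
    max_fraction: float = 0.15,
) -> list[str]:
    """Choose disjoint top-level branches (children of a namespace root).

    Returns ``n_branches`` root children whose propagated gene sets are
    pairwise disjoint enough (< 20% overlap), each holding between
    ``min_fraction`` and ``max_fraction`` of the corpus — large enough for
    a planted fold to reach significance reliably, small enough that a
    strong fold is feasible and the branch keeps a useful information
    value.  Larger qualifying branches are preferred; deterministic for a
    given corpus.
    """
    ns = namespace or ontology.namespaces[0]
    root = ontology.roots[ns]
    n_corpus = len(propagated.term_genes(root))
    children = sorted(ontology.children(root), key=lambda t: (-len(propagated.term_genes(t)), t))
    picked: list[str] = []
    for t in children:
        genes = propagated.term_genes(t)
        if not min_fraction * n_corpus <= len(genes) <= max_fraction * n_corpus:
            continue
        overlap = any(
            len(genes & propagated.term_genes(p)) > 0.2 * min(len(genes), len(propagated.term_genes(p)))
            for p in picked
        )
        if not overlap:
            picked.append(t)
        if len(picked) == n_branches:
            break
    if len(picked) < n_branches:
        raise ValueError(f"could not find {n_branches} disjoint branches")
    return picked


def _planted_weights(
    genes: list[str], propagated: AnnotationTable, spec: SyntheticSpec, N: int
) -> np.ndarray:
    """Per-gene sampling weights calibrated so each planted term's realized
    observed/expected ratio matches its fold.

    Each gene gets the maximum fold over the planted terms covering it;
    within a fold-f group the weight w_f = f*S/N, with the normalizer
    S = N*(N - sum C_f) / (N - sum f*C_f) chosen so the expected in-set
    share of every group is f times its background share simultaneously
    (exact for disjoint planted gene sets).  Requires sum f*C_f < N; an
    infeasible request is scaled down proportionally with a warning.
    """
    import warnings

    fold_of = np.ones(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for term, fold in spec.planted_terms.items():
        members = propagated.term_genes(term)
        if not members:
            raise ValueError(f"planted term {term} has zero background genes")
        for g in members:
            i = index.get(g)
            if i is not None:
                fold_of[i] = max(fold_of[i], fold)
    planted = fold_of > 1.0
    if planted.any() and float(fold_of[planted].sum()) >= N:
        scale = 0.95 * N / float(fold_of[planted].sum())
        warnings.warn(
            "requested fold enrichments are jointly infeasible "
            f"(sum fold*K = {fold_of[planted].sum():.0f} vs N = {N}); "
            f"scaling planted folds by {scale:.3f}",
            stacklevel=2,
        )
        fold_of[planted] = np.maximum(1.0, fold_of[planted] * scale)
    S = N * (N - planted.sum()) / (N - float(fold_of[planted].sum()))
    w = np.where(planted, fold_of * S / N, 1.0)
    return w


def make_interactions(
    ontology: OntologyGraph,
    corpus: AnnotationTable,
    spec: SyntheticSpec,
    source: Source = Source.EMPIRICAL_A,
    evidence_pool: tuple = ("reporter assay", "western blot", "microarray"),
    evidence_probs: tuple = (0.5, 0.3, 0.2),
    name: str = "synthetic",
    stage_offset: int = 0,
) -> tuple[InteractionSet, dict]:
    """Sample an interaction set with planted enrichment and Zipf degrees.

    Target genes are drawn without replacement from the annotated corpus
    with the calibrated planted weights; miRNA out-degrees follow a
    truncated Zipf law; every sampled gene receives at least one miRNA.
    Returns the set and a truth dict (sampled genes, planted flags, degrees).
    """
    rng = np.random.default_rng([_STAGE["interactions"] + stage_offset, spec.seed])
    prop = corpus if corpus.propagated else propagate(ontology, corpus)
    genes = sorted(prop.genes)
    N = len(genes)
    if spec.set_size > N:
        raise ValueError("set_size exceeds corpus size")
    w = _planted_weights(genes, prop, spec, N)
    p = w / w.sum()
    chosen_idx = rng.choice(N, size=spec.set_size, replace=False, p=p)
    chosen = [genes[i] for i in sorted(chosen_idx)]

    raw = rng.zipf(spec.degree_exponent, size=spec.n_mirnas)
    degrees = np.minimum(np.minimum(raw, spec.max_degree), spec.set_size)
    mirnas = [f"hsa-miR-{name}-{i + 1}" for i in range(spec.n_mirnas)]

    iset = InteractionSet(name=name)
    targeted: set[str] = set()
    for m, d in zip(mirnas, degrees):
        picks = rng.choice(spec.set_size, size=int(d), replace=False)
        for gi in picks:
            g = chosen[gi]
            ev = evidence_pool[rng.choice(len(evidence_pool), p=np.asarray(evidence_probs))]
            iset.add(Interaction(m, g, source, ev))
            targeted.add(g)
    for g in chosen:  # guarantee full coverage of the sampled gene set
        if g not in targeted:
            m = mirnas[int(rng.integers(spec.n_mirnas))]
            ev = evidence_pool[rng.choice(len(evidence_pool), p=np.asarray(evidence_probs))]
            iset.add(Interaction(m, g, source, ev))

    planted_genes = set()
    for term in spec.planted_terms:
        planted_genes |= prop.term_genes(term)
    truth = {
        "sampled_genes": chosen,
        "planted_terms": dict(spec.planted_terms),
        "planted_flags": {g: g in planted_genes for g in chosen},
        "degrees": {m: int(d) for m, d in zip(mirnas, degrees)},
    }
    return iset, truth


def make_scores(
    spec: SyntheticSpec, genes: list[str] | None = None
) -> tuple[np.ndarray, list[ScoredPrediction]]:
    """Draw validated scores and labelled predictions from the score model.

    Returns the validated-score sample (valid component only) and
    ``n_predicted`` predictions whose class ("valid"/"background") is drawn
    from ``prior_valid`` and recorded on the label field.
    """
    rng = spec.rng("scores")
    validated = rng.normal(spec.valid_mean, spec.valid_sd, size=spec.n_validated)
    is_valid = rng.random(spec.n_predicted) < spec.prior_valid
    scores = np.where(
        is_valid,
        rng.normal(spec.valid_mean, spec.valid_sd, size=spec.n_predicted),
        rng.normal(spec.bg_mean, spec.bg_sd, size=spec.n_predicted),
    )
    pool = genes or [f"PG{i + 1:06d}" for i in range(spec.n_predicted)]
    preds = [
        ScoredPrediction(
            mirna=f"hsa-miR-p{i + 1}",
            gene=pool[i % len(pool)],
            score=float(scores[i]),
            label="valid" if is_valid[i] else "background",
        )
        for i in range(spec.n_predicted)
    ]
    return validated, preds


def simulate(
    preset: str = "desk",
    seed: int = 0,
    out_dir=None,
    n_planted_branches: int = 3,
    fold: float = 3.0,
    **overrides,
):
    """Generate a complete synthetic study and optionally write its files.

    Builds the ontology and corpus, plants ``n_planted_branches`` disjoint
    top-level branches at the given fold, samples two empirical interaction
    sets (strong-evidence and direct dialects), and a predicted table whose
    pairs include the empirical pairs (scored from the valid component) plus
    background predictions.  When ``out_dir`` is given, writes
    ``ontology.obo``, ``annotations.tsv``, ``empirical_a.tsv``,
    ``empirical_b.tsv``, ``predicted.tsv`` and ``truth.json``.

    Returns a dict with all in-memory objects and the truth record.
    """
    base = {"desk": DESK, "genome": GENOME_SCALE}[preset].copy()
    base.update(overrides)
    spec = SyntheticSpec(seed=seed, **base)

    ontology = make_ontology(spec)
    corpus, corpus_truth = make_corpus(ontology, spec)
    prop = propagate(ontology, corpus)
    if not spec.planted_terms and n_planted_branches:
        branches = pick_branch_roots(ontology, prop, n_planted_branches)
        spec.planted_terms = {t: fold for t in branches}

    emp_a, truth_a = make_interactions(
        ontology, prop, spec, source=Source.EMPIRICAL_A, name="empA", stage_offset=0
    )
    emp_b, truth_b = make_interactions(
        ontology,
        prop,
        spec,
        source=Source.EMPIRICAL_B,
        evidence_pool=("direct",),
        evidence_probs=(1.0,),
        name="empB",
        stage_offset=10,
    )

    rng = spec.rng("scores")
    emp_pairs = sorted(emp_a.pairs | emp_b.pairs)
    predictions: list[ScoredPrediction] = []
    for m, g in emp_pairs:  # validated pairs also appear among predictions
        predictions.append(
            ScoredPrediction(m, g, float(rng.normal(spec.valid_mean, spec.valid_sd)), label="valid")
        )
    all_genes = sorted(prop.genes)
    n_bg = spec.n_predicted
    bg_genes = rng.choice(len(all_genes), size=n_bg, replace=True)
    for i in range(n_bg):
        predictions.append(
            ScoredPrediction(
                mirna=f"hsa-miR-bg{i + 1}",
                gene=all_genes[int(bg_genes[i])],
                score=float(rng.normal(spec.bg_mean, spec.bg_sd)),
                label="background",
            )
        )

    truth = {
        "seed": seed,
        "preset": preset,
        "spec": {k: v for k, v in asdict(spec).items() if k != "planted_terms"},
        "planted_terms": dict(spec.planted_terms),
        "corpus": corpus_truth,
        "empirical_a": truth_a,
        "empirical_b": truth_b,
    }
    out = {
        "spec": spec,
        "ontology": ontology,
        "corpus": corpus,
        "propagated": prop,
        "empirical_a": emp_a,
        "empirical_b": emp_b,
        "predictions": predictions,
        "truth": truth,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_obo(ontology, out_dir / "ontology.obo")
        write_annotations(corpus, out_dir / "annotations.tsv")
        _write_empirical(emp_a, out_dir / "empirical_a.tsv")
        _write_empirical(emp_b, out_dir / "empirical_b.tsv")
        write_predictions(predictions, out_dir / "predicted.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=str)
    return out


def _write_empirical(iset: InteractionSet, path) -> None:
    """Write the empirical dialect (one row per evidence record)."""
    import pandas as pd

    rows = []
    for rec in sorted(iset, key=lambda r: (r.mirna, r.gene)):
        evs = rec.evidence or [""]
        for ev in evs:
            rows.append({"mirna": rec.mirna, "gene": rec.gene, "evidence": ev})
    pd.DataFrame(rows, columns=["mirna", "gene", "evidence"]).to_csv(
        path, sep="\t", index=False
    )
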
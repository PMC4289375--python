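# Methods

This note documents the models and procedures implemented in `mirgo`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Interaction integration

Interactions are distinct (miRNA, gene) pairs.  Gene symbols are treated
as opaque identifiers normalized by trimming and upper-casing; no
nomenclature service is consulted (an optional user-supplied alias map can
be passed to the readers for symbol reconciliation).  "Strong experimental
evidence" is a configurable whitelist, by default `{reporter assay,
western blot}` for the strong-evidence dialect and `{direct}` for
direct-interaction exports.  Union keeps one record per pair and merges
provenance.  Venn accounting tabulates the seven disjoint regions of three
sets by gene, miRNA or pair.

The degree split partitions the miRNA universe into a high-degree set A
and the remainder B.  Two readings are supported because both are
defensible: `degree` mode (default) puts every miRNA with at least
`threshold` (default 6) distinct targets into A, so B is "fewer than six
targets"; `cover_fraction` mode takes miRNAs in decreasing degree order
until A's targets cover a given fraction (default 75%) of the gene
universe.  Ties at the threshold go to A.

## Posterior score filter

The filter realizes the rule "keep a prediction only if its probability of
being a valid interaction exceeds 0.98" with an explicitly documented
density model, since only the rule — not the original density estimator —
is specified for this analysis.  The default (`family="gaussian"`) fits:

- the valid component N(μ_v, σ_v²) by maximum likelihood on the scores of
  empirically validated interactions;
- the background component N(μ_b, σ_b²) and the mixing weight π by
  expectation–maximisation on the predicted-score population with the
  valid component held fixed.  This constrained EM is written in-house
  because off-the-shelf mixture fitters cannot freeze one component at the
  externally calibrated density.  Initialisation: background at the median
  and scaled MAD of the predicted scores, π = 0.2; convergence on relative
  log-likelihood change < 1e-10, at most 500 iterations.

`family="gaussian_mixture"` instead fits an unconstrained two-component
Gaussian mixture (scikit-learn, 3 restarts, fixed random state) to the
pooled predicted scores, for the case where no clean validated sample
exists; the component whose mean is closer to the validated mean is
labelled valid.

π can be overridden by the user; the threshold (default 0.98) is a
configuration value.  When the fitted components are nearly identical
(mean separation below 0.1 pooled standard deviations) the model is
flagged non-identifiable and a warning is raised — posteriors are then
uninformative and filtering should not be trusted.  Validated pairs found
among the predictions are excluded from the background sample before
fitting to avoid contaminating the background density.  Degenerate input
(all scores identical) is an error; non-finite scores are dropped and
counted.

## Ontology and annotation propagation

OBO parsing is delegated to `obonet`; the DAG lives in a networkx
multigraph with child→parent edges typed `is_a`, `part_of`, `regulates`.
Obsolete terms are dropped, unknown relationship types ignored with a
warning, and a cycle is a hard error naming the offending terms.

Annotations propagate to ancestors along `is_a` and `part_of` only
(standard true-path practice); `regulates` edges are retained for display
but never propagate, because regulation of a process does not imply
membership in it.  Propagation closes each gene's term set under ancestor
traversal (single topological pass, deduplicated across multiple paths)
and is idempotent.

The background for each namespace is the set of genes with at least one
propagated annotation in that namespace (equivalently, the root term's
propagated gene set).  Per-namespace backgrounds make expected counts
well-defined when the corpus covers several namespaces with different
annotation depth.

## Over-representation analysis

One-sided hypergeometric tail per term (equal to the one-sided Fisher
exact p of the 2×2 table), computed by `scipy.stats.hypergeom`; the test
suite verifies agreement with exhaustive exact-rational enumeration to
1e-12 for every margin combination with N ≤ 60.  The Bonferroni factor m
is the number of terms actually tested in the namespace (background count
≥ `min_term_size`, default 1) — the defensible default when the original
tool's m is unknown; m is reported in the run metadata.  The query size n
counts annotated members only; unannotated query genes are tallied
separately.  Direction `over` is the default; `under` and `both` are
available, and −log₁₀ values are reported on the adjusted p (raw p is also
emitted).

Significant terms (p_adj ≤ t_p; default t_p = 1e-5 for main runs, 0.05 for
null controls) induce a sub-DAG whose edges connect each significant term
to its nearest significant ancestors (transitive reduction of the ancestry
relation restricted to significant terms), so every significant ancestor
is reachable.  Leaves — significant terms with no significant descendant —
mark the most specific findings.  DOT export labels each node with name,
observed, expected and −log₁₀ p; leaves are drawn blue and functional
areas filled yellow.

## Functional abstraction

The published abstraction algorithm behind "functional areas" is cited but
not specified in the source analysis; `mirgo` implements a documented
greedy stand-in engineered for the four stated desiderata:

- **certainty** — candidates are significant terms only;
- **information value** — candidates need −log₂(K/N) ≥ 1 bit; the score
  multiplies by information value;
- **coverage** — the score's other factor is the term's share of the
  query set, and a candidate is only selected while its *marginal* gene
  coverage gain is ≥ 2% of the query set;
- **conciseness** — no selected term may be an ancestor or descendant of
  another; at most 25 areas.

Ties break toward higher information value, then lexicographically
smaller term id, making selection deterministic.  All four per-area
quantities are reported so alternative selectors can be compared.  The
defaults (2% gain, 25 areas, 1 bit) give area counts comparable to a
published-scale result (≈17 areas from ≈156 significant terms) while
remaining configurable.

## Validation procedures

**Null control.** Gene sets are sampled uniformly *without replacement*
from the pooled annotated background (the analysis this mirrors does not
state the sampling scheme; without replacement is assumed) and run through
ORA at α with Bonferroni.  Because the one-sided hypergeometric p-values
are valid and discrete, the empirical family-wise error rate is expected
at or below α.  Seeds are explicit and recorded in every report.

**Degree-split concordance.** ORA plus abstraction run on the full target
gene set and on each split side's targets; the report gives the area sets,
both asymmetric differences, and per-run median certainty.  Medians are
the lower median (for even counts) of the −log₁₀ adjusted p over the run's
selected areas.  Swapping the A/B labels swaps the report fields exactly.

## Synthetic data

The generator reproduces the statistical regime of the real inputs with
known ground truth; everything is bit-for-bit reproducible from (spec,
seed), with a deterministic sub-stream per stage.

- **Ontology**: layered DAG per namespace, one root each; every non-root
  term has an `is_a` parent in the previous layer and, with probability
  0.3, a second parent in an earlier layer of the *same top-level branch*
  (25% of these `part_of`).  Keeping multi-parent edges within a branch
  makes the root's children gene-disjoint, which is what lets planted
  branch structure be recovered exactly; occasional `regulates` links may
  cross branches but never propagate.
- **Corpus**: each term gets a Zipf weight (exponent 1 by default, so term
  sizes span orders of magnitude).  A gene picks a home branch
  (∝ branch weight mass) and draws its 1 + Poisson(3) direct annotations
  within it (∝ term weight).  The marginal per-term frequency is exactly
  the power law; co-annotations of one gene stay thematically close, as
  real GO annotations do.  The cost of this realism is cluster noise: term
  counts are resolvable against the target law only with enough draws per
  term, which the law-recovery test accounts for by using a configuration
  with few terms and many genes.
- **Interactions**: target genes are drawn without replacement with
  weights calibrated so each planted term's *realized* observed/expected
  ratio equals its requested fold, jointly across all planted terms
  (exact for disjoint planted gene sets; requires Σ fold·K < N, otherwise
  folds are scaled down with a warning).  miRNA out-degrees follow a
  truncated Zipf law (exponent 2, cap 229) — a few hub miRNAs with
  hundreds of targets, many with one — and every sampled gene receives at
  least one miRNA.
- **Scores**: valid N(−0.40, 0.10²) and background N(−0.05, 0.05²) with
  π = 0.2 by default, class labels retained.  In the full `simulate`
  bundle, the empirical pairs reappear among the predictions with
  valid-component scores (they are the calibration sample) plus 10,000
  background predictions over random corpus genes.

Presets: `desk` (500 terms, depth 6, 2,000 genes, 300-gene interaction
sets, 150 miRNAs) runs the full pipeline in seconds; `genome` scales the
corpus to 17,794 genes, 2,954-gene sets and 788 miRNAs.  The default desk
scenario plants three disjoint top-level branches — each holding 4–15% of
the corpus — at fold 3, the strongest integer fold that is jointly
realizable for three such branches (joint realizability requires
Σ fold·K < N).

What the generator does **not** emulate: sequence-level structure (no
seed sites or UTRs), evidence-code semantics, inter-gene annotation
correlations beyond the home-branch mechanism, and real GO's scale-free
term topology.  Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure under the
stated regime — not fidelity to any particular database snapshot, whose
headline counts depend on curation state and are out of scope here.

## Numerical conventions and edge cases

- Percentages and ratios in reports are rounded half-up (one decimal for
  fractions/ratios, nearest integer for the miRNA share), via decimal
  arithmetic, matching the arithmetic of the published-style tables.
- −log₁₀ p is clamped at the smallest positive double to avoid infinities.
- `p_adj = min(1, m·p_raw)`; an observed count of 0 gives p = 1 for
  over-representation.
- Empty significant DAGs export an empty DOT graph with a warning; an
  empty query-background intersection is an error.
- Reruns with the same config and seed produce byte-identical TSV/JSON
  outputs.

## Problem sizes used in the checks

The automated checks run at desk scale: exact-tail verification over all
margins with N ≤ 60; 100 null-control repeats of 300 genes against the
2,000-gene desk corpus; planted-term recovery on a 10,000-gene corpus
(term of ≈500 genes, fold 5, 300-gene sets) over 10 seeds; three-branch
area recovery on 10 desk corpora; score-model recovery at 10,000
predictions over 10 seeds.  These sizes were chosen to give each check
statistical resolution while keeping a full run in the minutes range.

## Known limitations

- The greedy area selector is a stand-in for an unpublished algorithm;
  different selectors can produce different (equally defensible) area
  sets, which is why all four selection quantities are reported per area.
- In the planted-term scenario, a large descendant sharing most of the
  planted term's genes can occasionally attain a marginally smaller
  p-value than the planted term itself — a consequence of true-path
  propagation, visible in the recovery rates.
- The Gaussian families are a modelling choice; heavy-tailed score
  distributions would need a different family, though the posterior rule
  itself is family-agnostic.
- Bonferroni with m = tested terms is conservative under the strong
  positive dependence of nested GO terms.
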
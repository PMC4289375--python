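# mirgo — what do miRNA-regulated genes do?

`mirgo` is a reusable, offline pipeline for the genomics question "what are
the biological roles of the genes regulated by miRNAs?".  It integrates
evidence-based and computationally predicted miRNA–gene interaction sets,
filters raw target-prediction scores through a Bayesian posterior rule,
runs Gene Ontology (GO) over-representation analysis on the resulting gene
set, condenses the significant-term DAG into a concise set of *functional
areas*, and provides the two validity checks such an analysis needs: a
random-gene-set null control and a miRNA degree-split robustness check.
A synthetic-data module generates every input with known ground truth, so
the entire pipeline is testable without touching any live database.

## The statistics at the core

**Posterior score filter.** Predicted interactions carry a context score
*s* (more negative = stronger predicted repression).  Scores are modelled
as a two-component mixture with a *valid* density f_v (calibrated on scores
of empirically validated interactions) and a *background* density f_b, with
mixing weight π.  A prediction is kept when

    P(valid | s) = π f_v(s) / (π f_v(s) + (1 − π) f_b(s)) > 0.98.

**Over-representation.** For a query set of n annotated genes against a
background of N annotated genes, a term with K background genes and k
query genes is scored with the one-sided hypergeometric tail

    p = P(X ≥ k),  X ~ Hypergeom(N, K, n),

equivalent to the one-sided Fisher exact test, and Bonferroni-adjusted by
the number m of tested terms.  Terms with adjusted p ≤ t_p (default
1·10⁻⁵) form the significant sub-DAG; its *leaves* (no significant
descendant) are the most specific findings.  Annotations obey the
true-path rule: a gene annotated to a term counts at every ancestor
reachable via `is_a`/`part_of` edges.

**Functional abstraction.** The significant DAG is summarized by greedily
selecting terms maximizing coverage × information value (−log₂ K/N),
excluding ancestors/descendants of already selected terms, until the
marginal coverage gain drops below a floor.  Each area reports coverage,
certainty (−log₁₀ adjusted p), information value and an optional topic
label.

## Worked example

Generate a desk-scale synthetic study (500-term ontology, 2,000 annotated
genes, three top-level branches planted at 3-fold enrichment, heavy-tailed
miRNA degrees, two-component prediction scores) and run the full pipeline:

```sh
mirgo simulate --preset desk --seed 7 --out-dir data
mirgo report --config run.toml     # paths to the files written above
```

With seed 7 the summary reports a merged set of 1,383 interactions over
510 genes and 298 miRNAs; the score filter keeps 1,267 of 11,397
predictions (1,988 → 500 distinct genes) at threshold 0.98; ORA tests
m = 496 terms against the N = 2,000-gene background and finds 35
significant terms; and functional abstraction condenses them into exactly
the three planted branches:

```
term        observed  fraction%  coverage  info value  certainty
GO:0000021  121       23.7       0.237     3.44        30.5
GO:0000024   95       18.6       0.186     3.87        25.7
GO:0000012   94       18.4       0.184     3.81        22.6
```

`observed` is the number of query genes under the term, `fraction%` their
share of the annotated query set, `coverage` the fraction of the query set
the area summarizes, and `certainty` the −log₁₀ Bonferroni-adjusted
p-value.  The truth file written by `simulate` confirms these are the
planted terms.

The validity checks are available both inside `report` (config flags) and
standalone:

```sh
mirgo null-check --gaf data/annotations.tsv --obo data/ontology.obo \
    --set-size 300 --repeats 10 --alpha 0.05 --seed 0
mirgo split-check --interactions out/merged_interactions.tsv \
    --gaf data/annotations.tsv --obo data/ontology.obo --threshold 6
```

## Layout

- `mirgo.interactions` — interaction-table dialects, union/Venn accounting,
  degree split
- `mirgo.prediction_filter` — score model and posterior filter
- `mirgo.ontology` — OBO parsing, true-path propagation
- `mirgo.ora` — exact tests, Bonferroni, significant sub-DAG, DOT export
- `mirgo.abstraction` — functional-area selection, topic labels
- `mirgo.validation` — null control, degree-split concordance
- `mirgo.synthetic` — ground-truth generators for every input
- `mirgo.pipeline` / `mirgo.cli` — orchestration and the `mirgo` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
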
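"""Validity checks for the enrichment pipeline.

Two procedures:

* **Random-gene-set null control** — gene sets drawn uniformly without
  replacement from the annotated background are run through ORA at a given
  alpha with Bonferroni correction; under the complete null essentially no
  repeat should yield a significant term, so the family-wise error rate is
  verified empirically.

* **Degree-split concordance** — the miRNA universe is partitioned into a
  small high-degree set A and a large low-degree set B; ORA plus functional
  abstraction is run on the full target gene set and on each side's targets,
  and the resulting functional-area sets are compared.  Robust results mean
  set A (and largely set B) reproduce the full analysis' areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mirgo.abstraction import AbstractionParams, select_functional_areas
from mirgo.interactions import DegreeSplit, InteractionSet
from mirgo.ontology import AnnotationTable, OntologyGraph
from mirgo.ora import ORAConfig, run_ora

__all__ = [
    "NullControlReport",
    "SplitConcordance",
    "null_control",
    "split_concordance",
]


@dataclass
class NullControlReport:
    """Outcome of the repeated random-gene-set experiment."""

    repeats: int
    set_size: int
    alpha: float
    seed: int
    significant_term_counts: list[int] = field(default_factory=list)
    runs_with_zero: int = 0

    @property
    def fraction_with_any(self) -> float:
        """Empirical family-wise error rate across repeats."""
        return 1.0 - self.runs_with_zero / self.repeats

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "set_size": self.set_size,
            "alpha": self.alpha,
            "seed": self.seed,
            "significant_term_counts": self.significant_term_counts,
            "runs_with_zero": self.runs_with_zero,
            "fraction_with_any": self.fraction_with_any,
        }


@dataclass
class SplitConcordance:
    """Functional-area agreement between a degree split and the full set."""

    areas_full: set[str]
    areas_a: set[str]
    areas_b: set[str]
    missing_in_a: set[str]
    missing_in_b: set[str]
    extra_in_a: set[str]
    extra_in_b: set[str]
    median_minus_log10_p_full: float
    median_minus_log10_p_a: float
    median_minus_log10_p_b: float

    def swapped(self) -> "SplitConcordance":
        """The same report with the A/B labels exchanged."""
        return SplitConcordance(
            areas_full=self.areas_full,
            areas_a=self.areas_b,
            areas_b=self.areas_a,
            missing_in_a=self.missing_in_b,
            missing_in_b=self.missing_in_a,
            extra_in_a=self.extra_in_b,
            extra_in_b=self.extra_in_a,
            median_minus_log10_p_full=self.median_minus_log10_p_full,
            median_minus_log10_p_a=self.median_minus_log10_p_b,
            median_minus_log10_p_b=self.median_minus_log10_p_a,
        )

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = sorted(v) if isinstance(v, set) else v
        return d


def null_control(
    annotations: AnnotationTable,
    ontology: OntologyGraph,
    set_size: int,
    repeats: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    correction: str = "bonferroni",
) -> NullControlReport:
    """Repeatedly test uniformly drawn gene sets for spurious enrichment.

    Each repeat samples ``set_size`` genes without replacement from the
    pooled annotated background and runs ORA at ``alpha`` with the given
    correction, recording the number of significant terms.
    """
    background = sorted(
        set().union(
            *(annotations.background(ontology, ns) for ns in ontology.namespaces)
        )
    )
    if set_size > len(background):
        raise ValueError(
            f"set_size {set_size} exceeds annotated background {len(background)}"
        )
    rng = np.random.default_rng(seed)
    config = ORAConfig(p_threshold=alpha, correction=correction, direction="over")
    report = NullControlReport(
        repeats=repeats, set_size=set_size, alpha=alpha, seed=seed
    )
    for _ in range(repeats):
        sample = rng.choice(background, size=set_size, replace=False)
        result = run_ora(sample, annotations, ontology, config)
        count = len(result.significant())
        report.significant_term_counts.append(count)
        if count == 0:
            report.runs_with_zero += 1
    return report


def _lower_median(values) -> float:
    """Median; the lower of the two middle values for even counts."""
    v = sorted(values)
    if not v:
        return float("nan")
    return float(v[(len(v) - 1) // 2])


def _areas_for(gene_set, annotations, ontology, config, params):
    result = run_ora(gene_set, annotations, ontology, config)
    terms: set[str] = set()
    certainties: list[float] = []
    for ns, dag in result.dags.items():
        for area in select_functional_areas(dag, ontology, params):
            terms.add(area.term)
            certainties.append(area.certainty)
    return terms, _lower_median(certainties)


def split_concordance(
    interactions: InteractionSet,
    split: DegreeSplit,
    annotations: AnnotationTable,
    ontology: OntologyGraph,
    config: ORAConfig | None = None,
    abstraction_params: AbstractionParams | None = None,
) -> SplitConcordance:
    """Compare functional areas of the full gene set vs each split side.

    Median summaries are the lower median of the -log10 adjusted p-values
    over each run's selected functional areas.
    """
    if config is None:
        config = ORAConfig()
    if abstraction_params is None:
        abstraction_params = AbstractionParams()
    universe = interactions.mirnas()
    if split.set_a | split.set_b != universe or (split.set_a & split.set_b):
        raise ValueError("split does not partition the interaction set's miRNAs")
    genes_full = interactions.genes()
    genes_a = interactions.targets_of(split.set_a)
    genes_b = interactions.targets_of(split.set_b)
    if not genes_a or not genes_b:
        raise ValueError("one side of the split has an empty target gene set")

    areas_full, med_full = _areas_for(
        genes_full, annotations, ontology, config, abstraction_params
    )
    areas_a, med_a = _areas_for(genes_a, annotations, ontology, config, abstraction_params)
    areas_b, med_b = _areas_for(genes_b, annotations, ontology, config, abstraction_params)

    return SplitConcordance(
        areas_full=areas_full,
        areas_a=areas_a,
        areas_b=areas_b,
        missing_in_a=areas_full - areas_a,
        missing_in_b=areas_full - areas_b,
        extra_in_a=areas_a - areas_full,
        extra_in_b=areas_b - areas_full,
        median_minus_log10_p_full=med_full,
        median_minus_log10_p_a=med_a,
        median_minus_log10_p_b=med_b,
    )
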
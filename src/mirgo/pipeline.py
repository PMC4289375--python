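"""End-to-end orchestration: merge, filter, ORA, abstraction, validation.

:func:`run_pipeline` drives the whole analysis from a single
:class:`RunConfig` and writes a report bundle — Venn accounting, filtered
prediction report, per-namespace enrichment tables, the functional-area
table, DOT renderings of the significant sub-DAGs, and a summary JSON with
source composition percentages and any requested term-count ratios (e.g.
nucleus vs cytoplasm observed counts).  Re-running with the same config and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from mirgo.abstraction import (
    AbstractionParams,
    apply_topic_map,
    areas_frame,
    select_functional_areas,
)
from mirgo.interactions import (
    DIRECT_EVIDENCE,
    STRONG_EVIDENCE,
    Source,
    degree_split,
    read_interaction_table,
    union_sets,
    venn_counts,
    write_interaction_table,
)
from mirgo.ontology import parse_obo, propagate, read_annotations
from mirgo.ora import ORAConfig, export_dag, run_ora
from mirgo.prediction_filter import ScoreModel, filter_predictions, read_predictions
from mirgo.validation import null_control, split_concordance

__all__ = ["RunConfig", "run_pipeline", "fraction_percent", "observed_ratio"]

log = logging.getLogger("mirgo.pipeline")


def fraction_percent(observed: int, set_size: int) -> float:
    """Percent share 100*observed/set_size, rounded half-up to one decimal."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if observed > set_size:
        raise ValueError(f"observed {observed} exceeds set size {set_size}")
    value = Decimal(100 * observed) / Decimal(set_size)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def observed_ratio(a: int, b: int, decimals: int = 1) -> float:
    """Ratio of two observed counts, rounded half-up."""
    if b <= 0:
        raise ValueError("denominator count must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(a) / Decimal(b)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """All inputs and knobs of one pipeline run.

    File paths are the TSV/OBO inputs; thresholds default to the main
    analysis settings (posterior filter 0.98, ORA t_p 1e-5 with Bonferroni,
    null-control alpha 0.05).
    """

    empirical_a: list = field(default_factory=list)
    empirical_b: list = field(default_factory=list)
    predicted: str | None = None
    obo: str = ""
    annotations: str = ""
    out_dir: str = "mirgo_out"
    evidence_whitelist_a: tuple = tuple(sorted(STRONG_EVIDENCE))
    evidence_whitelist_b: tuple = tuple(sorted(DIRECT_EVIDENCE))
    filter_threshold: float = 0.98
    score_family: str = "gaussian"
    p_threshold: float = 1.0e-5
    correction: str = "bonferroni"
    min_term_size: int = 1
    min_coverage_gain: float = 0.02
    max_areas: int = 25
    min_information_value: float = 1.0
    topics: dict = field(default_factory=dict)
    ratio_terms: list = field(default_factory=list)  # [[term_over, term_under], ...]
    run_null_control: bool = False
    null_set_size: int = 3000
    null_repeats: int = 10
    null_alpha: float = 0.05
    run_split_check: bool = False
    split_threshold: int = 6
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a TOML config; keys mirror the dataclass fields."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run merge -> filter -> ORA -> abstraction (-> validation); write bundle.

    Returns the summary dict (also written to ``summary.json``).  Any stage
    failure raises with the stage name prefixed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> dict:
    stage = "read-inputs"
    try:
        _stage(stage)
        sets = []
        for path in config.empirical_a:
            sets.append(
                read_interaction_table(
                    path,
                    dialect="empirical",
                    evidence_filter=set(config.evidence_whitelist_a),
                    source=Source.EMPIRICAL_A,
                    name="empirical_a",
                )
            )
        for path in config.empirical_b:
            sets.append(
                read_interaction_table(
                    path,
                    dialect="empirical",
                    evidence_filter=set(config.evidence_whitelist_b),
                    source=Source.EMPIRICAL_B,
                    name="empirical_b",
                )
            )
        if not sets:
            raise ValueError("no empirical input tables configured")
        empirical = union_sets(sets, name="empirical")
        ontology = parse_obo(config.obo)
        annotations = propagate(ontology, read_annotations(config.annotations))
        for s in sets + [empirical]:
            log.info("interactions %s: %s", s.name, s.summary())

        stage = "filter-predictions"
        _stage(stage)
        predicted_kept = None
        filter_report = None
        if config.predicted:
            predictions = read_predictions(config.predicted)
            emp_pairs = empirical.pairs
            validated_scores = [
                p.score for p in predictions if (p.mirna, p.gene) in emp_pairs
            ]
            background_pool = [
                p.score for p in predictions if (p.mirna, p.gene) not in emp_pairs
            ]
            model = ScoreModel(
                family=config.score_family, threshold=config.filter_threshold
            )
            model.fit(validated_scores, background_pool)
            predicted_kept, filter_report = filter_predictions(predictions, model)
            model.save(out_dir / "score_model.json")
            with open(out_dir / "filter_report.json", "w") as fh:
                json.dump(filter_report.to_dict(), fh, indent=2)
            log.info("filter: %s", filter_report.to_dict())

        stage = "merge"
        _stage(stage)
        all_sets = sets + ([predicted_kept] if predicted_kept else [])
        merged = union_sets(all_sets, name="merged")
        write_interaction_table(merged, out_dir / "merged_interactions.tsv")
        venn = None
        emp_a_all = union_sets(
            [s for s in sets if "empirical_a" in s.name] or [empirical], name="A"
        )
        emp_b_all = union_sets(
            [s for s in sets if "empirical_b" in s.name] or [empirical], name="B"
        )
        if predicted_kept is not None:
            venn = {
                by: venn_counts([emp_a_all, emp_b_all, predicted_kept], by=by)
                for by in ("gene", "mirna", "pair")
            }
            with open(out_dir / "venn.json", "w") as fh:
                json.dump(venn, fh, indent=2)

        stage = "ora"
        _stage(stage)
        gene_set = merged.genes()
        ora_config = ORAConfig(
            p_threshold=config.p_threshold,
            correction=config.correction,
            min_term_size=config.min_term_size,
        )
        result = run_ora(gene_set, annotations, ontology, ora_config)

        stage = "abstraction"
        _stage(stage)
        params = AbstractionParams(
            min_coverage_gain=config.min_coverage_gain,
            max_areas=config.max_areas,
            min_information_value=config.min_information_value,
        )
        all_areas = []
        for ns in sorted(result.dags):
            areas = select_functional_areas(result.dags[ns], ontology, params)
            all_areas.extend(areas)
        apply_topic_map(all_areas, config.topics)
        areas_frame(all_areas).to_csv(out_dir / "areas.tsv", sep="\t", index=False)

        stage = "write-tables"
        _stage(stage)
        import pandas as pd

        for ns in sorted(result.dags):
            rows = [
                {
                    "term_id": r.term,
                    "term_name": r.name,
                    "namespace": r.namespace,
                    "observed": r.observed,
                    "expected": round(r.expected, 4),
                    "fraction_percent": fraction_percent(r.observed, r.n),
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "minus_log10_p_adj": round(r.minus_log10_p_adj, 4),
                    "direction": r.direction,
                    "is_leaf": r.is_leaf,
                    "is_functional_area": r.is_functional_area,
                }
                for r in result.records
                if r.namespace == ns
            ]
            pd.DataFrame(rows).sort_values(["p_adj", "term_id"]).to_csv(
                out_dir / f"enrichment_{ns}.tsv", sep="\t", index=False
            )
            with open(out_dir / f"dag_{ns}.dot", "w") as fh:
                fh.write(export_dag(result.dags[ns]))

        stage = "validation"
        null_report = None
        split_report = None
        if config.run_null_control:
            _stage("null-control")
            set_size = min(
                config.null_set_size,
                max(len(b) for b in (annotations.background(ontology, ns) for ns in ontology.namespaces)),
            )
            null_report = null_control(
                annotations,
                ontology,
                set_size=set_size,
                repeats=config.null_repeats,
                alpha=config.null_alpha,
                seed=config.seed,
            )
            with open(out_dir / "null_control.json", "w") as fh:
                json.dump(null_report.to_dict(), fh, indent=2)
        if config.run_split_check:
            _stage("split-check")
            split = degree_split(merged, threshold=config.split_threshold)
            split_report = split_concordance(
                merged, split, annotations, ontology, ora_config, params
            )
            with open(out_dir / "split_concordance.json", "w") as fh:
                json.dump(split_report.to_dict(), fh, indent=2)

        stage = "summary"
        _stage(stage)
        summary = _summary(
            config, sets, predicted_kept, merged, venn, filter_report, result, all_areas,
            null_report, split_report,
        )
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _summary(
    config, sets, predicted_kept, merged, venn, filter_report, result, areas,
    null_report, split_report,
) -> dict:
    union_genes = merged.genes()
    sources: dict[str, dict] = {}
    by_source: dict[str, set] = {}
    for s in sets:
        by_source.setdefault(s.name, set()).update(s.genes())
    if predicted_kept is not None:
        by_source["predicted"] = predicted_kept.genes()
    for name, genes in by_source.items():
        others = set().union(*(g for n, g in by_source.items() if n != name)) if len(by_source) > 1 else set()
        exclusive = genes - others
        sources[name] = {
            "genes": len(genes),
            "genes_exclusive": len(exclusive),
            "percent_of_union": fraction_percent(len(genes & union_genes), len(union_genes)),
            "percent_exclusive_of_union": fraction_percent(len(exclusive & union_genes), len(union_genes)),
        }

    ratios = {}
    sig_by_term = {r.term: r for r in result.records if r.significant}
    all_by_term = {}
    for r in result.records:
        all_by_term.setdefault(r.term, r)
    for pair in config.ratio_terms:
        t_over, t_under = pair
        r1 = sig_by_term.get(t_over) or all_by_term.get(t_over)
        r2 = sig_by_term.get(t_under) or all_by_term.get(t_under)
        if r1 and r2 and r2.observed > 0:
            ratios[f"{t_over}/{t_under}"] = {
                "observed_over": r1.observed,
                "observed_under": r2.observed,
                "ratio": observed_ratio(r1.observed, r2.observed),
            }

    summary = {
        "seed": config.seed,
        "union": merged.summary(),
        "sources": sources,
        "venn": venn,
        "filter": filter_report.to_dict() if filter_report else None,
        "ora": {
            "meta": result.meta,
            "n_unannotated": result.n_unannotated,
            "n_significant": len({r.term for r in result.records if r.significant}),
        },
        "functional_areas": [
            {
                "term": a.term,
                "name": a.name,
                "namespace": a.namespace,
                "observed": a.observed,
                "fraction_percent": round(a.fraction_percent, 1),
                "coverage": round(a.coverage, 4),
                "information_value": round(a.information_value, 3),
                "certainty": round(a.certainty, 3),
                "topic": a.topic,
            }
            for a in areas
        ],
        "term_ratios": ratios,
        "null_control": null_report.to_dict() if null_report else None,
        "split_concordance": split_report.to_dict() if split_report else None,
    }
    return summary
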
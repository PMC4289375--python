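"""Reading, filtering and combining miRNA-gene interaction sets.

Two input dialects are supported.  The *empirical* dialect carries an
evidence label per row (mimicking strong-evidence exports of curated target
databases) and is filtered through an evidence whitelist; the *predicted*
dialect carries a real-valued context score per row (more negative = stronger
predicted repression).  Interactions are normalized (gene symbols trimmed and
upper-cased), deduplicated per (miRNA, gene) pair with provenance retained,
and combined by set union.  Venn accounting over three sets and the
high/low-degree miRNA split used for robustness checks live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "Source",
    "Interaction",
    "InteractionSet",
    "DegreeSplit",
    "FormatError",
    "read_interaction_table",
    "write_interaction_table",
    "union_sets",
    "venn_counts",
    "degree_split",
]

#: evidence labels accepted as "strong experimental evidence" by default
STRONG_EVIDENCE = frozenset({"reporter assay", "western blot"})
#: evidence whitelist for direct-interaction exports
DIRECT_EVIDENCE = frozenset({"direct"})


class FormatError(ValueError):
    """An input table is missing a mandatory column or is malformed."""


class Source(str, Enum):
    """Provenance of an interaction."""

    EMPIRICAL_A = "EMPIRICAL_A"
    EMPIRICAL_B = "EMPIRICAL_B"
    PREDICTED = "PREDICTED"


@dataclass(frozen=True)
class Interaction:
    """A single miRNA-gene interaction with provenance.

    Parameters
    ----------
    mirna : str
        miRNA identifier, e.g. ``"hsa-miR-34a"``.
    gene : str
        Gene symbol, normalized to trimmed upper case.
    source : Source
        Which input set the interaction came from.
    evidence : str
        Free-text evidence label, e.g. ``"reporter assay"``.
    """

    mirna: str
    gene: str
    source: Source
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.mirna or not self.gene:
            raise ValueError("mirna and gene identifiers must be non-empty")


@dataclass
class _PairRecord:
    """One distinct (miRNA, gene) pair with merged provenance."""

    mirna: str
    gene: str
    sources: set[str] = field(default_factory=set)
    evidence: list[str] = field(default_factory=list)
    n_records: int = 0


class InteractionSet:
    """A named set of distinct (miRNA, gene) pairs with per-pair provenance.

    Duplicate pairs are collapsed on insertion; their evidence labels and
    source tags accumulate on the single retained record.
    """

    def __init__(self, name: str = "", interactions=()) -> None:
        self.name = name
        self._pairs: dict[tuple[str, str], _PairRecord] = {}
        for ia in interactions:
            self.add(ia)

    def add(self, interaction: Interaction) -> None:
        key = (interaction.mirna, interaction.gene)
        rec = self._pairs.get(key)
        if rec is None:
            rec = _PairRecord(mirna=interaction.mirna, gene=interaction.gene)
            self._pairs[key] = rec
        rec.sources.add(str(interaction.source.value))
        if interaction.evidence:
            rec.evidence.append(interaction.evidence)
        rec.n_records += 1

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pairs

    def __iter__(self):
        return iter(self._pairs.values())

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def record(self, mirna: str, gene: str) -> _PairRecord:
        return self._pairs[(mirna, gene)]

    def genes(self) -> set[str]:
        return {g for (_, g) in self._pairs}

    def mirnas(self) -> set[str]:
        return {m for (m, _) in self._pairs}

    def degrees(self) -> dict[str, int]:
        """Number of distinct target genes per miRNA."""
        out: dict[str, int] = {}
        for m, _ in self._pairs:
            out[m] = out.get(m, 0) + 1
        return out

    def targets_of(self, mirnas) -> set[str]:
        wanted = set(mirnas)
        return {g for (m, g) in self._pairs if m in wanted}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": rec.mirna,
                "gene": rec.gene,
                "sources": ",".join(sorted(rec.sources)),
                "evidence": ";".join(rec.evidence),
            }
            for rec in sorted(self._pairs.values(), key=lambda r: (r.mirna, r.gene))
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "sources", "evidence"])

    def summary(self) -> dict:
        return {
            "name": self.name,
            "pairs": len(self),
            "genes": len(self.genes()),
            "mirnas": len(self.mirnas()),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = self.summary()
        return (
            f"InteractionSet(name={s['name']!r}, pairs={s['pairs']}, "
            f"genes={s['genes']}, mirnas={s['mirnas']})"
        )


@dataclass
class DegreeSplit:
    """Partition of the miRNA universe into high-degree (A) and low-degree (B).

    ``coverage_fraction`` is the fraction of the gene universe covered by set
    A's targets; ``share_a_percent`` is A's share of all miRNAs as the nearest
    integer percent.
    """

    set_a: set[str]
    set_b: set[str]
    threshold: int
    coverage_fraction: float
    share_a_percent: int


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["mirna"] = df["mirna"].astype(str).str.strip()
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    df = df[(df["mirna"] != "") & (df["gene"] != "")]
    return df


def read_interaction_table(
    path,
    dialect: str = "empirical",
    evidence_filter=None,
    source: Source = Source.EMPIRICAL_A,
    name: str | None = None,
    alias_map: dict[str, str] | None = None,
) -> InteractionSet:
    """Read a TSV interaction table into an :class:`InteractionSet`.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    dialect : {"empirical", "predicted", "merged"}
        ``empirical`` requires columns ``mirna, gene, evidence`` (``pmid``
        optional); ``predicted`` requires ``mirna, gene, context_score``;
        ``merged`` reads this module's own writer output back.
    evidence_filter : set of str, optional
        Keep only rows whose evidence label is in this set (empirical
        dialect).  ``None`` keeps everything.
    source : Source
        Provenance tag for the resulting interactions.
    alias_map : dict, optional
        Gene-symbol alias resolution applied after normalization.

    Raises
    ------
    FormatError
        If a mandatory column for the dialect is missing.
    """
    required = {
        "empirical": ["mirna", "gene", "evidence"],
        "predicted": ["mirna", "gene", "context_score"],
        "merged": ["mirna", "gene", "sources", "evidence"],
    }
    if dialect not in required:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required[dialect]:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    df = _normalize(df)
    if alias_map:
        df["gene"] = df["gene"].map(lambda g: alias_map.get(g, g))

    if name is None:
        name = str(path)
    out = InteractionSet(name=name)

    if dialect == "empirical":
        df["evidence"] = df["evidence"].astype(str).str.strip()
        if evidence_filter is not None:
            df = df[df["evidence"].isin(set(evidence_filter))]
        for row in df.itertuples(index=False):
            out.add(Interaction(row.mirna, row.gene, source, row.evidence))
    elif dialect == "predicted":
        for row in df.itertuples(index=False):
            out.add(
                Interaction(
                    row.mirna, row.gene, Source.PREDICTED, f"score={row.context_score}"
                )
            )
    else:  # merged
        for row in df.itertuples(index=False):
            srcs = [s for s in str(row.sources).split(",") if s]
            evs = [e for e in str(row.evidence).split(";") if e]
            if not srcs:
                srcs = [source.value]
            first = True
            for s in srcs:
                ev = ";".join(evs) if first else ""
                out.add(Interaction(row.mirna, row.gene, Source(s), ev))
                first = False

    if len(out) == 0:
        warnings.warn(f"no interactions left after filtering {path}", stacklevel=2)
    return out


def write_interaction_table(iset: InteractionSet, path) -> None:
    """Write an interaction set as TSV (``mirna, gene, sources, evidence``)."""
    iset.to_frame().to_csv(path, sep="\t", index=False)


def union_sets(sets: list[InteractionSet], name: str = "union") -> InteractionSet:
    """Union of interaction sets over distinct (miRNA, gene) pairs.

    Provenance (sources and evidence labels) is merged onto the single
    retained record per pair.  Commutative, associative and idempotent on the
    pair set.
    """
    if not sets:
        raise ValueError("union_sets requires at least one set")
    out = InteractionSet(name=name)
    for s in sets:
        for rec in s:
            for src in sorted(rec.sources):
                out.add(Interaction(rec.mirna, rec.gene, Source(src)))
            merged = out.record(rec.mirna, rec.gene)
            merged.evidence.extend(rec.evidence)
            merged.n_records += rec.n_records - len(rec.sources)
    return out


def _entities(iset: InteractionSet, by: str):
    if by == "gene":
        return iset.genes()
    if by == "mirna":
        return iset.mirnas()
    if by == "pair":
        return iset.pairs
    raise ValueError(f"unknown venn mode {by!r}")


def venn_counts(sets, by: str = "gene") -> dict[str, int]:
    """Counts of the 7 disjoint regions of a three-set Venn diagram.

    Keys are membership patterns over the three input sets in order, e.g.
    ``"110"`` = in the first and second set but not the third.  The counts
    sum to the distinct-entity count of the union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly three sets")
    a, b, c = (_entities(s, by) for s in sets)
    regions = {f"{i}{j}{k}": 0 for i in (0, 1) for j in (0, 1) for k in (0, 1)}
    del regions["000"]
    for x in a | b | c:
        key = f"{int(x in a)}{int(x in b)}{int(x in c)}"
        regions[key] += 1
    return regions


def degree_split(
    iset: InteractionSet,
    threshold: int = 6,
    mode: str = "degree",
    cover_fraction: float = 0.75,
) -> DegreeSplit:
    """Split the miRNA universe into a high-degree set A and the remainder B.

    In ``degree`` mode, set A holds every miRNA targeting at least
    ``threshold`` distinct genes (ties at the threshold go to A) and set B
    the rest, matching a "fewer than *threshold* targets" definition of B.
    In ``cover_fraction`` mode, miRNAs are taken in decreasing degree order
    until their joint targets cover at least ``cover_fraction`` of the gene
    universe; the reported threshold is then the smallest degree in A.
    """
    if len(iset) == 0:
        raise ValueError("cannot split an empty interaction set")
    degrees = iset.degrees()
    n_genes = len(iset.genes())
    if mode == "degree":
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        set_a = {m for m, d in degrees.items() if d >= threshold}
        eff_threshold = threshold
    elif mode == "cover_fraction":
        order = sorted(degrees, key=lambda m: (-degrees[m], m))
        set_a: set[str] = set()
        covered: set[str] = set()
        for m in order:
            if len(covered) >= cover_fraction * n_genes:
                break
            set_a.add(m)
            covered |= iset.targets_of([m])
        eff_threshold = min((degrees[m] for m in set_a), default=1)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    set_b = set(degrees) - set_a
    coverage = len(iset.targets_of(set_a)) / n_genes if n_genes else 0.0
    share = round(100 * len(set_a) / len(degrees)) if degrees else 0
    return DegreeSplit(
        set_a=set_a,
        set_b=set_b,
        threshold=eff_threshold,
        coverage_fraction=coverage,
        share_a_percent=share,
    )
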
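"""Interaction readers, union/Venn accounting and the degree split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirgo.interactions import (
    FormatError,
    Interaction,
    InteractionSet,
    Source,
    degree_split,
    read_interaction_table,
    union_sets,
    venn_counts,
    write_interaction_table,
)


def make_set(pairs, name="s", source=Source.EMPIRICAL_A):
    return InteractionSet(
        name=name, interactions=[Interaction(m, g, source) for m, g in pairs]
    )


def write_empirical(path, rows):
    lines = ["mirna\tgene\tevidence"]
    lines += [f"{m}\t{g}\t{e}" for m, g, e in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReader:
    def test_evidence_whitelist_drops_weak_rows(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_empirical(
            p,
            [
                ("m1", "G1", "reporter"),
                ("m1", "G2", "western"),
                ("m2", "G3", "microarray"),
                ("m2", "G4", "reporter"),
            ],
        )
        iset = read_interaction_table(p, evidence_filter={"reporter", "western"})
        assert len(iset) == 3

    def test_duplicate_pair_collapsed_with_provenance(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_empirical(p, [("m1", "G1", "reporter"), ("m1", "g1 ", "western")])
        iset = read_interaction_table(p)
        assert len(iset) == 1
        rec = iset.record("m1", "G1")
        assert rec.n_records == 2 and rec.evidence == ["reporter", "western"]

    def test_gene_symbols_normalized(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_empirical(p, [("m1", "  tp53 ", "reporter")])
        iset = read_interaction_table(p)
        assert iset.genes() == {"TP53"}

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("mirna\tgene\nm1\tG1\n")
        with pytest.raises(FormatError, match="evidence"):
            read_interaction_table(p)

    def test_empty_after_filter_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_empirical(p, [("m1", "G1", "microarray")])
        with pytest.warns(UserWarning, match="no interactions"):
            iset = read_interaction_table(p, evidence_filter={"reporter"})
        assert len(iset) == 0

    def test_synthetic_duplicates_brute_force_count(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = []
        pairs = [(f"m{i}", f"G{i}") for i in range(90)]
        for m, g in pairs:
            rows.append((m, g, "reporter"))
        for m, g in [pairs[i] for i in rng.choice(90, size=10, replace=False)]:
            rows.append((m, g, "western"))
        p = tmp_path / "t.tsv"
        write_empirical(p, rows)
        iset = read_interaction_table(p)
        # oracle: distinct pairs by direct enumeration of the rows written
        assert len(iset) == len({(m, g) for m, g, _ in rows}) == 90

    def test_round_trip_preserves_pair_set(self, tmp_path, desk_bundle):
        iset = desk_bundle["empirical_a"]
        out = tmp_path / "merged.tsv"
        write_interaction_table(iset, out)
        back = read_interaction_table(out, dialect="merged")
        assert back.pairs == iset.pairs


class TestUnion:
    def test_small_example(self):
        a = make_set([("m1", "G1"), ("m1", "G2")])
        b = make_set([("m1", "G2"), ("m2", "G3")], source=Source.EMPIRICAL_B)
        u = union_sets([a, b])
        assert len(u) == 3 and u.mirnas() == {"m1", "m2"} and len(u.genes()) == 3
        assert u.record("m1", "G2").sources == {"EMPIRICAL_A", "EMPIRICAL_B"}

    def test_idempotent(self):
        a = make_set([("m1", "G1"), ("m2", "G2")])
        assert union_sets([a, a]).pairs == a.pairs

    def test_inclusion_exclusion_on_constructed_overlaps(self):
        rng = np.random.default_rng(0)
        universe = [(f"m{i}", f"G{j}") for i in range(10) for j in range(20)]
        picks = [
            {universe[i] for i in rng.choice(len(universe), size=n, replace=False)}
            for n in (50, 40, 30)
        ]
        sets = [make_set(p, name=str(i)) for i, p in enumerate(picks)]
        u = union_sets(sets)
        a, b, c = picks
        incl_excl = (
            len(a) + len(b) + len(c)
            - len(a & b) - len(a & c) - len(b & c)
            + len(a & b & c)
        )
        assert len(u) == incl_excl == len(a | b | c)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.sampled_from("mnop"), st.sampled_from("ABCDEF")),
                max_size=10,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_union_is_order_invariant(self, groups):
        groups = [g for g in groups if g] or [[("m", "A")]]
        sets = [make_set(g, name=str(i)) for i, g in enumerate(groups)]
        assert union_sets(sets).pairs == union_sets(sets[::-1]).pairs


class TestVenn:
    def test_disjoint_sets(self):
        sets = [
            make_set([("m", f"A{i}") for i in range(2)]),
            make_set([("m", f"B{i}") for i in range(3)]),
            make_set([("m", f"C{i}") for i in range(4)]),
        ]
        regions = venn_counts(sets, by="gene")
        assert (regions["100"], regions["010"], regions["001"]) == (2, 3, 4)
        assert sum(regions.values()) == 9

    def test_identical_sets_all_in_center(self):
        s = make_set([("m", f"G{i}") for i in range(5)])
        regions = venn_counts([s, s, s], by="gene")
        assert regions["111"] == 5 and sum(regions.values()) == 5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_regions_sum_to_union_cardinality(self, data):
        genes = [f"G{i}" for i in range(12)]
        sets = []
        membership = []
        for i in range(3):
            chosen = data.draw(st.sets(st.sampled_from(genes)), label=f"set{i}")
            membership.append(chosen)
            sets.append(make_set([("m", g) for g in chosen], name=str(i)))
        regions = venn_counts(sets, by="gene")
        assert all(v >= 0 for v in regions.values())
        assert sum(regions.values()) == len(set().union(*membership))
        # brute-force membership tabulation oracle
        for key, count in regions.items():
            expect = sum(
                1
                for g in set().union(*membership)
                if "".join(str(int(g in m)) for m in membership) == key
            )
            assert count == expect


class TestDegreeSplit:
    def test_threshold_partitions(self):
        pairs = (
            [("m1", f"G{i}") for i in range(10)]
            + [("m2", f"G{i}") for i in range(7)]
            + [("m3", f"G{i}") for i in range(5)]
            + [("m4", "G0")]
        )
        split = degree_split(make_set(pairs), threshold=6)
        assert split.set_a == {"m1", "m2"} and split.set_b == {"m3", "m4"}

    def test_share_reported_as_nearest_integer_percent(self):
        # 181 of 788 miRNAs in the high-degree set is a 23% share
        pairs = []
        for i in range(181):
            pairs += [(f"hub{i}", f"G{j}") for j in range(6)]
        for i in range(788 - 181):
            pairs += [(f"low{i}", f"G{i % 6}")]
        split = degree_split(make_set(pairs), threshold=6)
        assert len(split.set_a) == 181 and split.share_a_percent == 23

    def test_coverage_matches_brute_force_union(self, desk_bundle):
        iset = desk_bundle["empirical_a"]
        split = degree_split(iset, threshold=6)
        brute = set()
        for m, g in iset.pairs:
            if m in split.set_a:
                brute.add(g)
        assert split.coverage_fraction == pytest.approx(len(brute) / len(iset.genes()))
        degrees = iset.degrees()
        assert min((degrees[m] for m in split.set_a), default=6) >= 6
        assert max((degrees[m] for m in split.set_b), default=0) < 6
        assert split.set_a | split.set_b == iset.mirnas()
        assert not split.set_a & split.set_b

    def test_cover_fraction_mode_reaches_target(self, desk_bundle):
        iset = desk_bundle["empirical_a"]
        split = degree_split(iset, mode="cover_fraction", cover_fraction=0.75)
        assert split.coverage_fraction >= 0.75

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            degree_split(InteractionSet(name="empty"), threshold=6)
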
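"""Subpattern notation, region partitions, clade tables, candidate reports."""

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pancassette.clades import (
    CladeAssignment,
    DistanceMatrix,
    complete_linkage,
    cut_clades,
)
from pancassette.patterns import (
    OGCPattern,
    collapse_identical_patterns,
    conserved_adjacent_pairs,
    expand_collapsed_patterns,
    format_subpattern,
    parse_subpattern,
    partition_regions,
    reconstruct_pattern,
    recombination_candidates,
    subpattern_clade_table,
)


class TestFormatSubpattern:
    @pytest.mark.parametrize(
        "tokens, expect",
        [
            ([4724, 4725, 4726, 4727, 4728, 4729, 4730], "(4724-4730)"),
            ([8734, 8733, 8732, 8731, 8730, 8729], "(8734-8729)"),  # descending run
            ([], "()"),
            ([5718, 3752], "(5718,3752)"),
            ([1, 2, 3, 10, 11, 7], "(1-3,10-11,7)"),
            ([5], "(5)"),
        ],
    )
    def test_notation(self, tokens, expect):
        assert format_subpattern(tokens) == expect

    @pytest.mark.parametrize(
        "s, expect",
        [
            ("(3751-3752)", [3751, 3752]),
            ("()", []),
            ("(8734-8729)", [8734, 8733, 8732, 8731, 8730, 8729]),
            ("(5718,3752)", [5718, 3752]),
        ],
    )
    def test_parse(self, s, expect):
        assert parse_subpattern(s) == expect

    def test_malformed_strings_error_with_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_subpattern("(12,x)")
        with pytest.raises(ValueError, match="parenthesized"):
            parse_subpattern("12,13")

    @given(st.lists(st.integers(min_value=0, max_value=99999), max_size=30))
    def test_round_trip(self, tokens):
        assert parse_subpattern(format_subpattern(tokens)) == tokens


class TestConservedPairs:
    def test_single_strain_returns_all_adjacent_pairs(self):
        p = OGCPattern("G", (1, 2, 3))
        assert conserved_adjacent_pairs([p]) == [(1, 2), (2, 3)]

    def test_insertion_breaks_only_the_spanned_pair(self):
        ps = [OGCPattern("G1", (1, 2, 3, 4)), OGCPattern("G2", (1, 2, 9, 3, 4))]
        assert conserved_adjacent_pairs(ps) == [(1, 2), (3, 4)]

    def test_repeat_disqualifies_the_pair(self):
        ps = [OGCPattern("G1", (1, 2, 3)), OGCPattern("G2", (1, 2, 3, 1))]
        assert conserved_adjacent_pairs(ps) == [(2, 3)]

    def test_study_layout_pairs_recovered(self, small_sim):
        from pancassette.simulate import CONSERVED_PAIRS

        ps = [OGCPattern(s, small_sim.truth.walks[s]) for s in small_sim.strains]
        assert conserved_adjacent_pairs(ps) == list(CONSERVED_PAIRS)


ANCHORS = (3712, 3756)
PAIRS = [(3721, 3722), (3749, 3750), (3753, 3754)]


class TestPartitionRegions:
    def test_study_layout_labels(self):
        walk = (4723, 3721, 3722, 4724, 4725, 3749, 3750, 4752, 4753, 3753, 3754, 4754)
        regions = partition_regions(OGCPattern("G", walk), ANCHORS, PAIRS)
        assert [r[0] for r in regions] == [
            "3712-3721", "3722-3749", "3750-3753", "3754-3756",
        ]
        assert regions[0][1] == (4723,)
        assert regions[2][1] == (4752, 4753)

    def test_empty_region_yields_null_subpattern(self):
        walk = (3721, 3722, 4724, 3749, 3750, 4752, 3753, 3754)
        regions = partition_regions(OGCPattern("G", walk), ANCHORS, PAIRS)
        assert regions[0][1] == () and format_subpattern(regions[0][1]) == "()"
        assert regions[3][1] == ()

    def test_missing_boundary_names_strain_and_ogc(self):
        walk = (4723, 3721, 4724, 3749, 3750, 3753, 3754)  # 3722 missing
        with pytest.raises(ValueError, match=r"3722.*Gx"):
            partition_regions(OGCPattern("Gx", walk), ANCHORS, PAIRS)

    def test_reconstruction_round_trip(self, small_sim):
        from pancassette.simulate import CONSERVED_PAIRS, LEFT_ANCHOR, RIGHT_ANCHOR

        for s in small_sim.strains:
            walk = small_sim.truth.walks[s]
            regions = partition_regions(
                OGCPattern(s, walk), (LEFT_ANCHOR, RIGHT_ANCHOR), list(CONSERVED_PAIRS)
            )
            rebuilt = reconstruct_pattern(
                regions, (LEFT_ANCHOR, RIGHT_ANCHOR), list(CONSERVED_PAIRS)
            )
            assert rebuilt == (LEFT_ANCHOR,) + walk + (RIGHT_ANCHOR,)


def _fake_clades(clade_of: dict) -> CladeAssignment:
    """CladeAssignment carrying just the mapping (dendrogram unused here)."""
    labels = sorted(clade_of)
    n = len(labels)
    d = DistanceMatrix(labels, 1.0 - np.eye(n))
    dend = complete_linkage(d)
    return CladeAssignment(dict(clade_of), dend, 0.5)


class TestSubpatternTable:
    def _partitions(self, walks):
        return {
            s: partition_regions(OGCPattern(s, w), ANCHORS, PAIRS)
            for s, w in walks.items()
        }

    def test_single_strain_counts_one_per_region(self):
        walks = {"G": (4723, 3721, 3722, 4724, 3749, 3750, 4752, 3753, 3754, 4754)}
        table = subpattern_clade_table(self._partitions(walks), {"G": "I"})
        assert len(table.df) == 4
        assert (table.df["I"] == 1).all()

    def test_strain_missing_from_one_input_is_an_error(self):
        walks = {"G": (4723, 3721, 3722, 4724, 3749, 3750, 4752, 3753, 3754, 4754)}
        with pytest.raises(ValueError, match="only one input"):
            subpattern_clade_table(self._partitions(walks), {"G": "I", "H": "II"})

    def test_region_column_sums_equal_clade_sizes(self):
        rng = random.Random(23)
        walks = {}
        for i in range(12):
            r1 = tuple(rng.sample(range(100, 110), rng.randint(0, 2)))
            r3 = tuple(rng.sample(range(200, 210), rng.randint(0, 2)))
            walks[f"G{i:02d}"] = (
                r1 + (3721, 3722) + (4724,) + (3749, 3750) + r3 + (3753, 3754)
            )
        clade_of = {s: ("I" if i < 7 else "II") for i, s in enumerate(sorted(walks))}
        table = subpattern_clade_table(self._partitions(walks), clade_of)
        for region in table.region_order:
            sub = table.df[table.df["region"] == region]
            assert sub["I"].sum() == 7 and sub["II"].sum() == 5

    def test_counts_match_bruteforce_recount(self):
        rng = random.Random(5)
        walks = {}
        for i in range(15):
            r2 = tuple(rng.sample(range(300, 306), rng.randint(0, 3)))
            walks[f"G{i:02d}"] = (3721, 3722) + r2 + (3749, 3750) + (3753, 3754)
        clade_of = {s: rng.choice(["I", "II", "III"]) for s in walks}
        parts = self._partitions(walks)
        table = subpattern_clade_table(parts, clade_of)
        # brute-force recount
        expect: dict = {}
        for s, regions in parts.items():
            for label, toks in regions:
                key = (label, format_subpattern(toks), clade_of[s])
                expect[key] = expect.get(key, 0) + 1
        for _, row in table.df.iterrows():
            for clade in table.clade_labels:
                key = (row["region"], row["subpattern"], clade)
                assert row[clade] == expect.get(key, 0)


class TestCollapse:
    def test_distinct_patterns_do_not_collapse(self):
        pats = {"a": (1, 2), "b": (1, 3)}
        rows = collapse_identical_patterns(pats)
        assert [r[1] for r in rows] == [1, 1]

    def test_identical_patterns_merge_with_multiplicity(self):
        pats = {"a": (1, 2), "b": (1, 2), "c": (1, 2)}
        rows = collapse_identical_patterns(pats)
        assert rows == [((1, 2), 3, ["a", "b", "c"])]

    @given(
        st.dictionaries(
            st.text(alphabet="abcdef", min_size=1, max_size=3),
            st.lists(st.integers(0, 5), max_size=4).map(tuple),
            max_size=8,
        )
    )
    def test_expansion_round_trip(self, pats):
        rows = collapse_identical_patterns(pats)
        assert expand_collapsed_patterns(rows) == {s: tuple(p) for s, p in pats.items()}


class TestRecombinationCandidates:
    def _table_and_clades(self, walks, clade_of):
        parts = {
            s: partition_regions(OGCPattern(s, w), ANCHORS, PAIRS)
            for s, w in walks.items()
        }
        return subpattern_clade_table(parts, clade_of), _fake_clades(clade_of)

    def _uniform_walks(self, clade_of, variants):
        return {s: variants[clade_of[s]] for s in clade_of}

    VARIANTS = {
        "I": (101, 3721, 3722, 111, 3749, 3750, 121, 3753, 3754, 131),
        "II": (201, 3721, 3722, 211, 3749, 3750, 221, 3753, 3754, 231),
    }

    def test_no_shared_subpatterns_no_candidates(self):
        clade_of = {f"A{i}": "I" for i in range(4)} | {f"B{i}": "II" for i in range(4)}
        table, clades = self._table_and_clades(
            self._uniform_walks(clade_of, self.VARIANTS), clade_of
        )
        d = DistanceMatrix(sorted(clade_of), 1.0 - np.eye(8))
        assert recombination_candidates(table, clades, d, include_outliers=False) == []

    def test_region_swap_is_flagged_with_minority_strain(self):
        clade_of = {f"A{i}": "I" for i in range(4)} | {f"B{i}": "II" for i in range(4)}
        walks = self._uniform_walks(clade_of, self.VARIANTS)
        # B3 receives clade I's third region
        walks["B3"] = (201, 3721, 3722, 211, 3749, 3750, 121, 3753, 3754, 231)
        table, clades = self._table_and_clades(walks, clade_of)
        d = DistanceMatrix(sorted(clade_of), 1.0 - np.eye(8))
        out = recombination_candidates(table, clades, d, include_outliers=False)
        assert len(out) == 1
        c = out[0]
        assert c.kind == "region"
        assert c.region_label == "3750-3753"
        assert c.subpattern == "(121)"
        assert c.strains == ("B3",)
        assert dict(c.clade_counts) == {"I": 4, "II": 1}

    def test_outlier_strain_flagged_when_clade_absent_from_neighbours(self):
        # 6 strains; s5's gene-content clade is II but its nearest ANI
        # neighbours are all clade I
        clade_of = {f"s{i}": ("I" if i < 3 else "II") for i in range(6)}
        clade_of["s2"] = "II"  # content clade II, genomically amid clade I
        labels = sorted(clade_of)
        d = np.full((6, 6), 5.0)
        for grp in ([0, 1, 2], [3, 4, 5]):  # genomic blocks
            for i in grp:
                for j in grp:
                    d[i, j] = 0.0 if i == j else 0.3
        dm = DistanceMatrix(labels, d, scale="ani_pct_distance")
        walks = {
            s: (self.VARIANTS["I"] if c == "I" else self.VARIANTS["II"])
            for s, c in clade_of.items()
        }
        parts = {
            s: partition_regions(OGCPattern(s, w), ANCHORS, PAIRS)
            for s, w in walks.items()
        }
        table = subpattern_clade_table(parts, clade_of)
        out = recombination_candidates(_table := table, _fake_clades(clade_of), dm, q=2)
        outliers = [c for c in out if c.kind == "outlier_strain"]
        assert [c.strains for c in outliers] == [("s2",)]

    def test_singleton_clades_are_never_outliers(self):
        clade_of = {"s0": "I", "s1": "I", "s2": "I", "s3": "II"}
        labels = sorted(clade_of)
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(labels, d, scale="ani_pct_distance")
        walks = {
            s: (self.VARIANTS["I"] if c == "I" else self.VARIANTS["II"])
            for s, c in clade_of.items()
        }
        parts = {
            s: partition_regions(OGCPattern(s, w), ANCHORS, PAIRS)
            for s, w in walks.items()
        }
        table = subpattern_clade_table(parts, clade_of)
        out = recombination_candidates(table, _fake_clades(clade_of), dm, q=3)
        assert [c for c in out if c.kind == "outlier_strain"] == []
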
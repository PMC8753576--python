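"""Unit tests for OGC clustering, the pan-genome graph, and re-annotation."""

import itertools
import random

import pytest

from pancassette.pangraph import (
    ExactMatchSearch,
    Gene,
    GenomeAnnotation,
    HomologyMatch,
    KmerEdlibSearch,
    Placement,
    SearchHit,
    adjacency_key,
    annotate_genome,
    build_pgg,
    cluster_ogcs,
    compute_medoid,
    iterate_to_stability,
    reverse_complement,
)
from pancassette.pipeline import (
    annotations_from_genes,
    medoid_sequences,
    nucleotide_matches,
)


def mk_gene(gene_id, genome, seq="ATGAAATTTGGGTAA", contig="c1", start=0, strand="+"):
    return Gene(gene_id, genome, contig, start, start + len(seq), strand, seq)


def mk_match(q, s, pid=100.0, cov=1.0, bits=100.0):
    return HomologyMatch(q, s, pid, cov, cov, bits)


class TestClusterOgcs:
    def test_mutual_full_match_forms_one_ogc(self):
        genes = [mk_gene("a", "G1"), mk_gene("b", "G2")]
        ogcs = cluster_ogcs(genes, [mk_match("a", "b"), mk_match("b", "a")])
        assert len(ogcs) == 1
        assert ogcs[0].members == frozenset({"a", "b"})

    def test_match_below_identity_threshold_yields_singletons(self):
        genes = [mk_gene("a", "G1"), mk_gene("b", "G2")]
        ogcs = cluster_ogcs(genes, [mk_match("a", "b", pid=89.0, cov=0.95)])
        assert [set(o.members) for o in ogcs] == [{"a"}, {"b"}]

    def test_unknown_gene_in_match_is_an_error(self):
        genes = [mk_gene("a", "G1")]
        with pytest.raises(ValueError, match="ghost"):
            cluster_ogcs(genes, [mk_match("a", "ghost")])

    def test_one_gene_per_genome_always_holds(self, small_sim):
        genes = [g for s in small_sim.strains for g in small_sim.genes[s]]
        ogcs = cluster_ogcs(genes, nucleotide_matches(genes))
        genome_of = {g.gene_id: g.genome_id for g in genes}
        for ogc in ogcs:
            genomes = [genome_of[g] for g in ogc.members]
            assert len(genomes) == len(set(genomes))

    def test_invariant_under_match_order_permutation(self):
        genes = [mk_gene(g, G) for g, G in
                 [("a1", "GA"), ("a2", "GA"), ("b", "GB"), ("c", "GC")]]
        matches = [
            mk_match("a1", "b", pid=95, bits=200),
            mk_match("a2", "b", pid=94, bits=150),
            mk_match("a1", "c", pid=95, bits=190),
            mk_match("a2", "c", pid=96, bits=180),
            mk_match("b", "c", pid=95, bits=170),
            mk_match("a1", "a2", pid=93, bits=160),
        ]
        reference = cluster_ogcs(genes, matches)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = matches[:]
            rng.shuffle(shuffled)
            assert cluster_ogcs(genes, shuffled) == reference

    def test_paralog_split_matches_bruteforce_max_bitscore_partition(self):
        """Component splitting agrees with exhaustive search over valid
        one-gene-per-genome partitions maximizing summed retained bitscore."""
        genes = [mk_gene(g, G) for g, G in
                 [("a1", "GA"), ("a2", "GA"), ("b", "GB"), ("c", "GC")]]
        matches = [
            mk_match("a1", "b", pid=95, bits=200),
            mk_match("a2", "b", pid=94, bits=150),
            mk_match("a1", "c", pid=95, bits=190),
            mk_match("a2", "c", pid=96, bits=180),
            mk_match("b", "c", pid=95, bits=170),
            mk_match("a1", "a2", pid=93, bits=160),
        ]
        bits = {frozenset((m.query_gene_id, m.subject_gene_id)): m.bitscore
                for m in matches}
        genome_of = {g.gene_id: g.genome_id for g in genes}
        ids = [g.gene_id for g in genes]

        def partitions(items):
            if not items:
                yield []
                return
            head, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] + [head]] + part[i + 1:]
                yield part + [[head]]

        def valid(part):
            return all(
                len({genome_of[g] for g in block}) == len(block) for block in part
            )

        def score(part):
            return sum(
                bits.get(frozenset((x, y)), 0.0)
                for block in part
                for x, y in itertools.combinations(block, 2)
            )

        best = max((p for p in partitions(ids) if valid(p)), key=score)
        expected = sorted(frozenset(b) for b in best)
        got = sorted(o.members for o in cluster_ogcs(genes, matches))
        assert got == expected
        assert score([sorted(m) for m in got]) == score(best)


class TestComputeMedoid:
    def test_singleton(self):
        assert compute_medoid(["only"], lambda a, b: 0.0) == "only"

    def test_three_members_min_summed_distance(self):
        d = {("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 4.0}
        assert compute_medoid(["A", "B", "C"], d) == "A"  # sums: A=2, B=5, C=5

    def test_all_equal_distances_breaks_tie_lexicographically(self):
        members = ["d", "b", "c", "a"]
        assert compute_medoid(members, lambda a, b: 1.0) == "a"

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            compute_medoid([], lambda a, b: 0.0)


def ann(genome, walk, contig="c1", length=10, gap=5):
    pls = []
    pos = 0
    for ogc, strand in walk:
        pls.append(Placement(ogc, pos, pos + length, strand))
        pos += length + gap
    return GenomeAnnotation.build(genome, {contig: pls})


class TestBuildPgg:
    def test_single_walk_edges(self):
        pgg = build_pgg([ann("G1", [(1, "+"), (2, "+"), (3, "+")])])
        assert pgg.nodes == {1, 2, 3}
        assert len(pgg.edge_support) == 2
        assert all(v == 1 for v in pgg.edge_support.values())
        assert pgg.has_edge(1, "+", 2, "+") and pgg.has_edge(2, "+", 3, "+")

    def test_identical_walks_double_support(self):
        walk = [(1, "+"), (2, "+"), (3, "+")]
        pgg = build_pgg([ann("G1", walk), ann("G2", walk)])
        assert len(pgg.edge_support) == 2
        assert all(v == 2 for v in pgg.edge_support.values())

    def test_duplicate_genome_is_an_error(self):
        walk = [(1, "+"), (2, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            build_pgg([ann("G1", walk), ann("G1", walk)])

    def test_random_annotations_match_bruteforce_recount(self):
        rng = random.Random(42)
        annotations = []
        for i in range(10):
            walk = [
                (rng.randint(1, 6), rng.choice("+-")) for _ in range(rng.randint(1, 8))
            ]
            annotations.append(ann(f"G{i}", walk))
        pgg = build_pgg(annotations)
        recount: dict = {}
        total = 0
        for a in annotations:
            for pls in a.placements.values():
                total += max(0, len(pls) - 1)
                for p, q in zip(pls, pls[1:]):
                    key = adjacency_key(p.ogc_id, p.strand, q.ogc_id, q.strand)
                    recount[key] = recount.get(key, 0) + 1
        assert pgg.edge_support == recount
        assert sum(pgg.edge_support.values()) == total

    def test_core_threshold(self):
        pgg = build_pgg(
            [ann("G1", [(1, "+"), (2, "+")]), ann("G2", [(1, "+")])],
            core_threshold=0.95,
        )
        assert pgg.is_core(1) and not pgg.is_core(2)


class TestAnnotateGenome:
    def _medoids(self):
        return {1: "ATGAAACCCGGGTTTACGTAA", 2: "ATGCCCACGTGCAAATTTTAA", 3: "ATGGGGACCCTTGCACAATAA"}

    def test_concatenated_medoids_found_in_order(self):
        med = self._medoids()
        contig = "NN" + med[1] + "NN" + med[2] + "NN" + med[3] + "NN"
        pgg = build_pgg([ann("ref", [(1, "+"), (2, "+"), (3, "+")])])
        out = annotate_genome(pgg, med, "G", {"c1": contig}, ExactMatchSearch())
        walk = out.walks()["c1"]
        assert walk == ((1, "+"), (2, "+"), (3, "+"))

    def test_reverse_complement_flips_walk(self):
        med = self._medoids()
        contig = "NN" + med[1] + "NN" + med[2] + "NN" + med[3] + "NN"
        pgg = build_pgg([ann("ref", [(1, "+"), (2, "+"), (3, "+")])])
        fwd = annotate_genome(pgg, med, "G", {"c1": contig}, ExactMatchSearch())
        rev = annotate_genome(
            pgg, med, "G", {"c1": reverse_complement(contig)}, ExactMatchSearch()
        )
        expect = tuple((o, "-" if s == "+" else "+") for o, s in reversed(fwd.walks()["c1"]))
        assert rev.walks()["c1"] == expect

    def test_graph_consistent_candidate_beats_higher_score(self):
        """Of two overlapping candidates, the one whose neighbours exist as
        PGG edges wins even with the lower alignment score."""
        pgg = build_pgg([ann("ref", [(1, "+"), (2, "+"), (3, "+")])])

        def stub_search(medoids, contig):
            return [
                SearchHit(1, 0, 10, "+", 100.0, 1.0, 10.0),
                SearchHit(2, 20, 30, "+", 95.0, 1.0, 9.0),   # graph-consistent
                SearchHit(9, 20, 30, "+", 99.0, 1.0, 12.0),  # better score, no context
                SearchHit(3, 40, 50, "+", 100.0, 1.0, 10.0),
            ]

        out = annotate_genome(pgg, {}, "G", {"c1": "N" * 60}, stub_search)
        assert [p.ogc_id for p in out.placements["c1"]] == [1, 2, 3]

    def test_contig_without_candidates_is_empty_not_an_error(self):
        pgg = build_pgg([ann("ref", [(1, "+"), (2, "+")])])
        out = annotate_genome(
            pgg, self._medoids(), "G", {"c1": "A" * 50}, ExactMatchSearch()
        )
        assert out.placements["c1"] == ()


class TestIterateToStability:
    def _setup(self, small_sim):
        genes = [g for s in small_sim.strains for g in small_sim.genes[s]]
        ogcs = cluster_ogcs(genes, nucleotide_matches(genes))
        anns = annotations_from_genes(genes, ogcs)
        med = medoid_sequences(ogcs, {g.gene_id: g for g in genes})
        return anns, med

    def test_fixed_point_returns_input_after_one_round(self, small_sim):
        anns, med = self._setup(small_sim)
        res = iterate_to_stability(
            small_sim.genomes, anns, med, KmerEdlibSearch(), max_iters=10
        )
        assert res.converged and res.n_iters == 1
        for gid, a in res.annotations.items():
            assert a.walks() == anns[gid].walks()

    def test_omitted_gene_is_recovered(self, small_sim):
        anns, med = self._setup(small_sim)
        strain = small_sim.strains[0]
        contig = f"{strain}_c1"
        full = anns[strain].placements[contig]
        truncated = dict(anns)
        truncated[strain] = GenomeAnnotation.build(
            strain, {contig: full[:3] + full[4:]}  # drop one interior gene
        )
        res = iterate_to_stability(
            small_sim.genomes, truncated, med, KmerEdlibSearch(), max_iters=10
        )
        assert res.converged and res.n_iters <= 3
        assert res.annotations[strain].walks()[contig] == anns[strain].walks()[contig]
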
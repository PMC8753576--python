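"""Ortholog gene clusters (OGCs) and the pan-genome graph (PGG).

An OGC is a set of computationally determined orthologous genes with at most
one member per genome.  The pan-genome graph has OGCs as nodes and
orientation-aware genome adjacencies as edges.  Genomes are (re-)annotated
against the graph by searching each contig for the medoid sequence of every
node and resolving conflicting placements with graph context; alternating
graph construction and re-annotation is iterated to a fixed point so that
every genome is annotated consistently.

Coordinates are 0-based half-open throughout.  Gene sequences are stored in
coding orientation (the reverse complement of the genome slice for ``-``
strand genes).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import edlib
import networkx as nx

__all__ = [
    "Gene",
    "HomologyMatch",
    "OGC",
    "Placement",
    "GenomeAnnotation",
    "PanGenomeGraph",
    "SearchHit",
    "ExactMatchSearch",
    "KmerEdlibSearch",
    "IterationResult",
    "adjacency_key",
    "cluster_ogcs",
    "compute_medoid",
    "build_pgg",
    "annotate_genome",
    "iterate_to_stability",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A single annotated gene.

    ``start``/``end`` are 0-based half-open genome coordinates; ``sequence``
    is the coding-strand nucleotide sequence (length ``end - start``).
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= end - start = {self.end - self.start}"
            )


@dataclass(frozen=True)
class HomologyMatch:
    """Directed pairwise homology evidence (BLAST-like)."""

    query_gene_id: str
    subject_gene_id: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must lie in [0, 100]")
        for cov in (self.query_coverage, self.subject_coverage):
            if not (0.0 <= cov <= 1.0):
                raise ValueError("coverages must lie in [0, 1]")
        if self.bitscore < 0:
            raise ValueError("bitscore must be nonnegative")


@dataclass(frozen=True)
class OGC:
    """An ortholog gene cluster: at most one member gene per genome."""

    ogc_id: int
    members: frozenset[str]
    medoid_gene_id: str

    def __post_init__(self) -> None:
        if self.medoid_gene_id not in self.members:
            raise ValueError(f"OGC {self.ogc_id}: medoid not among members")


class Placement(NamedTuple):
    """One OGC placed on a contig."""

    ogc_id: int
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered, non-overlapping OGC placements per contig of one genome."""

    genome_id: str
    placements: dict[str, tuple[Placement, ...]]

    @staticmethod
    def build(
        genome_id: str, placements: Mapping[str, Iterable[Placement]]
    ) -> "GenomeAnnotation":
        """Sort placements per contig and verify they do not overlap."""
        clean: dict[str, tuple[Placement, ...]] = {}
        for contig, pls in placements.items():
            ordered = tuple(sorted(pls, key=lambda p: (p.start, p.end, p.ogc_id)))
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{genome_id}/{contig}: overlapping placements "
                        f"{a} and {b}"
                    )
            clean[contig] = ordered
        return GenomeAnnotation(genome_id, clean)

    def walks(self) -> dict[str, tuple[tuple[int, str], ...]]:
        """Per-contig ordered (ogc_id, strand) walk."""
        return {
            contig: tuple((p.ogc_id, p.strand) for p in pls)
            for contig, pls in self.placements.items()
        }


def adjacency_key(
    a: int, a_strand: str, b: int, b_strand: str
) -> tuple[int, str, int, str]:
    """Canonical orientation-aware edge key for the adjacency ``a`` then ``b``.

    Each gene has an intrinsic *tail* (5' end of its coding strand) and
    *head* (3' end).  Reading a contig left to right one leaves a ``+`` gene
    at its head and enters a ``+`` gene at its tail (and vice versa for
    ``-``).  The key is symmetric under reverse complementation of the
    contig, so the same physical junction always maps to the same edge.
    """
    ea = "head" if a_strand == "+" else "tail"
    eb = "tail" if b_strand == "+" else "head"
    fwd = (a, ea, b, eb)
    rev = (b, eb, a, ea)
    return min(fwd, rev)


@dataclass
class PanGenomeGraph:
    """OGC nodes plus orientation-aware adjacency edges with support counts.

    ``edge_support`` counts adjacency occurrences over all genomes, so that
    the total support equals ``sum over contigs of max(0, n_placements - 1)``
    and a brute-force adjacency recount reproduces it exactly.
    """

    n_genomes: int
    core_threshold: float
    node_support: dict[int, int]
    edge_support: dict[tuple[int, str, int, str], int]

    @property
    def nodes(self) -> set[int]:
        return set(self.node_support)

    def is_core(self, ogc_id: int) -> bool:
        return self.node_support.get(ogc_id, 0) >= self.core_threshold * self.n_genomes

    def has_edge(self, a: int, a_strand: str, b: int, b_strand: str) -> bool:
        return adjacency_key(a, a_strand, b, b_strand) in self.edge_support


def build_pgg(
    annotations: Iterable[GenomeAnnotation], core_threshold: float = 0.95
) -> PanGenomeGraph:
    """Construct the pan-genome graph from genome annotations.

    Nodes are all placed OGCs; one edge per distinct orientation-aware
    adjacency, supported by the number of times it is observed.  Contig ends
    create no edges.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("build_pgg requires at least one annotation")
    if not (0.0 < core_threshold <= 1.0):
        raise ValueError("core_threshold must lie in (0, 1]")
    seen_genomes: set[str] = set()
    node_genomes: dict[int, set[str]] = defaultdict(set)
    edges: Counter = Counter()
    for ann in annotations:
        if ann.genome_id in seen_genomes:
            raise ValueError(f"duplicate genome {ann.genome_id}")
        seen_genomes.add(ann.genome_id)
        for pls in ann.placements.values():
            for p in pls:
                node_genomes[p.ogc_id].add(ann.genome_id)
            for p, q in zip(pls, pls[1:]):
                edges[adjacency_key(p.ogc_id, p.strand, q.ogc_id, q.strand)] += 1
    return PanGenomeGraph(
        n_genomes=len(seen_genomes),
        core_threshold=core_threshold,
        node_support={k: len(v) for k, v in node_genomes.items()},
        edge_support=dict(edges),
    )


# ---------------------------------------------------------------------------
# OGC clustering
# ---------------------------------------------------------------------------


def _symmetrize(
    matches: Iterable[HomologyMatch],
    gene_ids: set[str],
    min_identity: float,
    min_coverage: float,
) -> dict[frozenset[str], tuple[float, float]]:
    """Undirected retained matches: pair -> (best identity, best bitscore).

    A pair is retained if either direction passes the identity and coverage
    thresholds.
    """
    retained: dict[frozenset[str], tuple[float, float]] = {}
    for m in matches:
        for gid in (m.query_gene_id, m.subject_gene_id):
            if gid not in gene_ids:
                raise ValueError(f"match references unknown gene {gid!r}")
        if m.query_gene_id == m.subject_gene_id:
            continue
        if m.percent_identity < min_identity:
            continue
        if min(m.query_coverage, m.subject_coverage) < min_coverage:
            continue
        key = frozenset((m.query_gene_id, m.subject_gene_id))
        prev = retained.get(key)
        cur = (m.percent_identity, m.bitscore)
        if prev is None or cur > prev:
            retained[key] = cur
    return retained


def compute_medoid(
    members: Iterable[str] | OGC,
    distances: Callable[[str, str], float] | Mapping[tuple[str, str], float],
) -> str:
    """Member with the lowest summed pairwise distance to all other members.

    Ties break toward the lexicographically smallest gene id.  ``distances``
    may be a callable or a (symmetric) mapping of gene-id pairs; the
    diagonal is taken as zero.
    """
    if isinstance(members, OGC):
        members = members.members
    members = sorted(members)
    if not members:
        raise ValueError("cannot compute the medoid of an empty OGC")
    if callable(distances):
        dist = distances
    else:
        mapping = distances

        def dist(a: str, b: str) -> float:
            if a == b:
                return 0.0
            if (a, b) in mapping:
                return mapping[(a, b)]
            return mapping[(b, a)]

    best_id, best_sum = None, None
    for g in members:
        s = sum(dist(g, h) for h in members if h != g)
        if best_sum is None or s < best_sum:
            best_id, best_sum = g, s
    assert best_id is not None
    return best_id


_MISSING_PAIR_DISTANCE = 200.0  # beyond any 100 - identity value


def cluster_ogcs(
    genes: Iterable[Gene],
    matches: Iterable[HomologyMatch],
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> list[OGC]:
    """Cluster genes into OGCs from pairwise homology evidence.

    Clustering is connected components of the graph of reciprocal retained
    matches (a pair is kept if either direction passes the thresholds).
    Components placing two genes of one genome together are split: the
    component medoid is computed from match distances (100 - identity,
    missing pairs penalized), each conflicted genome keeps the gene with the
    higher bitscore to the medoid (lexicographic tie-break), and the evicted
    genes are re-clustered among themselves.  OGC ids are assigned in
    ascending order of the sorted member gene-id tuples; medoids come from
    the same distance lookup.
    """
    gene_list = sorted(genes, key=lambda g: g.gene_id)
    genome_of = {g.gene_id: g.genome_id for g in gene_list}
    if len(genome_of) != len(gene_list):
        raise ValueError("duplicate gene ids")
    retained = _symmetrize(matches, set(genome_of), min_identity, min_coverage)

    def pair_distance(a: str, b: str) -> float:
        hit = retained.get(frozenset((a, b)))
        return 100.0 - hit[0] if hit is not None else _MISSING_PAIR_DISTANCE

    def pair_bitscore(a: str, b: str) -> float:
        hit = retained.get(frozenset((a, b)))
        return hit[1] if hit is not None else -1.0

    graph = nx.Graph()
    graph.add_nodes_from(genome_of)
    for pair in retained:
        a, b = sorted(pair)
        graph.add_edge(a, b)

    member_sets: list[tuple[str, ...]] = []

    def resolve(component: list[str]) -> None:
        component = sorted(component)
        per_genome: dict[str, list[str]] = defaultdict(list)
        for gid in component:
            per_genome[genome_of[gid]].append(gid)
        if all(len(v) == 1 for v in per_genome.values()):
            member_sets.append(tuple(component))
            return
        medoid = compute_medoid(component, pair_distance)
        kept: list[str] = []
        evicted: list[str] = []
        for genome in sorted(per_genome):
            cands = per_genome[genome]
            if len(cands) == 1:
                kept.append(cands[0])
                continue
            if genome == genome_of[medoid]:
                chosen = medoid
            else:
                # higher bitscore to the medoid wins; ties -> smallest id
                chosen = min(cands, key=lambda g: (-pair_bitscore(g, medoid), g))
            kept.append(chosen)
            evicted.extend(g for g in cands if g != chosen)
        member_sets.append(tuple(sorted(kept)))
        if evicted:
            sub = graph.subgraph(evicted)
            for comp in sorted(nx.connected_components(sub), key=min):
                resolve(sorted(comp))

    for comp in sorted(nx.connected_components(graph), key=min):
        resolve(sorted(comp))

    member_sets.sort()
    ogcs = []
    for i, members in enumerate(member_sets, start=1):
        medoid = compute_medoid(members, pair_distance)
        ogcs.append(OGC(ogc_id=i, members=frozenset(members), medoid_gene_id=medoid))
    return ogcs


# ---------------------------------------------------------------------------
# Similarity search and genome annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchHit:
    """Candidate placement returned by a similarity searcher."""

    ogc_id: int
    start: int
    end: int
    strand: str
    identity: float  # percent, 0-100
    coverage: float  # fraction of the medoid covered, 0-1
    score: float


def _medoid_sequence(value) -> str:
    return value.sequence if isinstance(value, Gene) else str(value)


class ExactMatchSearch:
    """Exact substring searcher (both strands); useful for tests."""

    def __call__(self, medoid_index: Mapping[int, object], contig: str) -> list[SearchHit]:
        hits = []
        for ogc_id in sorted(medoid_index):
            seq = _medoid_sequence(medoid_index[ogc_id])
            for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
                pos = contig.find(probe)
                while pos != -1:
                    hits.append(
                        SearchHit(ogc_id, pos, pos + len(probe), strand, 100.0, 1.0, float(len(probe)))
                    )
                    pos = contig.find(probe, pos + 1)
        return hits


class KmerEdlibSearch:
    """Banded infix alignment of each medoid against the contig via edlib.

    For every medoid the best-scoring alignment locations on both strands
    (within ``max_divergence`` of the medoid length) are reported.  Multiple
    loci are only recovered when they tie for the best edit distance, which
    suffices for identical repeats such as IS elements; a full seed-and-
    extend multi-locus search is deliberately out of scope.
    """

    def __init__(self, max_divergence: float = 0.15):
        self.max_divergence = max_divergence

    def __call__(self, medoid_index: Mapping[int, object], contig: str) -> list[SearchHit]:
        hits: list[SearchHit] = []
        for ogc_id in sorted(medoid_index):
            seq = _medoid_sequence(medoid_index[ogc_id])
            kmax = max(1, int(self.max_divergence * len(seq)))
            for strand in ("+", "-"):
                probe = seq if strand == "+" else reverse_complement(seq)
                res = edlib.align(probe, contig, mode="HW", task="locations", k=kmax)
                if res["editDistance"] < 0:
                    continue
                dist = res["editDistance"]
                prev_end = -1
                for s, e in sorted(res["locations"]):
                    if s is None:
                        s = 0
                    if s < prev_end:  # overlapping shift of the same locus
                        continue
                    end = e + 1
                    prev_end = end
                    identity = 100.0 * (1.0 - dist / len(seq))
                    coverage = min(1.0, (end - s) / len(seq))
                    hits.append(
                        SearchHit(ogc_id, s, end, strand, identity, coverage, float(len(seq) - dist))
                    )
        return hits


def _overlap_groups(hits: list[SearchHit]) -> list[list[SearchHit]]:
    """Connected components of interval overlap, in left-to-right order."""
    groups: list[list[SearchHit]] = []
    current: list[SearchHit] = []
    current_end = -1
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.ogc_id)):
        if current and h.start >= current_end:
            groups.append(current)
            current = []
            current_end = -1
        current.append(h)
        current_end = max(current_end, h.end)
    if current:
        groups.append(current)
    return groups


def annotate_genome(
    pgg: PanGenomeGraph,
    medoid_index: Mapping[int, object],
    genome_id: str,
    contigs: Mapping[str, str],
    search: Callable[[Mapping[int, object], str], list[SearchHit]],
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> GenomeAnnotation:
    """Assign genome regions to PGG nodes with a pluggable searcher.

    Candidates failing the identity/coverage thresholds are dropped.
    Overlapping candidates are grouped (connected components of interval
    overlap) and one winner per group is chosen by (1) the number of
    flanking chosen placements consistent with PGG edges, (2) the higher
    score, (3) the smaller ogc id.  Two refinement passes over the groups
    make the context criterion self-consistent; all tie-breaks are
    deterministic.  A contig with no passing candidates yields an empty
    placement list.
    """
    placements: dict[str, list[Placement]] = {}
    for contig_id in sorted(contigs):
        seq = contigs[contig_id]
        hits = [
            h
            for h in search(medoid_index, seq)
            if h.identity >= min_identity and h.coverage >= min_coverage
        ]
        groups = _overlap_groups(hits)
        # initial choice: best score, then smaller ogc_id, then leftmost
        chosen: list[SearchHit] = [
            max(g, key=lambda h: (h.score, -h.ogc_id, -h.start)) for g in groups
        ]
        for _ in range(2):
            new_chosen = list(chosen)
            for i, group in enumerate(groups):
                prev_hit = new_chosen[i - 1] if i > 0 else None
                next_hit = chosen[i + 1] if i + 1 < len(groups) else None

                def consistency(h: SearchHit) -> int:
                    c = 0
                    if prev_hit is not None and pgg.has_edge(
                        prev_hit.ogc_id, prev_hit.strand, h.ogc_id, h.strand
                    ):
                        c += 1
                    if next_hit is not None and pgg.has_edge(
                        h.ogc_id, h.strand, next_hit.ogc_id, next_hit.strand
                    ):
                        c += 1
                    return c

                new_chosen[i] = max(
                    group, key=lambda h: (consistency(h), h.score, -h.ogc_id, -h.start)
                )
            if new_chosen == chosen:
                break
            chosen = new_chosen
        placements[contig_id] = [
            Placement(h.ogc_id, h.start, h.end, h.strand) for h in chosen
        ]
    return GenomeAnnotation.build(genome_id, placements)


class IterationResult(NamedTuple):
    pgg: PanGenomeGraph
    annotations: dict[str, GenomeAnnotation]
    n_iters: int
    converged: bool


def _walk_state(annotations: Mapping[str, GenomeAnnotation]):
    return {
        (gid, contig): walk
        for gid, ann in annotations.items()
        for contig, walk in ann.walks().items()
    }


def iterate_to_stability(
    genomes: Mapping[str, Mapping[str, str]],
    initial_annotations: Mapping[str, GenomeAnnotation],
    medoid_index: Mapping[int, object],
    search: Callable[[Mapping[int, object], str], list[SearchHit]],
    core_threshold: float = 0.95,
    max_iters: int = 10,
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> IterationResult:
    """Alternate ``build_pgg`` and ``annotate_genome`` to a fixed point.

    Convergence is defined on the multiset of per-contig ordered OGC walks
    (not base coordinates).  Stops after ``max_iters`` rounds with
    ``converged=False`` if the walks keep changing.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    current = dict(initial_annotations)
    for it in range(1, max_iters + 1):
        pgg = build_pgg(current.values(), core_threshold)
        new = {
            gid: annotate_genome(
                pgg, medoid_index, gid, genomes[gid], search, min_identity, min_coverage
            )
            for gid in sorted(genomes)
        }
        if _walk_state(new) == _walk_state(current):
            return IterationResult(build_pgg(new.values(), core_threshold), new, it, True)
        current = new
    warnings.warn(
        f"pan-genome graph did not stabilize within {max_iters} iterations",
        RuntimeWarning,
        stacklevel=2,
    )
    return IterationResult(
        build_pgg(current.values(), core_threshold), current, max_iters, False
    )
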
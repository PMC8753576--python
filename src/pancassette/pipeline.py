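"""End-to-end orchestration: genes -> OGCs -> cassettes -> clades -> patterns.

This module wires the stages together the way a full analysis runs them:
all-vs-all nucleotide homology (k-mer prefilter plus edlib global
alignment) feeds OGC clustering; gene calls plus cluster assignments give
initial genome annotations; anchor OGCs are located by their gene product
names; cassettes, the presence matrix, Jaccard clades, minhash ANI,
region partitions, the subpattern table and recombination candidates
follow.  The built-in aligners are simple global/infix edit-distance
scorers — external BLAST tabular output can be substituted at the match
interfaces wherever deeper sensitivity is needed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .cassette import Cassette, cassette_presence_matrix, locate_cassette, repair_split_cassette
from .clades import (
    CladeAssignment,
    Dendrogram,
    DistanceMatrix,
    PresenceMatrix,
    ani_distance_matrix,
    complete_linkage,
    cut_clades,
    presence_jaccard_matrix,
)
from .orthologs import (
    OrthologGroup,
    ProteinMatch,
    filter_matches,
    group_strain_count,
    merge_groups,
    translate_medoids,
    weak_matches,
)
from .pangraph import (
    OGC,
    Gene,
    GenomeAnnotation,
    HomologyMatch,
    Placement,
    cluster_ogcs,
)
from .patterns import (
    OGCPattern,
    RecombinationCandidate,
    SubpatternTable,
    conserved_adjacent_pairs,
    partition_regions,
    recombination_candidates,
    subpattern_clade_table,
)

__all__ = [
    "nucleotide_matches",
    "annotations_from_genes",
    "anchor_ogcs_by_product",
    "medoid_sequences",
    "ogc_clade_map",
    "protein_matches_from_sequences",
    "CassettePipelineResult",
    "run_cassette_pipeline",
    "evaluate_candidates",
]


def _sampled_kmers(seq: str, k: int, keep_mod: int) -> set[int]:
    data = seq.encode("ascii")
    out = set()
    for i in range(0, len(data) - k + 1):
        h = zlib.crc32(data[i : i + k])  # stable across processes
        if h % keep_mod == 0:
            out.add(h)
    return out


def nucleotide_matches(
    genes: Sequence[Gene],
    k: int = 15,
    keep_mod: int = 4,
    min_report_identity: float = 85.0,
) -> list[HomologyMatch]:
    """All-vs-all nucleotide homology with a shared-k-mer prefilter.

    Candidate pairs share at least one sampled k-mer (every ``keep_mod``-th
    by hash) on the coding strand; each candidate pair is scored by edlib
    global alignment.  Reported identity is ``100 (1 - d / max(len))`` —
    a conservative lower bound — with coverage ``min(len)/own len`` and a
    bitscore proxy of matched positions.  Pairs below
    ``min_report_identity`` are not reported at all.
    """
    index: dict[int, list[int]] = {}
    kmer_sets = []
    for gi, g in enumerate(genes):
        ks = _sampled_kmers(g.sequence, k, keep_mod)
        kmer_sets.append(ks)
        for h in ks:
            index.setdefault(h, []).append(gi)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) < 2:
            continue
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                pairs.add((hits[ai], hits[bi]))
    matches: list[HomologyMatch] = []
    for ai, bi in sorted(pairs):
        a, b = genes[ai], genes[bi]
        la, lb = len(a.sequence), len(b.sequence)
        longer = max(la, lb)
        kband = int((1.0 - min_report_identity / 100.0) * longer) + 1
        res = edlib.align(a.sequence, b.sequence, mode="NW", task="distance", k=kband)
        dist = res["editDistance"]
        if dist < 0:
            continue  # beyond the banded distance: below reporting threshold
        identity = 100.0 * (1.0 - dist / longer)
        if identity < min_report_identity:
            continue
        score = float(longer - dist)
        matches.append(
            HomologyMatch(
                query_gene_id=a.gene_id,
                subject_gene_id=b.gene_id,
                percent_identity=identity,
                query_coverage=min(la, lb) / la,
                subject_coverage=min(la, lb) / lb,
                bitscore=score,
            )
        )
    return matches


def annotations_from_genes(
    genes: Iterable[Gene], ogcs: Iterable[OGC]
) -> dict[str, GenomeAnnotation]:
    """Initial annotations: gene coordinates plus cluster assignments."""
    ogc_of_gene = {
        gid: ogc.ogc_id for ogc in ogcs for gid in ogc.members
    }
    per_genome: dict[str, dict[str, list[Placement]]] = {}
    for g in genes:
        per_genome.setdefault(g.genome_id, {}).setdefault(g.contig_id, []).append(
            Placement(ogc_of_gene[g.gene_id], g.start, g.end, g.strand)
        )
    return {
        gid: GenomeAnnotation.build(gid, contigs)
        for gid, contigs in sorted(per_genome.items())
    }


def anchor_ogcs_by_product(
    genes: Iterable[Gene], ogcs: Iterable[OGC], products: tuple[str, str]
) -> tuple[int, int]:
    """Find the anchor OGC ids from the anchor genes' product annotations."""
    ogc_of_gene = {gid: ogc.ogc_id for ogc in ogcs for gid in ogc.members}
    found: dict[str, set[int]] = {p: set() for p in products}
    for g in genes:
        if g.product in found:
            found[g.product].add(ogc_of_gene[g.gene_id])
    out = []
    for p in products:
        if len(found[p]) != 1:
            raise ValueError(
                f"anchor product {p!r} maps to {len(found[p])} OGCs; expected exactly 1"
            )
        out.append(found[p].pop())
    return out[0], out[1]


def ogc_ids_with_product(
    genes: Iterable[Gene], ogcs: Iterable[OGC], product_substring: str
) -> set[int]:
    """OGC ids whose member genes carry a product annotation substring.

    Used to identify IS-element OGCs ("transposase") for split repair the
    same way anchors are identified: from the functional annotation, not
    from ground truth.
    """
    ogc_of_gene = {gid: ogc.ogc_id for ogc in ogcs for gid in ogc.members}
    return {
        ogc_of_gene[g.gene_id]
        for g in genes
        if product_substring.lower() in g.product.lower()
    }


def medoid_sequences(ogcs: Iterable[OGC], genes_by_id: Mapping[str, Gene]) -> dict[int, str]:
    return {o.ogc_id: genes_by_id[o.medoid_gene_id].sequence for o in ogcs}


def ogc_clade_map(presence: PresenceMatrix, clades: CladeAssignment) -> dict[int, str]:
    """Clade of each cassette OGC: majority clade among carrying strains."""
    out: dict[int, str] = {}
    for j, ogc in enumerate(presence.ogcs):
        carriers = [presence.strains[i] for i in np.flatnonzero(presence.values[:, j])]
        counts: dict[str, int] = {}
        for s in carriers:
            c = clades.clades[s]
            counts[c] = counts.get(c, 0) + 1
        out[ogc] = min(counts, key=lambda c: (-counts[c], c))
    return out


def protein_matches_from_sequences(proteins: Mapping[int, str]) -> list[ProteinMatch]:
    """All-vs-all peptide comparison of OGC medoid translations.

    Symmetric pairs are emitted in both directions with a global
    edit-distance identity lower bound and a matched-positions bitscore
    proxy, mirroring the shape of tabular protein-BLAST output.
    """
    out: list[ProteinMatch] = []
    ids = sorted(proteins)
    for i, q in enumerate(ids):
        for s in ids[i + 1 :]:
            pq, ps = proteins[q], proteins[s]
            longer = max(len(pq), len(ps))
            res = edlib.align(pq, ps, mode="NW", task="distance")
            identity = 100.0 * (1.0 - res["editDistance"] / longer)
            if identity <= 0:
                continue
            score = float(longer - res["editDistance"])
            for a, b, la, lb in ((q, s, len(pq), len(ps)), (s, q, len(ps), len(pq))):
                out.append(
                    ProteinMatch(
                        query_ogc=a,
                        subject_ogc=b,
                        percent_identity=identity,
                        match_len=min(la, lb),
                        query_len=la,
                        subject_len=lb,
                        bitscore=score,
                    )
                )
    return out


@dataclass
class CassettePipelineResult:
    """Everything the gene-content pipeline computes, stage by stage."""

    ogcs: list[OGC]
    annotations: dict[str, GenomeAnnotation]
    anchors: tuple[int, int]
    cassettes: dict[str, Cassette]
    presence: PresenceMatrix
    jaccard: DistanceMatrix
    content_dendrogram: Dendrogram
    clades: CladeAssignment
    ani: DistanceMatrix | None
    ani_dendrogram: Dendrogram | None
    patterns: dict[str, OGCPattern]
    pairs: list[tuple[int, int]]
    partitions: dict[str, list]
    table: SubpatternTable
    candidates: list[RecombinationCandidate]
    ortholog_groups: list[OrthologGroup] = field(default_factory=list)
    group_counts: dict[int, int] = field(default_factory=dict)
    weak_protein_matches: list[ProteinMatch] = field(default_factory=list)


def run_cassette_pipeline(
    genes: Sequence[Gene],
    genomes: Mapping[str, Mapping[str, str]] | None = None,
    anchor_products: tuple[str, str] = ("yvyE", "ribZB"),
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
    cut_method: str = "max_gap",
    cut_k: int | None = None,
    repair_is: Mapping[str, int | set] | None = None,
    ani_sketch_size: int = 10000,
    ani_k: int = 21,
    merge_proteins: bool = True,
    neighbour_q: int = 3,
) -> CassettePipelineResult:
    """Run the full gene-content analysis on annotated genomes.

    ``repair_is`` maps strain -> IS OGC id(s) for strains whose cassette
    needs IS-inversion split repair before extraction.  ANI stages are
    skipped when ``genomes`` is None (then no outlier candidates are
    produced).  ``ani_sketch_size`` defaults high enough that sketches of
    small genomes are exhaustive.
    """
    matches = nucleotide_matches(genes)
    ogcs = cluster_ogcs(genes, matches, min_identity, min_coverage)
    genes_by_id = {g.gene_id: g for g in genes}
    annotations = annotations_from_genes(genes, ogcs)
    left, right = anchor_ogcs_by_product(genes, ogcs, anchor_products)

    cassettes: dict[str, Cassette] = {}
    for strain in sorted(annotations):
        if repair_is and strain in repair_is:
            cassettes[strain] = repair_split_cassette(
                annotations[strain], left, right, repair_is[strain]
            )
        else:
            cassettes[strain] = locate_cassette(annotations[strain], left, right)

    presence = cassette_presence_matrix(cassettes.values())
    jaccard = presence_jaccard_matrix(presence)
    content_dend = complete_linkage(jaccard)
    if cut_method == "k":
        clade_assignment = cut_clades(content_dend, method="k", k=cut_k)
    else:
        clade_assignment = cut_clades(content_dend, method=cut_method)

    ani = ani_dend = None
    if genomes is not None:
        ani = ani_distance_matrix(genomes, k=ani_k, sketch_size=ani_sketch_size)
        ani_dend = complete_linkage(ani)

    patterns = {
        s: OGCPattern(s, tuple(c.walk)) for s, c in sorted(cassettes.items())
    }
    pairs = conserved_adjacent_pairs(patterns.values())
    partitions = {
        s: partition_regions(p, (left, right), pairs) for s, p in patterns.items()
    }
    table = subpattern_clade_table(partitions, clade_assignment)
    if ani is not None:
        candidates = recombination_candidates(table, clade_assignment, ani, q=neighbour_q)
    else:
        candidates = recombination_candidates(
            table, clade_assignment, jaccard, q=neighbour_q, include_outliers=False
        )

    groups: list[OrthologGroup] = []
    group_counts: dict[int, int] = {}
    weak: list[ProteinMatch] = []
    if merge_proteins:
        med = medoid_sequences(ogcs, genes_by_id)
        cassette_ogc_ids = set(presence.ogcs)
        proteins = translate_medoids(
            {o: s for o, s in med.items() if o in cassette_ogc_ids}
        )
        pmatches = protein_matches_from_sequences(proteins)
        clade_of_ogc = ogc_clade_map(presence, clade_assignment)
        retained = filter_matches(pmatches, clade_of_ogc)
        weak = weak_matches(pmatches)
        groups = merge_groups(retained, sorted(cassette_ogc_ids))
        group_counts = {
            g.group_id: group_strain_count(g, presence) for g in groups
        }

    return CassettePipelineResult(
        ogcs=ogcs,
        annotations=annotations,
        anchors=(left, right),
        cassettes=cassettes,
        presence=presence,
        jaccard=jaccard,
        content_dendrogram=content_dend,
        clades=clade_assignment,
        ani=ani,
        ani_dendrogram=ani_dend,
        patterns=patterns,
        pairs=pairs,
        partitions=partitions,
        table=table,
        candidates=candidates,
        ortholog_groups=groups,
        group_counts=group_counts,
        weak_protein_matches=weak,
    )


def evaluate_candidates(
    candidates: Sequence[RecombinationCandidate],
    truth_events: Sequence[Mapping],
    region_order: Sequence[str] | None = None,
) -> dict[str, float]:
    """Precision/recall of candidates against simulator truth events.

    A predicted region candidate matches a true region event when it
    flags the same region (matched positionally via ``region_order``,
    since pipeline region labels are built from pipeline OGC ids while
    truth events record region indices) and the event's recipient strain
    is among the candidate's minority-clade strains.  A predicted outlier
    matches a true whole-cassette event when the strain is the event's
    recipient.  Returns precision and recall per kind (1.0 when nothing
    was predicted and nothing was true).
    """
    true_region = [e for e in truth_events if e["kind"] == "region"]
    true_whole = [e for e in truth_events if e["kind"] == "whole_cassette"]
    pred_region = [c for c in candidates if c.kind == "region"]
    pred_outlier = [c for c in candidates if c.kind == "outlier_strain"]

    def region_match(c: RecombinationCandidate, e: Mapping) -> bool:
        if region_order is not None and c.region_label in region_order:
            same_region = region_order.index(c.region_label) == e["region_index"]
        else:
            same_region = c.region_label == e.get("region_label")
        return same_region and e["recipient_strain"] in c.strains

    region_tp_pred = sum(
        1 for c in pred_region if any(region_match(c, e) for e in true_region)
    )
    region_recalled = sum(
        1 for e in true_region if any(region_match(c, e) for c in pred_region)
    )
    outlier_tp_pred = sum(
        1
        for c in pred_outlier
        if any(e["recipient_strain"] == c.strains[0] for e in true_whole)
    )
    outlier_recalled = sum(
        1
        for e in true_whole
        if any(c.strains[0] == e["recipient_strain"] for c in pred_outlier)
    )

    def ratio(num: int, den: int) -> float:
        return 1.0 if den == 0 else num / den

    return {
        "region_precision": ratio(region_tp_pred, len(pred_region)),
        "region_recall": ratio(region_recalled, len(true_region)),
        "outlier_precision": ratio(outlier_tp_pred, len(pred_outlier)),
        "outlier_recall": ratio(outlier_recalled, len(true_whole)),
    }
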
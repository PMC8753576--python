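"""Protein-level merging of OGCs into ortholog groups.

Strict nucleotide clustering (90%/90%) splits diverged orthologs across
several OGCs.  Translating each OGC's medoid and comparing the peptides
all-vs-all recovers the deeper orthology: matches are retained at >=40%
identity over >=80% of the shorter protein, a paralog cut truncates each
query's match list at the first same-clade subject, and ortholog groups
are the connected components of the retained matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio.Seq import Seq

from .clades import PresenceMatrix

__all__ = [
    "ProteinMatch",
    "OrthologGroup",
    "translate_medoids",
    "filter_matches",
    "weak_matches",
    "merge_groups",
    "group_strain_count",
]


@dataclass(frozen=True)
class ProteinMatch:
    """A directed peptide-level match between two OGC medoids."""

    query_ogc: int
    subject_ogc: int
    percent_identity: float
    match_len: int
    query_len: int
    subject_len: int
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.query_len <= 0 or self.subject_len <= 0:
            raise ValueError("protein lengths must be positive")
        if self.match_len > max(self.query_len, self.subject_len):
            raise ValueError("match_len exceeds both protein lengths")


@dataclass(frozen=True)
class OrthologGroup:
    group_id: int
    member_ogcs: frozenset[int]
    summed_strain_count: int = 0
    label: str | None = None


def translate_medoids(
    medoid_sequences: Mapping[int, str], genetic_code: int = 11
) -> dict[int, str]:
    """Translate each OGC medoid nucleotide sequence into a peptide.

    A trailing stop codon is removed; a length not divisible by three or
    an internal stop raises an error naming the offending OGC.
    ``genetic_code`` is an NCBI translation table id (11 = bacterial).
    """
    proteins: dict[int, str] = {}
    for ogc_id in sorted(medoid_sequences):
        nt = medoid_sequences[ogc_id]
        if len(nt) % 3 != 0:
            raise ValueError(
                f"OGC {ogc_id}: medoid length {len(nt)} is not divisible by 3"
            )
        aa = str(Seq(nt).translate(table=genetic_code))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise ValueError(f"OGC {ogc_id}: internal stop codon in medoid")
        proteins[ogc_id] = aa
    return proteins


def _passes(m: ProteinMatch, min_identity: float, min_shorter_cov: float) -> bool:
    shorter = min(m.query_len, m.subject_len)
    return (
        m.percent_identity >= min_identity
        and m.match_len >= min_shorter_cov * shorter
    )


def filter_matches(
    matches: Iterable[ProteinMatch],
    clade_of: Mapping[int, str],
    min_identity: float = 40.0,
    min_shorter_cov: float = 0.8,
    paralog_rule: str = "truncate_after_first",
) -> list[ProteinMatch]:
    """Apply the retention thresholds and the paralog cut.

    Self matches are removed; a match survives the thresholds iff its
    percent identity is >= ``min_identity`` and its match length covers at
    least ``min_shorter_cov`` of the shorter protein.  Per query, matches
    are scanned in descending bitscore (ties by ascending subject OGC id):

    - ``"truncate_after_first"`` (default): the first match whose subject
      clade repeats a clade already accepted for this query is itself kept
      (it has the larger bitscore of the paralogous pair), but every match
      after it is dropped.
    - ``"per_clade_best"``: only the repeated-clade match itself is
      dropped; later matches to new clades survive.
    """
    if paralog_rule not in ("truncate_after_first", "per_clade_best"):
        raise ValueError(f"unknown paralog_rule {paralog_rule!r}")
    out: list[ProteinMatch] = []
    per_query: dict[int, list[ProteinMatch]] = {}
    for m in matches:
        for ogc in (m.query_ogc, m.subject_ogc):
            if ogc not in clade_of:
                raise ValueError(f"OGC {ogc} has no clade assignment")
        if m.query_ogc == m.subject_ogc:
            continue
        if not _passes(m, min_identity, min_shorter_cov):
            continue
        per_query.setdefault(m.query_ogc, []).append(m)
    for query in sorted(per_query):
        ranked = sorted(per_query[query], key=lambda m: (-m.bitscore, m.subject_ogc))
        seen_clades: set[str] = set()
        for m in ranked:
            clade = clade_of[m.subject_ogc]
            if clade in seen_clades:
                out.append(m)  # the paralog itself is retained ...
                if paralog_rule == "truncate_after_first":
                    break  # ... but nothing ranked after it
                out.pop()  # per_clade_best: drop just the repeated-clade match
                continue
            seen_clades.add(clade)
            out.append(m)
    return out


def weak_matches(
    matches: Iterable[ProteinMatch],
    min_identity: float = 40.0,
    min_shorter_cov: float = 0.8,
    weak_min_identity: float = 25.0,
    weak_min_shorter_cov: float = 0.3,
) -> list[ProteinMatch]:
    """Matches failing the ortholog thresholds but passing looser ones.

    These are reported separately (e.g. ``weak_matches.tsv``) for manual
    inspection and are never merged into ortholog groups.
    """
    out = []
    for m in matches:
        if m.query_ogc == m.subject_ogc:
            continue
        if _passes(m, min_identity, min_shorter_cov):
            continue
        if _passes(m, weak_min_identity, weak_min_shorter_cov):
            out.append(m)
    return sorted(out, key=lambda m: (m.query_ogc, m.subject_ogc))


def merge_groups(
    retained: Iterable[ProteinMatch], universe: Iterable[int]
) -> list[OrthologGroup]:
    """Connected components of retained matches over the OGC universe.

    An undirected edge exists if the pair was retained in either
    direction.  OGCs with no retained match form singleton groups.  Group
    ids are assigned in ascending order of each group's smallest OGC id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(universe))
    for m in retained:
        if m.query_ogc not in graph or m.subject_ogc not in graph:
            raise ValueError("retained match references an OGC outside the universe")
        graph.add_edge(m.query_ogc, m.subject_ogc)
    comps = sorted(nx.connected_components(graph), key=min)
    return [
        OrthologGroup(group_id=i, member_ogcs=frozenset(c))
        for i, c in enumerate(comps, start=1)
    ]


def group_strain_count(
    group: OrthologGroup | Iterable[int], presence: PresenceMatrix
) -> int:
    """Number of strains containing at least one member OGC of the group."""
    ogcs = sorted(group.member_ogcs if isinstance(group, OrthologGroup) else group)
    col_index = {o: j for j, o in enumerate(presence.ogcs)}
    missing = [o for o in ogcs if o not in col_index]
    if missing:
        raise ValueError(f"OGCs absent from the presence matrix: {missing}")
    cols = [col_index[o] for o in ogcs]
    return int(presence.values[:, cols].any(axis=1).sum())
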
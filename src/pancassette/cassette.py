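"""Extraction of anchored gene cassettes from genome annotations.

A cassette is the ordered OGC walk of one strain strictly between two
single-copy core anchor OGCs on one contig.  Walks are orientation
normalized so they always read left anchor to right anchor, and a cassette
split by an inversion between two inverted IS-element copies can be
repaired by virtually undoing the inversion before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .clades import PresenceMatrix
from .pangraph import GenomeAnnotation, Placement

__all__ = [
    "Cassette",
    "locate_cassette",
    "repair_split_cassette",
    "invert_between_is",
    "cassette_presence_matrix",
]

_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class Cassette:
    """One strain's orientation-normalized cassette walk.

    ``walk`` lists the OGC ids strictly between the anchors (repeats
    allowed); ``strands`` gives each walk member's strand after
    normalization.  ``source_intervals`` records the genomic interval(s)
    the walk was read from: one interval normally, two when the cassette
    was repaired from an inversion split.
    """

    genome_id: str
    left_anchor: int
    right_anchor: int
    walk: tuple[int, ...]
    strands: tuple[str, ...]
    strand_normalized: bool = True
    split_repaired: bool = False
    source_intervals: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.left_anchor in self.walk or self.right_anchor in self.walk:
            raise ValueError("anchors must not appear inside the walk")
        if len(self.walk) != len(self.strands):
            raise ValueError("walk and strands must have equal length")
        if self.split_repaired and len(self.source_intervals) != 2:
            raise ValueError("a split-repaired cassette records two source intervals")


def _anchor_placement(
    annotation: GenomeAnnotation, anchor: int
) -> tuple[str, int, Placement]:
    """Locate the unique placement of an anchor OGC; informative errors."""
    found: list[tuple[str, int, Placement]] = []
    for contig, pls in annotation.placements.items():
        for i, p in enumerate(pls):
            if p.ogc_id == anchor:
                found.append((contig, i, p))
    if not found:
        raise ValueError(
            f"anchor OGC {anchor} is not placed in genome {annotation.genome_id}"
        )
    if len(found) > 1:
        raise ValueError(
            f"anchor OGC {anchor} is placed {len(found)} times in genome "
            f"{annotation.genome_id}; anchors must be single copy"
        )
    return found[0]


def locate_cassette(
    annotation: GenomeAnnotation,
    left_anchor: int,
    right_anchor: int,
    split_repaired: bool = False,
    source_intervals: tuple[tuple[str, int, int, str], ...] | None = None,
) -> Cassette:
    """Extract the OGC walk strictly between two anchor OGCs.

    If the anchors occur in descending coordinate order the cassette lies
    on the minus strand: the walk is reversed and strands flipped so the
    output always reads left anchor to right anchor.
    """
    lc, li, lp = _anchor_placement(annotation, left_anchor)
    rc, ri, rp = _anchor_placement(annotation, right_anchor)
    if lc != rc:
        raise ValueError(
            f"anchors {left_anchor} and {right_anchor} lie on different contigs "
            f"({lc!r} vs {rc!r}) in genome {annotation.genome_id}; if an IS "
            "inversion split the cassette, use repair_split_cassette"
        )
    pls = annotation.placements[lc]
    if li < ri:
        between = pls[li + 1 : ri]
        walk = tuple(p.ogc_id for p in between)
        strands = tuple(p.strand for p in between)
        reading = "+"
        span = (lp.end, rp.start)
    else:
        between = pls[ri + 1 : li]
        walk = tuple(p.ogc_id for p in reversed(between))
        strands = tuple(_FLIP[p.strand] for p in reversed(between))
        reading = "-"
        span = (rp.end, lp.start)
    if source_intervals is None:
        source_intervals = ((lc, span[0], span[1], reading),)
    return Cassette(
        genome_id=annotation.genome_id,
        left_anchor=left_anchor,
        right_anchor=right_anchor,
        walk=walk,
        strands=strands,
        strand_normalized=True,
        split_repaired=split_repaired,
        source_intervals=source_intervals,
    )


def _is_placements(
    annotation: GenomeAnnotation, is_ogc: int | Iterable[int]
) -> tuple[str, int, int]:
    """Find exactly two inverted IS placements; return (contig, idx1, idx2)."""
    is_set = {is_ogc} if isinstance(is_ogc, int) else set(is_ogc)
    found: list[tuple[str, int, Placement]] = []
    for contig, pls in annotation.placements.items():
        for i, p in enumerate(pls):
            if p.ogc_id in is_set:
                found.append((contig, i, p))
    if len(found) != 2:
        raise ValueError(
            f"split repair assumes exactly two IS copies of {sorted(is_set)}; "
            f"found {len(found)} in genome {annotation.genome_id}"
        )
    (c1, i1, p1), (c2, i2, p2) = found
    if c1 != c2:
        raise ValueError("the two IS copies must lie on one contig")
    if p1.strand == p2.strand:
        raise ValueError(
            "split repair assumes the IS copies are in inverted orientation "
            f"(both are {p1.strand!r} in genome {annotation.genome_id})"
        )
    return c1, min(i1, i2), max(i1, i2)


def invert_between_is(
    annotation: GenomeAnnotation, is_ogc: int | Iterable[int]
) -> GenomeAnnotation:
    """Virtually invert the segment strictly between two inverted IS copies.

    Placements between the copies are mirrored in coordinate space, their
    order reversed and strands flipped; everything else (including the IS
    copies themselves) is untouched.  Applying the operation twice is the
    identity.
    """
    contig, i1, i2 = _is_placements(annotation, is_ogc)
    pls = list(annotation.placements[contig])
    lo = pls[i1].end
    hi = pls[i2].start
    segment = pls[i1 + 1 : i2]
    mirrored = [
        Placement(p.ogc_id, lo + (hi - p.end), lo + (hi - p.start), _FLIP[p.strand])
        for p in reversed(segment)
    ]
    new_pls = pls[: i1 + 1] + mirrored + pls[i2:]
    placements = {c: v for c, v in annotation.placements.items()}
    placements[contig] = tuple(new_pls)
    return GenomeAnnotation.build(annotation.genome_id, placements)


def repair_split_cassette(
    annotation: GenomeAnnotation,
    left_anchor: int,
    right_anchor: int,
    is_ogc: int | Iterable[int],
) -> Cassette:
    """Undo an IS-mediated inversion and extract the cassette as one piece.

    Assumes exactly two placements of ``is_ogc`` in inverted orientation on
    one contig (one copy inside the cassette, one outside); the segment
    between them is virtually re-inverted, after which the cassette is
    extracted as usual.  The repaired walk contains the interior IS copy at
    its pre-inversion position.  ``is_ogc`` may be a single OGC id or a
    set of ids (identical IS copies can be assigned to different OGCs by
    strict clustering).
    """
    repaired = invert_between_is(annotation, is_ogc)
    contig, i1, i2 = _is_placements(repaired, is_ogc)
    pls = repaired.placements[contig]
    lp = next(p for p in pls if p.ogc_id == left_anchor)
    pieces = (
        (contig, lp.end, pls[i1].start, "+"),
        (contig, pls[i1].end, pls[i2].start, "+"),
    )
    return locate_cassette(
        repaired,
        left_anchor,
        right_anchor,
        split_repaired=True,
        source_intervals=pieces,
    )


def cassette_presence_matrix(
    cassettes: Iterable[Cassette], include_anchors: bool = False
) -> PresenceMatrix:
    """Strain x OGC boolean presence over all cassette walks.

    Columns are the ascending union of all OGCs observed in any walk;
    repeats within a walk collapse to a single presence.  The bounding
    anchors are excluded by default (they are core by construction);
    ``include_anchors=True`` adds their always-true columns.
    """
    cassettes = list(cassettes)
    if not cassettes:
        raise ValueError("need at least one cassette")
    strains: list[str] = []
    seen: set[str] = set()
    for c in cassettes:
        if c.genome_id in seen:
            raise ValueError(f"duplicate genome {c.genome_id}")
        seen.add(c.genome_id)
        strains.append(c.genome_id)
    strains = sorted(strains)
    tokens = {o for c in cassettes for o in c.walk}
    if include_anchors:
        tokens |= {c.left_anchor for c in cassettes}
        tokens |= {c.right_anchor for c in cassettes}
    ogcs = sorted(tokens)
    col = {o: j for j, o in enumerate(ogcs)}
    row = {s: i for i, s in enumerate(strains)}
    values = np.zeros((len(strains), len(ogcs)), dtype=bool)
    for c in cassettes:
        seen = list(c.walk)
        if include_anchors:
            seen += [c.left_anchor, c.right_anchor]
        for o in seen:
            values[row[c.genome_id], col[o]] = True
    return PresenceMatrix(strains, ogcs, values)
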
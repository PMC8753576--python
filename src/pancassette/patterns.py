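"""OGC pattern and subpattern analysis of cassette walks.

An OGC pattern is the ordered list of OGC ids across a strain's cassette.
Conserved adjacent OGC pairs — pairs adjacent, in order, exactly once in
every strain — partition the cassette into regions; the per-region
subpatterns, tabulated against gene-content clades, expose sub-cassette
homologous recombination (a subpattern shared by several clades) while
clade-vs-ANI discordance flags whole-cassette transfers.

Subpatterns are printed as a parenthesized comma-separated token list in
which maximal runs of consecutive ids (ascending or descending) compress
to "first-last"; the empty subpattern is "()".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clades import CladeAssignment, DistanceMatrix

__all__ = [
    "OGCPattern",
    "RegionPartition",
    "SubpatternTable",
    "RecombinationCandidate",
    "format_subpattern",
    "parse_subpattern",
    "conserved_adjacent_pairs",
    "partition_regions",
    "reconstruct_pattern",
    "subpattern_clade_table",
    "collapse_identical_patterns",
    "expand_collapsed_patterns",
    "recombination_candidates",
]


@dataclass(frozen=True)
class OGCPattern:
    """One strain's cassette walk (anchors excluded)."""

    genome_id: str
    tokens: tuple[int, ...]


@dataclass(frozen=True)
class RegionPartition:
    """Boundary OGCs (anchors plus conserved-pair members) and region labels."""

    boundaries: tuple[int, ...]
    region_labels: tuple[str, ...]


def format_subpattern(tokens: Sequence[int]) -> str:
    """Render a token list, hyphen-compressing consecutive runs.

    Maximal runs of consecutively numbered OGCs (step +1 or -1, length at
    least two) become "first-last"; other tokens are comma separated; an
    empty list renders as "()".
    """
    tokens = list(tokens)
    parts: list[str] = []
    i = 0
    while i < len(tokens):
        j = i
        if i + 1 < len(tokens) and abs(tokens[i + 1] - tokens[i]) == 1:
            step = tokens[i + 1] - tokens[i]
            j = i + 1
            while j + 1 < len(tokens) and tokens[j + 1] - tokens[j] == step:
                j += 1
        if j > i:
            parts.append(f"{tokens[i]}-{tokens[j]}")
        else:
            parts.append(str(tokens[i]))
        i = j + 1
    return "(" + ",".join(parts) + ")"


_ITEM_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def parse_subpattern(s: str) -> list[int]:
    """Inverse of :func:`format_subpattern`; errors carry the position."""
    if not (s.startswith("(") and s.endswith(")")):
        raise ValueError(f"subpattern must be parenthesized: {s!r} (position 0)")
    body = s[1:-1]
    if body.strip() == "":
        return []
    tokens: list[int] = []
    pos = 1
    for item in body.split(","):
        m = _ITEM_RE.match(item.strip())
        if m is None:
            raise ValueError(f"malformed subpattern item {item!r} at position {pos}")
        a = int(m.group(1))
        if m.group(2) is None:
            tokens.append(a)
        else:
            b = int(m.group(2))
            step = 1 if b >= a else -1
            tokens.extend(range(a, b + step, step))
        pos += len(item) + 1
    return tokens


def conserved_adjacent_pairs(
    patterns: Iterable[OGCPattern],
) -> list[tuple[int, int]]:
    """Ordered pairs (x, y) adjacent exactly once in every strain's pattern.

    A pair qualifies iff every pattern contains x exactly once, y exactly
    once, and y immediately follows x.  Pairs are returned in the order
    they appear in the first pattern.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("need at least one pattern")
    first = patterns[0].tokens
    candidates = [(first[i], first[i + 1]) for i in range(len(first) - 1)]
    out = []
    for x, y in candidates:
        ok = True
        for p in patterns:
            toks = p.tokens
            if toks.count(x) != 1 or toks.count(y) != 1:
                ok = False
                break
            i = toks.index(x)
            if i + 1 >= len(toks) or toks[i + 1] != y:
                ok = False
                break
        if ok:
            out.append((x, y))
    return out


def partition_regions(
    pattern: OGCPattern,
    anchors: tuple[int, int],
    pairs: Sequence[tuple[int, int]],
) -> list[tuple[str, tuple[int, ...]]]:
    """Split an anchored pattern into regions between conserved pairs.

    With anchors (L, R) and conserved pairs (p1a,p1b) .. (pma,pmb) the
    boundary blocks are [L], [p1a,p1b], ..., [R]; region k spans the tokens
    strictly between consecutive blocks and is labelled
    "<right token of left block>-<left token of right block>" (for the
    study layout: 3712-3721, 3722-3749, 3750-3753, 3754-3756).
    Concatenating blocks and regions in order reconstructs the full
    anchored pattern; a missing or duplicated boundary OGC is an error.
    """
    left, right = anchors
    full = (left,) + tuple(pattern.tokens) + (right,)
    blocks: list[tuple[int, ...]] = [(left,)] + [tuple(p) for p in pairs] + [(right,)]
    positions: list[tuple[int, int]] = []  # (start_idx, end_idx) per block
    for block in blocks:
        for ogc in block:
            c = full.count(ogc)
            if c != 1:
                raise ValueError(
                    f"boundary OGC {ogc} occurs {c} times in strain "
                    f"{pattern.genome_id}; regions require exactly one"
                )
        i = full.index(block[0])
        if tuple(full[i : i + len(block)]) != block:
            raise ValueError(
                f"conserved pair {block} is not adjacent in strain {pattern.genome_id}"
            )
        positions.append((i, i + len(block)))
    starts = [p[0] for p in positions]
    if starts != sorted(starts):
        raise ValueError(
            f"boundary blocks out of order in strain {pattern.genome_id}"
        )
    regions = []
    for (la, lb), (ra, rb), lblock, rblock in zip(
        positions, positions[1:], blocks, blocks[1:]
    ):
        label = f"{lblock[-1]}-{rblock[0]}"
        regions.append((label, tuple(full[lb:ra])))
    return regions


def reconstruct_pattern(
    regions: Sequence[tuple[str, tuple[int, ...]]],
    anchors: tuple[int, int],
    pairs: Sequence[tuple[int, int]],
) -> tuple[int, ...]:
    """Concatenate boundary blocks and region tokens (round-trip check)."""
    blocks = [(anchors[0],)] + [tuple(p) for p in pairs] + [(anchors[1],)]
    out: list[int] = list(blocks[0])
    for (label, tokens), block in zip(regions, blocks[1:]):
        out.extend(tokens)
        out.extend(block)
    return tuple(out)


@dataclass
class SubpatternTable:
    """Region x subpattern x clade strain counts (machine-readable table).

    ``df`` has columns ``region``, ``subpattern`` and one count column per
    clade label; per-region column sums equal the clade sizes.
    ``strains`` maps (region, subpattern) to the sorted strains showing it.
    """

    df: pd.DataFrame
    clade_sizes: dict[str, int]
    region_order: list[str]
    strains: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def clade_labels(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("region", "subpattern")]


def subpattern_clade_table(
    partitions: Mapping[str, Sequence[tuple[str, tuple[int, ...]]]],
    clades: CladeAssignment | Mapping[str, str],
) -> SubpatternTable:
    """Count strains per (region, subpattern, clade).

    Rows are ordered by region (cassette order), then descending total
    count, then subpattern string.  Every strain must appear in both
    inputs.
    """
    clade_of = clades.clades if isinstance(clades, CladeAssignment) else dict(clades)
    if set(partitions) != set(clade_of):
        missing = set(partitions) ^ set(clade_of)
        raise ValueError(f"strains present in only one input: {sorted(missing)}")
    region_order: list[str] = []
    for strain in sorted(partitions):
        labels = [label for label, _ in partitions[strain]]
        if not region_order:
            region_order = labels
        elif labels != region_order:
            raise ValueError(f"inconsistent region labels for strain {strain}")
    clade_labels = sorted(set(clade_of.values()))
    counts: dict[tuple[str, str], dict[str, int]] = {}
    strains_of: dict[tuple[str, str], list[str]] = {}
    for strain in sorted(partitions):
        clade = clade_of[strain]
        for label, tokens in partitions[strain]:
            sp = format_subpattern(tokens)
            row = counts.setdefault((label, sp), {c: 0 for c in clade_labels})
            row[clade] += 1
            strains_of.setdefault((label, sp), []).append(strain)
    records = []
    for (label, sp), row in counts.items():
        records.append({"region": label, "subpattern": sp, **row})
    df = pd.DataFrame.from_records(records)
    df["_total"] = df[clade_labels].sum(axis=1)
    df["_region_rank"] = df["region"].map({r: i for i, r in enumerate(region_order)})
    df = df.sort_values(
        ["_region_rank", "_total", "subpattern"], ascending=[True, False, True]
    ).drop(columns=["_total", "_region_rank"]).reset_index(drop=True)
    sizes: dict[str, int] = {}
    for c in clade_of.values():
        sizes[c] = sizes.get(c, 0) + 1
    return SubpatternTable(df, sizes, region_order, strains_of)


def collapse_identical_patterns(
    patterns: Mapping[str, Sequence[int]],
) -> list[tuple[tuple[int, ...], int, list[str]]]:
    """Merge strains with identical full patterns into one row each.

    Returns (pattern, multiplicity, sorted strains) rows, ordered by
    descending multiplicity then pattern; lossless (see
    :func:`expand_collapsed_patterns`).
    """
    groups: dict[tuple[int, ...], list[str]] = {}
    for strain in sorted(patterns):
        groups.setdefault(tuple(patterns[strain]), []).append(strain)
    return sorted(
        ((pat, len(ss), sorted(ss)) for pat, ss in groups.items()),
        key=lambda row: (-row[1], row[0]),
    )


def expand_collapsed_patterns(
    rows: Iterable[tuple[tuple[int, ...], int, list[str]]],
) -> dict[str, tuple[int, ...]]:
    out: dict[str, tuple[int, ...]] = {}
    for pat, count, strains in rows:
        if count != len(strains):
            raise ValueError("multiplicity does not match strain list")
        for s in strains:
            out[s] = tuple(pat)
    return out


@dataclass(frozen=True)
class RecombinationCandidate:
    """Evidence of cassette-scale horizontal transfer.

    ``kind`` is ``"region"`` (a subpattern with nonzero counts in two or
    more clades) or ``"outlier_strain"`` (a strain whose gene-content
    clade is absent among its nearest ANI neighbours, consistent with a
    whole-cassette transfer).
    """

    kind: str
    strains: tuple[str, ...]
    region_label: str | None = None
    subpattern: str | None = None
    clade_counts: tuple[tuple[str, int], ...] = ()
    evidence: str = ""


def recombination_candidates(
    table: SubpatternTable,
    clades: CladeAssignment,
    ani_dist: DistanceMatrix,
    q: int = 3,
    include_outliers: bool = True,
) -> list[RecombinationCandidate]:
    """Report region-level and whole-cassette recombination candidates.

    Region candidates: every (region, subpattern) with nonzero counts in
    two or more clades, with the clades, counts and (when recorded in the
    table) the minority-clade strains showing the subpattern.

    Outlier candidates: strains whose gene-content clade does not appear
    at all among the clades of their ``q`` nearest ANI neighbours
    (distance ties broken by strain label).  Strains in singleton
    gene-content clades are skipped — with no clade-mate there is no ANI
    expectation to violate.  Ordering is deterministic: table order, then
    strain label.
    """
    out: list[RecombinationCandidate] = []
    clade_labels = table.clade_labels
    for _, row in table.df.iterrows():
        nonzero = [(c, int(row[c])) for c in clade_labels if row[c] > 0]
        if len(nonzero) < 2:
            continue
        majority = max(nonzero, key=lambda cc: cc[1])[0]
        key = (str(row["region"]), str(row["subpattern"]))
        shown = table.strains.get(key, [])
        minority_strains = tuple(
            s for s in shown if clades.clades[s] != majority
        )
        out.append(
            RecombinationCandidate(
                kind="region",
                strains=minority_strains,
                region_label=key[0],
                subpattern=key[1],
                clade_counts=tuple(nonzero),
                evidence=f"subpattern shared by {len(nonzero)} clades "
                f"(majority clade {majority})",
            )
        )
    if not include_outliers:
        return out
    sizes = clades.sizes()
    labels = ani_dist.labels
    index = {s: i for i, s in enumerate(labels)}
    for strain in sorted(clades.clades):
        own = clades.clades[strain]
        if sizes[own] < 2:
            continue
        i = index[strain]
        order = sorted(
            (s for s in labels if s != strain),
            key=lambda s: (ani_dist.values[i, index[s]], s),
        )
        neighbours = order[: min(q, len(order))]
        neighbour_clades = [clades.clades[s] for s in neighbours]
        if own not in neighbour_clades:
            out.append(
                RecombinationCandidate(
                    kind="outlier_strain",
                    strains=(strain,),
                    evidence=(
                        f"gene-content clade {own} absent among {len(neighbours)} "
                        f"nearest ANI neighbours ({', '.join(neighbour_clades)})"
                    ),
                )
            )
    return out
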
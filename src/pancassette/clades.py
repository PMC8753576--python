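"""Gene-content clades, minhash ANI, dereplication, and tree concordance.

Strains are clustered by the Jaccard distance of their cassette gene
content (presence/absence of OGCs) under deterministic complete-linkage
agglomeration, and independently by whole-genome average nucleotide
identity (ANI) estimated from bottom-s minhash sketches of canonical
k-mers (Mash distance D = -(1/k) ln(2j / (1+j))).  Discordance between the
two trees — gene-content clades that intermix on the ANI tree — is the
signal for horizontal acquisition of cassette content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, to_tree

__all__ = [
    "PresenceMatrix",
    "DistanceMatrix",
    "Dendrogram",
    "CladeAssignment",
    "AniEstimate",
    "jaccard_distance",
    "presence_jaccard_matrix",
    "complete_linkage",
    "cut_clades",
    "minhash_sketch",
    "minhash_ani",
    "ani_distance_matrix",
    "dereplicate",
    "clade_concordance",
    "roman",
]


def roman(n: int) -> str:
    """Roman numeral for a positive integer (clade labels I, II, ...)."""
    if n < 1:
        raise ValueError("roman numerals start at 1")
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class PresenceMatrix:
    """Boolean strain x OGC presence matrix."""

    strains: list[str]
    ogcs: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain labels")
        if len(set(self.ogcs)) != len(self.ogcs):
            raise ValueError("duplicate OGC labels")
        if self.values.shape != (len(self.strains), len(self.ogcs)):
            raise ValueError("presence matrix shape mismatch")

    def vector(self, strain: str) -> np.ndarray:
        return self.values[self.strains.index(strain)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.ogcs)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with labelled rows.

    ``scale`` is ``"jaccard_0_1"`` for gene-content distances or
    ``"ani_pct_distance"`` for 100 - ANI percentage-point distances.
    """

    labels: list[str]
    values: np.ndarray
    scale: str = "jaccard_0_1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.scale == "jaccard_0_1" and (self.values > 1.0 + 1e-12).any():
            raise ValueError("jaccard distances must not exceed 1")

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage form with leaf labels."""

    labels: list[str]
    linkage: np.ndarray  # (n-1, 4): child, child, height, size

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


class CladeAssignment(NamedTuple):
    clades: dict[str, str]  # strain -> clade label ("I", "II", ...)
    dendrogram: Dendrogram
    cut_height: float

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.clades.values():
            out[label] = out.get(label, 0) + 1
        return out

    def members(self, label: str) -> list[str]:
        return sorted(s for s, c in self.clades.items() if c == label)


def jaccard_distance(a: Sequence[bool] | np.ndarray, b: Sequence[bool] | np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on boolean presence vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("Jaccard distance is undefined for two empty sets")
    inter = int(np.logical_and(a, b).sum())
    return 1.0 - inter / union


def presence_jaccard_matrix(presence: PresenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distance over the rows of a presence matrix."""
    m = presence.values.astype(np.int64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if (union == 0).any():
        raise ValueError("a strain with no OGCs makes Jaccard undefined")
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(presence.strains), d, scale="jaccard_0_1")


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Deterministic complete-linkage agglomeration.

    Standard Lance-Williams furthest-neighbour updates; equal-distance ties
    are broken by merging the pair whose sorted member-label tuples compare
    lexicographically smallest, so the tree is reproducible regardless of
    input order.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("complete linkage needs at least two points")
    D = dist.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    reps: dict[int, tuple[str, ...]] = {i: (dist.labels[i],) for i in range(n)}
    scipy_id = {i: i for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        dmin = sub.min()
        best: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_pair: tuple[int, int] | None = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                if D[i, j] == dmin:
                    r = tuple(sorted((reps[i], reps[j])))
                    if best is None or r < best:
                        best, best_pair = r, (i, j)
        assert best_pair is not None
        i, j = best_pair
        a, b = sorted((scipy_id[i], scipy_id[j]))
        Z[step] = (a, b, dmin, sizes[i] + sizes[j])
        # complete-linkage update into slot i
        D[i, :] = np.maximum(D[i, :], D[j, :])
        D[:, i] = D[i, :]
        D[i, i] = np.inf
        active.remove(j)
        reps[i] = tuple(sorted(reps[i] + reps[j]))
        sizes[i] += sizes[j]
        scipy_id[i] = n + step
    return Dendrogram(list(dist.labels), Z)


def _label_partition(
    dendrogram: Dendrogram, flat: np.ndarray, cut_height: float
) -> CladeAssignment:
    """Label clusters I, II, ... by descending size, ties by smallest strain."""
    groups: dict[int, list[str]] = {}
    for strain, cid in zip(dendrogram.labels, flat):
        groups.setdefault(int(cid), []).append(strain)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    clades = {}
    for rank, members in enumerate(ordered, start=1):
        for s in members:
            clades[s] = roman(rank)
    return CladeAssignment(clades, dendrogram, cut_height)


def _cut_after_merges(dendrogram: Dendrogram, n_merges: int) -> np.ndarray:
    """Flat clusters after applying the first ``n_merges`` merges."""
    n = len(dendrogram.labels)
    parent = list(range(n + n_merges))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n_merges):
        a, b = int(dendrogram.linkage[step, 0]), int(dendrogram.linkage[step, 1])
        root = n + step
        parent[find(a)] = root
        parent[find(b)] = root
    return np.array([find(i) for i in range(n)])


def cut_clades(
    dendrogram: Dendrogram,
    method: str = "max_gap",
    height: float | None = None,
    k: int | None = None,
) -> CladeAssignment:
    """Cut a dendrogram into clades.

    ``method`` is one of:

    - ``"max_gap"`` (default): cut at the largest gap between consecutive
      merge heights (ties resolved toward the earliest such gap); with no
      positive gap all strains form one clade.
    - ``"height"``: cut at ``height`` (merges with height <= ``height``
      are applied).
    - ``"k"``: exactly ``k`` clusters, obtained by applying the first
      ``n - k`` merges.

    Clade labels are Roman numerals by descending clade size, ties by the
    smallest member strain label.
    """
    n = len(dendrogram.labels)
    heights = dendrogram.heights
    if method == "height":
        if height is None:
            raise ValueError("method 'height' requires height=")
        flat = _cut_after_merges(dendrogram, int(np.sum(heights <= height)))
        return _label_partition(dendrogram, flat, float(height))
    if method == "k":
        if k is None:
            raise ValueError("method 'k' requires k=")
        if k > n or k < 1:
            raise ValueError(f"k={k} outside 1..{n}")
        flat = _cut_after_merges(dendrogram, n - k)
        cut_h = float(heights[n - k - 1]) if n - k > 0 else 0.0
        return _label_partition(dendrogram, flat, cut_h)
    if method == "max_gap":
        gaps = np.diff(heights)
        if len(gaps) == 0 or gaps.max() <= 0:
            flat = _cut_after_merges(dendrogram, n - 1)
            return _label_partition(dendrogram, flat, float(heights[-1]))
        i = int(np.argmax(gaps))
        cut_h = float((heights[i] + heights[i + 1]) / 2)
        flat = _cut_after_merges(dendrogram, i + 1)
        return _label_partition(dendrogram, flat, cut_h)
    raise ValueError(f"unknown cut method {method!r}")


# ---------------------------------------------------------------------------
# Minhash ANI
# ---------------------------------------------------------------------------

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
DEFAULT_HASH_SEED = 0x5EED_CA55  # fixed, documented sketch hash seed


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _SPLITMIX_GAMMA).astype(np.uint64)
    x = ((x ^ (x >> np.uint64(30))) * _MIX1).astype(np.uint64)
    x = ((x ^ (x >> np.uint64(27))) * _MIX2).astype(np.uint64)
    return (x ^ (x >> np.uint64(31))).astype(np.uint64)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-minimum) 2-bit packed k-mer codes; k <= 31."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > 31:
        raise ValueError("k must be <= 31 to pack into 64 bits")
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr)
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    valid = arr >= 0
    base = np.where(valid, arr, 0).astype(np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(base, k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    fwd = windows @ powers
    comp = np.where(valid, 3 - arr, 0).astype(np.uint64)[::-1]
    rwindows = np.lib.stride_tricks.sliding_window_view(comp, k)
    rev_all = rwindows @ powers
    rev = rev_all[::-1]
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.minimum(fwd, rev)[ok]


def minhash_sketch(
    seq: str, k: int = 21, sketch_size: int = 1000, seed: int = DEFAULT_HASH_SEED
) -> np.ndarray:
    """Bottom-s sketch of 64-bit hashes of canonical k-mers (sorted)."""
    if sketch_size <= 0:
        raise ValueError("sketch_size must be positive")
    codes = _kmer_codes(seq, k)
    hashes = _splitmix64(codes ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    uniq = np.unique(hashes)  # sorted ascending
    return uniq[:sketch_size]


class AniEstimate(NamedTuple):
    ani: float  # percent
    jaccard: float
    mash_distance: float
    zero_overlap: bool  # True when no sketch hashes are shared (ANI floored at 0)


def sketch_ani(a: np.ndarray, b: np.ndarray, k: int, sketch_size: int) -> AniEstimate:
    """Mash ANI estimate from two precomputed bottom-s sketches."""
    merged = np.union1d(a, b)[:sketch_size]
    shared = np.intersect1d(merged, np.intersect1d(a, b, assume_unique=True))
    denom = len(merged)
    j = len(shared) / denom if denom else 0.0
    if j <= 0.0:
        return AniEstimate(0.0, 0.0, float("inf"), True)
    d = -(1.0 / k) * np.log(2.0 * j / (1.0 + j))
    ani = max(0.0, 100.0 * (1.0 - d))
    return AniEstimate(float(ani), float(j), float(d), False)


def minhash_ani(
    seq_a: str,
    seq_b: str,
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = DEFAULT_HASH_SEED,
) -> AniEstimate:
    """Estimate ANI between two sequences by minhash (Mash formula).

    The sketch Jaccard j feeds the Mash distance
    ``D = -(1/k) ln(2j / (1+j))`` and ``ANI = 100 (1 - D)``.  With no
    shared sketch hashes the ANI is reported as the lower bound 0 with
    ``zero_overlap=True``.
    """
    a = minhash_sketch(seq_a, k, sketch_size, seed)
    b = minhash_sketch(seq_b, k, sketch_size, seed)
    return sketch_ani(a, b, k, sketch_size)


def ani_distance_matrix(
    genomes: Mapping[str, str] | Mapping[str, Mapping[str, str]],
    k: int = 21,
    sketch_size: int = 1000,
    seed: int = DEFAULT_HASH_SEED,
) -> DistanceMatrix:
    """Pairwise (100 - ANI) percentage-point distances between genomes.

    ``genomes`` maps genome id to either a sequence or a contig mapping
    (contigs are concatenated for sketching, separated by an N to avoid
    chimeric k-mers).
    """
    labels = sorted(genomes)
    seqs = {}
    for gid in labels:
        g = genomes[gid]
        seqs[gid] = g if isinstance(g, str) else "N".join(g[c] for c in sorted(g))
    sketches = {gid: minhash_sketch(seqs[gid], k, sketch_size, seed) for gid in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            est = sketch_ani(sketches[labels[i]], sketches[labels[j]], k, sketch_size)
            d[i, j] = d[j, i] = 100.0 - est.ani
    return DistanceMatrix(labels, d, scale="ani_pct_distance")


def dereplicate(ani_dist: DistanceMatrix, threshold: float = 0.01) -> list[str]:
    """Retain one medoid strain per tight ANI cluster.

    Complete-linkage clusters are cut at ``threshold`` (percentage-point
    ANI distance; the default 0.01 corresponds to one difference per
    10,000 bp) and each cluster keeps its medoid (minimum summed distance,
    lexicographic tie-break).
    """
    if ani_dist.scale != "ani_pct_distance":
        raise ValueError("dereplicate expects an ani_pct_distance matrix")
    if len(ani_dist.labels) == 1:
        return list(ani_dist.labels)
    dend = complete_linkage(ani_dist)
    flat = fcluster(dend.linkage, t=threshold, criterion="distance")
    retained = []
    for cid in sorted(set(flat)):
        idx = np.flatnonzero(flat == cid)
        members = [dend.labels[i] for i in idx]
        sub = ani_dist.values[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        order = sorted(range(len(members)), key=lambda i: (sums[i], members[i]))
        retained.append(members[order[0]])
    return sorted(retained)


def clade_concordance(
    clades: CladeAssignment, ani_dendrogram: Dendrogram
) -> dict[str, dict[str, object]]:
    """Check each gene-content clade against the ANI dendrogram.

    For every clade the smallest ANI subtree containing all members is
    located; ``n_intruders`` counts leaves of other clades inside it
    (listed under ``intruders``) and ``monophyletic`` is true iff there
    are none.
    """
    if set(clades.clades) != set(ani_dendrogram.labels):
        raise ValueError("clade assignment and ANI dendrogram label mismatch")
    root = to_tree(ani_dendrogram.linkage)
    label_of_leaf = {i: s for i, s in enumerate(ani_dendrogram.labels)}

    leaf_sets: dict[int, frozenset[str]] = {}

    def collect(node) -> frozenset[str]:
        if node.is_leaf():
            s = frozenset([label_of_leaf[node.id]])
        else:
            s = collect(node.left) | collect(node.right)
        leaf_sets[node.id] = s
        return s

    collect(root)
    report: dict[str, dict[str, object]] = {}
    for label in sorted(set(clades.clades.values())):
        members = frozenset(clades.members(label))
        best = min(
            (s for s in leaf_sets.values() if members <= s), key=len
        )
        intruders = sorted(best - members)
        report[label] = {
            "monophyletic": not intruders,
            "n_intruders": len(intruders),
            "intruders": intruders,
        }
    return report
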
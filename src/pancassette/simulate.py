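"""Synthetic pan-genomes with known clade structure and recombination.

The generator emulates the structure of a bacterial subspecies pan-genome
carrying a variable gene cassette between two core anchor genes: a
caterpillar phylogeny of clades accumulates nucleotide divergence on a
conserved backbone, each clade carries its own cassette variant sharing
the anchors and three conserved adjacent gene pairs, and optional events
inject whole-cassette transfers, single-region swaps between clades, and
an inversion between two inverted IS-element copies that splits one
strain's cassette.  Full ground truth (clades, variants, events, walks,
gene-to-token map) is emitted alongside the genomes so every pipeline
stage can be tested offline.

The substitution model is uniform random substitution with no indels,
applied codon-safely (start and stop codons protected, substitutions that
would create an internal stop are re-drawn) so every gene stays
translatable.  Cassette region genes within the same region index derive
from a region-ancestral coding sequence at ~10% nucleotide divergence per
clade: far enough apart to remain distinct OGCs under a 90% identity
clustering rule, close enough to remain protein-level orthologs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .pangraph import Gene, reverse_complement

__all__ = [
    "LEFT_ANCHOR",
    "RIGHT_ANCHOR",
    "CONSERVED_PAIRS",
    "IS_TOKEN",
    "REGION_LABELS",
    "SimulationConfig",
    "TruthSet",
    "SimulatedPanGenome",
    "default_cassette_library",
    "simulate_pangenome",
    "inject_region_swap",
    "inject_whole_cassette_transfer",
    "inject_identifiable_events",
    "write_fixtures",
    "load_fixtures",
    "verify_manifest",
]

# Token ids mirror the study layout so walks and region labels read like the
# real cassette: anchors 3712/3756, conserved pairs (3721,3722), (3749,3750),
# (3753,3754), regions 3712-3721, 3722-3749, 3750-3753, 3754-3756.
LEFT_ANCHOR = 3712
RIGHT_ANCHOR = 3756
CONSERVED_PAIRS: tuple[tuple[int, int], ...] = ((3721, 3722), (3749, 3750), (3753, 3754))
IS_TOKEN = 9990
BACKBONE_BASE = 100

REGION_LABELS = ("3712-3721", "3722-3749", "3750-3753", "3754-3756")

_PRODUCT_OF = {
    LEFT_ANCHOR: "yvyE",
    RIGHT_ANCHOR: "ribZB",
    3721: "tagO",
    3722: "tuaH",
    3749: "lytD",
    3750: "pmiA",
    3753: "gerBC",
    3754: "ywtG",
    IS_TOKEN: "IS1182 family transposase",
}

_SPACER = "TTGACAGCTAGG"  # fixed intergenic pad
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


def default_cassette_library(n_clades: int) -> dict[int, tuple[int, ...]]:
    """One cassette variant per clade, sharing anchors and conserved pairs.

    Region token ids are consecutive within each (clade, region) block so
    subpatterns hyphen-compress the way real tables print.  Region sizes
    vary a little across clades (region 2 is the large variable one; the
    fifth clade gets an expanded first region, mimicking the one clade
    whose cassette diverges from the anchor-adjacent layout).
    """
    library: dict[int, tuple[int, ...]] = {}
    for c in range(1, n_clades + 1):
        r1_len = 3 if c == 5 else 1
        r2_len = 4 + (c - 1) % 3
        r3_len = 2
        r4_len = 1
        base = 4000 + 1000 * (c - 1)
        r1 = tuple(base + 0 + j for j in range(r1_len))
        r2 = tuple(base + 100 + j for j in range(r2_len))
        r3 = tuple(base + 200 + j for j in range(r3_len))
        r4 = tuple(base + 300 + j for j in range(r4_len))
        library[c] = (
            r1 + CONSERVED_PAIRS[0] + r2 + CONSERVED_PAIRS[1] + r3
            + CONSERVED_PAIRS[2] + r4
        )
    return library


def _validate_variant(clade: int, walk: tuple[int, ...]) -> None:
    if LEFT_ANCHOR in walk or RIGHT_ANCHOR in walk:
        raise ValueError(f"clade {clade} variant contains an anchor OGC")
    pos = -1
    for x, y in CONSERVED_PAIRS:
        if walk.count(x) != 1 or walk.count(y) != 1:
            raise ValueError(
                f"clade {clade} variant must contain conserved pair ({x},{y}) exactly once"
            )
        i = walk.index(x)
        if i + 1 >= len(walk) or walk[i + 1] != y:
            raise ValueError(f"clade {clade} variant breaks conserved pair ({x},{y})")
        if i <= pos:
            raise ValueError(f"clade {clade} variant has conserved pairs out of order")
        pos = i


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults mirror the analysed data set: seven gene-content clades of
    sizes 43, 2, 3, 1, 23, 35, 1 (108 strains), a conserved core backbone,
    clade-specific cassette variants between the anchors, small
    within-clade nucleotide divergence and larger between-clade divergence
    accumulated along a caterpillar clade phylogeny.
    """

    n_clades: int = 7
    strains_per_clade: tuple[int, ...] = (43, 2, 3, 1, 23, 35, 1)
    backbone_len: int = 80
    cassette_library: dict[int, tuple[int, ...]] | None = None
    gene_len_range: tuple[int, int] = (150, 300)  # cassette genes, bp
    backbone_gene_len_range: tuple[int, int] = (900, 1500)  # core backbone, bp
    clade_divergence: float = 0.004  # subs/site per caterpillar branch
    within_clade_divergence: float = 0.0015  # subs/site strain from clade
    region_token_divergence: float = 0.15  # region token vs region ancestor
    p_whole_cassette: float = 0.0
    p_region_swap: float = 0.0
    inversion_strain: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strains_per_clade) != self.n_clades:
            raise ValueError("strains_per_clade length must equal n_clades")
        for p in (self.p_whole_cassette, self.p_region_swap):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cassette_library is None:
            self.cassette_library = default_cassette_library(self.n_clades)
        for clade, walk in self.cassette_library.items():
            _validate_variant(clade, tuple(walk))


@dataclass
class TruthSet:
    """Ground truth emitted with every simulation."""

    clade_of: dict[str, int]
    variant_of: dict[str, int]
    walks: dict[str, tuple[int, ...]]  # post-event, pre-inversion cassette walk
    events: list[dict]
    inversion: dict | None
    gene_tokens: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "clade_of": self.clade_of,
            "variant_of": self.variant_of,
            "walks": {s: list(w) for s, w in self.walks.items()},
            "events": self.events,
            "inversion": self.inversion,
            "gene_tokens": self.gene_tokens,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "TruthSet":
        d = json.loads(text)
        return TruthSet(
            clade_of={k: int(v) for k, v in d["clade_of"].items()},
            variant_of={k: int(v) for k, v in d["variant_of"].items()},
            walks={k: tuple(v) for k, v in d["walks"].items()},
            events=d["events"],
            inversion=d["inversion"],
            gene_tokens={k: int(v) for k, v in d["gene_tokens"].items()},
        )


@dataclass
class _SimGene:
    token: int
    sequence: str  # coding orientation
    strand: str


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_CODONS[i] for i in body) + "TAA"


def _mutate_cds(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution avoiding start/stop disruption and new stops."""
    if rate <= 0:
        return seq
    chars = list(seq)
    n = len(chars)
    hits = np.flatnonzero(rng.random(n) < rate)
    for i in hits:
        if i < 3 or i >= n - 3:
            continue  # protect start and terminal stop codons
        codon_start = (i // 3) * 3
        alternatives = [b for b in _BASES if b != chars[i]]
        order = rng.permutation(len(alternatives))
        for j in order:
            old = chars[i]
            chars[i] = alternatives[j]
            codon = "".join(chars[codon_start : codon_start + 3])
            if codon not in _STOPS:
                break
            chars[i] = old
    return "".join(chars)


def _token_strand(token: int) -> str:
    return "-" if token % 3 == 0 else "+"


@dataclass
class SimulatedPanGenome:
    """A rendered synthetic pan-genome plus its ground truth.

    ``genomes`` maps strain -> {contig -> sequence}; ``genes`` maps strain
    -> list of :class:`~pancassette.pangraph.Gene` in genome order; the
    internal pre-inversion gene lists stay available so injection
    operations can edit and re-render.
    """

    config: SimulationConfig
    strains: list[str]
    clade_of: dict[str, int]
    sim_genes: dict[str, list[_SimGene]]
    events: list[dict] = field(default_factory=list)
    genomes: dict[str, dict[str, str]] = field(default_factory=dict)
    genes: dict[str, list[Gene]] = field(default_factory=dict)
    truth: TruthSet | None = None

    def cassette_slice(self, strain: str) -> tuple[int, int]:
        """Indices (i, j) with sim_genes[strain][i+1:j] == the cassette walk."""
        tokens = [g.token for g in self.sim_genes[strain]]
        return tokens.index(LEFT_ANCHOR), tokens.index(RIGHT_ANCHOR)

    def region_slice(self, strain: str, region_index: int) -> tuple[int, int]:
        """Gene-list indices bounding region ``region_index`` (0-based), exclusive."""
        tokens = [g.token for g in self.sim_genes[strain]]
        blocks = [(LEFT_ANCHOR,)] + [p for p in CONSERVED_PAIRS] + [(RIGHT_ANCHOR,)]
        left_block = blocks[region_index]
        right_block = blocks[region_index + 1]
        return tokens.index(left_block[-1]), tokens.index(right_block[0])

    def walk_tokens(self, strain: str) -> tuple[int, ...]:
        i, j = self.cassette_slice(strain)
        return tuple(g.token for g in self.sim_genes[strain][i + 1 : j])

    def render(self) -> None:
        """Lay genes on contigs and rebuild genomes, annotations and truth."""
        variant_of = {
            s: self._variant_id(s) for s in self.strains
        }
        genomes: dict[str, dict[str, str]] = {}
        genes: dict[str, list[Gene]] = {}
        gene_tokens: dict[str, int] = {}
        inversion_record = None
        for strain in self.strains:
            ordered = list(self.sim_genes[strain])
            if self.config.inversion_strain == strain:
                ordered, inversion_record = self._apply_inversion(strain, ordered)
            contig_id = f"{strain}_c1"
            parts: list[str] = []
            pos = 0
            gene_list: list[Gene] = []
            for idx, sg in enumerate(ordered, start=1):
                parts.append(_SPACER)
                pos += len(_SPACER)
                gene_id = f"{strain}_g{idx:03d}"
                genomic = sg.sequence if sg.strand == "+" else reverse_complement(sg.sequence)
                parts.append(genomic)
                gene_list.append(
                    Gene(
                        gene_id=gene_id,
                        genome_id=strain,
                        contig_id=contig_id,
                        start=pos,
                        end=pos + len(genomic),
                        strand=sg.strand,
                        sequence=sg.sequence,
                        product=_PRODUCT_OF.get(sg.token, "hypothetical protein"),
                    )
                )
                gene_tokens[gene_id] = sg.token
                pos += len(genomic)
            parts.append(_SPACER)
            genomes[strain] = {contig_id: "".join(parts)}
            genes[strain] = gene_list
        self.genomes = genomes
        self.genes = genes
        self.truth = TruthSet(
            clade_of=dict(self.clade_of),
            variant_of=variant_of,
            walks={s: self.walk_tokens(s) for s in self.strains},
            events=list(self.events),
            inversion=inversion_record,
            gene_tokens=gene_tokens,
        )

    def _variant_id(self, strain: str) -> int:
        walk = self.walk_tokens(strain)
        for clade, variant in self.config.cassette_library.items():
            if tuple(variant) == walk:
                return clade
        return -1  # recombinant / modified walk

    def _apply_inversion(
        self, strain: str, ordered: list[_SimGene]
    ) -> tuple[list[_SimGene], dict]:
        idx = [i for i, g in enumerate(ordered) if g.token == IS_TOKEN]
        if len(idx) != 2:
            raise ValueError(
                f"inversion strain {strain} must carry exactly two IS copies"
            )
        i1, i2 = idx
        segment = ordered[i1 + 1 : i2]
        flipped = [
            _SimGene(g.token, g.sequence, "-" if g.strand == "+" else "+")
            for g in reversed(segment)
        ]
        new = ordered[: i1 + 1] + flipped + ordered[i2:]
        record = {
            "strain": strain,
            "is_token": IS_TOKEN,
            "segment_genes": len(segment),
        }
        return new, record

    def truth_annotations(self):
        """Testing utility: GenomeAnnotations keyed by ground-truth tokens.

        Placement ogc_ids are the simulator tokens — the route downstream
        stages take when gene calls and cluster assignments are given, as
        with a precomputed assignment table.
        """
        from .pangraph import GenomeAnnotation, Placement

        out = {}
        for strain in self.strains:
            pls = [
                Placement(self.truth.gene_tokens[g.gene_id], g.start, g.end, g.strand)
                for g in self.genes[strain]
            ]
            out[strain] = GenomeAnnotation.build(
                strain, {self.genes[strain][0].contig_id: pls}
            )
        return out


def _build_strains(config: SimulationConfig, rng: np.random.Generator):
    lo, hi = config.gene_len_range
    lo_c, hi_c = max(3, lo // 3), max(4, hi // 3)
    blo, bhi = config.backbone_gene_len_range
    blo_c, bhi_c = max(3, blo // 3), max(4, bhi // 3)

    def draw_len() -> int:
        return int(rng.integers(lo_c, hi_c + 1))

    def draw_backbone_len() -> int:
        return int(rng.integers(blo_c, bhi_c + 1))

    backbone_tokens = [BACKBONE_BASE + i for i in range(config.backbone_len)]
    core_tokens = (
        backbone_tokens
        + [LEFT_ANCHOR, RIGHT_ANCHOR]
        + [t for pair in CONSERVED_PAIRS for t in pair]
        + [IS_TOKEN]
    )
    ancestral: dict[int, str] = {
        t: _random_cds(rng, draw_backbone_len() if t in set(backbone_tokens) else draw_len())
        for t in core_tokens
    }

    # region-ancestral coding sequences shared by all clades' region tokens
    library = config.cassette_library
    assert library is not None
    region_lengths = [0, 0, 0, 0]
    region_tokens_of: dict[int, list[tuple[int, ...]]] = {}
    for clade, walk in library.items():
        regions = _split_variant(tuple(walk))
        region_tokens_of[clade] = regions
        for r, toks in enumerate(regions):
            region_lengths[r] = max(region_lengths[r], len(toks))
    region_ancestors = [
        [_random_cds(rng, draw_len()) for _ in range(region_lengths[r])]
        for r in range(4)
    ]
    token_seq: dict[int, str] = {}
    for clade in sorted(library):
        for r, toks in enumerate(region_tokens_of[clade]):
            for j, t in enumerate(toks):
                token_seq[t] = _mutate_cds(
                    region_ancestors[r][j], config.region_token_divergence, rng
                )

    # caterpillar inheritance of core sequences across clades
    clade_core: list[dict[int, str]] = []
    prev = ancestral
    for _c in range(config.n_clades):
        cur = {
            t: _mutate_cds(prev[t], config.clade_divergence, rng) for t in core_tokens
        }
        clade_core.append(cur)
        prev = cur

    strains: list[str] = []
    clade_of: dict[str, int] = {}
    sim_genes: dict[str, list[_SimGene]] = {}
    half = config.backbone_len // 2
    for clade in range(1, config.n_clades + 1):
        core = clade_core[clade - 1]
        walk = tuple(library[clade])
        for s in range(1, config.strains_per_clade[clade - 1] + 1):
            strain = f"G{clade:02d}_{s:02d}"
            strains.append(strain)
            clade_of[strain] = clade
            layout = (
                [BACKBONE_BASE + i for i in range(half)]
                + [LEFT_ANCHOR]
                + list(walk)
                + [RIGHT_ANCHOR]
                + [BACKBONE_BASE + i for i in range(half, config.backbone_len)]
            )
            genes: list[_SimGene] = []
            for t in layout:
                base_seq = core[t] if t in core else token_seq[t]
                seq = _mutate_cds(base_seq, config.within_clade_divergence, rng)
                genes.append(_SimGene(t, seq, _token_strand(t)))
            if config.inversion_strain == strain:
                is_seq = _mutate_cds(core[IS_TOKEN], config.within_clade_divergence, rng)
                # interior copy inside region 2, exterior copy beyond the
                # right anchor, inverted relative to the interior copy
                tokens = [g.token for g in genes]
                r2_left = tokens.index(CONSERVED_PAIRS[0][1])
                genes.insert(r2_left + 2, _SimGene(IS_TOKEN, is_seq, "+"))
                tokens = [g.token for g in genes]
                right = tokens.index(RIGHT_ANCHOR)
                genes.insert(right + 2, _SimGene(IS_TOKEN, is_seq, "-"))
            sim_genes[strain] = genes
    return strains, clade_of, sim_genes


def _split_variant(walk: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Region token lists of a variant walk (between anchors and pairs)."""
    bounds = []
    for x, _y in CONSERVED_PAIRS:
        bounds.append(walk.index(x))
    r1 = walk[: bounds[0]]
    r2 = walk[bounds[0] + 2 : bounds[1]]
    r3 = walk[bounds[1] + 2 : bounds[2]]
    r4 = walk[bounds[2] + 2 :]
    return [r1, r2, r3, r4]


def inject_whole_cassette_transfer(
    sim: SimulatedPanGenome, donor_strain: str, recipient_strain: str
) -> None:
    """Replace the recipient's entire cassette with the donor's copy.

    Walk tokens and gene sequences between the anchors (exclusive) are
    copied from the donor strain; all other loci are untouched.  A no-op
    when donor and recipient coincide.  The simulation is re-rendered and
    the event recorded in the truth set.
    """
    if donor_strain == recipient_strain:
        return
    di, dj = sim.cassette_slice(donor_strain)
    ri, rj = sim.cassette_slice(recipient_strain)
    donor_genes = [
        _SimGene(g.token, g.sequence, g.strand)
        for g in sim.sim_genes[donor_strain][di + 1 : dj]
    ]
    sim.sim_genes[recipient_strain][ri + 1 : rj] = donor_genes
    sim.events.append(
        {
            "kind": "whole_cassette",
            "donor_strain": donor_strain,
            "recipient_strain": recipient_strain,
            "donor_clade": sim.clade_of[donor_strain],
            "recipient_clade": sim.clade_of[recipient_strain],
        }
    )
    sim.render()


def inject_region_swap(
    sim: SimulatedPanGenome,
    donor_strain: str,
    recipient_strain: str,
    region_index: int,
) -> None:
    """Replace one recipient region (0-based index) with the donor's copy.

    The region must be bounded by the anchors/conserved pairs in both
    strains (guaranteed by construction); only the region's genes change.
    A no-op when donor and recipient coincide.
    """
    if not (0 <= region_index < 4):
        raise ValueError("region_index must be 0..3")
    if donor_strain == recipient_strain:
        return
    di, dj = sim.region_slice(donor_strain, region_index)
    ri, rj = sim.region_slice(recipient_strain, region_index)
    donor_genes = [
        _SimGene(g.token, g.sequence, g.strand)
        for g in sim.sim_genes[donor_strain][di + 1 : dj]
    ]
    sim.sim_genes[recipient_strain][ri + 1 : rj] = donor_genes
    sim.events.append(
        {
            "kind": "region",
            "donor_strain": donor_strain,
            "recipient_strain": recipient_strain,
            "donor_clade": sim.clade_of[donor_strain],
            "recipient_clade": sim.clade_of[recipient_strain],
            "region_label": REGION_LABELS[region_index],
            "region_index": region_index,
        }
    )
    sim.render()


def simulate_pangenome(config: SimulationConfig) -> SimulatedPanGenome:
    """Generate a synthetic pan-genome under the given study conditions.

    Deterministic under ``config.seed``: two runs with the same
    configuration produce byte-identical genomes and truth.  Random
    whole-cassette and region-swap events are drawn per strain at the
    configured probabilities with donors chosen uniformly from other
    clades.
    """
    rng = np.random.default_rng(config.seed)
    strains, clade_of, sim_genes = _build_strains(config, rng)
    sim = SimulatedPanGenome(
        config=config, strains=strains, clade_of=clade_of, sim_genes=sim_genes
    )
    sim.render()
    for strain in strains:
        if config.p_whole_cassette > 0 and rng.random() < config.p_whole_cassette:
            donor = _pick_donor(sim, strain, rng)
            if donor is not None:
                inject_whole_cassette_transfer(sim, donor, strain)
        if config.p_region_swap > 0 and rng.random() < config.p_region_swap:
            donor = _pick_donor(sim, strain, rng)
            if donor is not None:
                region = int(rng.integers(0, 4))
                inject_region_swap(sim, donor, strain, region)
    return sim


def _pick_donor(
    sim: SimulatedPanGenome, recipient: str, rng: np.random.Generator
) -> str | None:
    own = sim.clade_of[recipient]
    others = [s for s in sim.strains if sim.clade_of[s] != own]
    if not others:
        return None
    return others[int(rng.integers(0, len(others)))]


def inject_identifiable_events(
    sim: SimulatedPanGenome,
    rng: np.random.Generator,
    n_region_swaps: int = 5,
    n_whole_transfers: int = 3,
    swap_regions: tuple[int, ...] = (0, 2, 3),
) -> list[dict]:
    """Inject recombination events in the identifiable regime.

    Identifiability means each event is recoverable from gene content
    alone: donors and recipients are pairwise distinct, untouched strains
    from clades with at least four members (so a flagged subpattern has a
    clear majority clade and an outlier strain has clade-mates among its
    ANI neighbours); region swaps use the smaller regions (by default not
    the large variable region), whose exchange cannot flip the
    recipient's gene-content clade.  Returns the truth events appended.
    """
    sizes: dict[int, int] = {}
    for c in sim.clade_of.values():
        sizes[c] = sizes.get(c, 0) + 1
    eligible = sorted(c for c, n in sizes.items() if n >= 4)
    if len(eligible) < 2:
        raise ValueError("need at least two clades with >= 4 strains")
    used: set[str] = set()

    def pick(clade: int) -> str:
        pool = [
            s for s in sim.strains if sim.clade_of[s] == clade and s not in used
        ]
        if not pool:
            raise ValueError(f"clade {clade} exhausted while injecting events")
        return pool[int(rng.integers(0, len(pool)))]

    before = len(sim.events)
    for i in range(n_region_swaps):
        dc = eligible[int(rng.integers(0, len(eligible)))]
        rc = dc
        while rc == dc:
            rc = eligible[int(rng.integers(0, len(eligible)))]
        donor, recipient = pick(dc), pick(rc)
        used.update((donor, recipient))
        region = swap_regions[int(rng.integers(0, len(swap_regions)))]
        inject_region_swap(sim, donor, recipient, region)
    # two recipients of the same donor->recipient clade pair would land in
    # the same new gene-content clade and shield each other as mutual ANI
    # neighbours, so whole transfers use distinct clade pairs
    clade_pairs = [
        (a, b) for a in eligible for b in eligible if a != b
    ]
    if n_whole_transfers > len(clade_pairs):
        raise ValueError("not enough distinct clade pairs for whole transfers")
    order = rng.permutation(len(clade_pairs))
    for i in range(n_whole_transfers):
        dc, rc = clade_pairs[int(order[i])]
        donor, recipient = pick(dc), pick(rc)
        used.update((donor, recipient))
        inject_whole_cassette_transfer(sim, donor, recipient)
    return sim.events[before:]


# ---------------------------------------------------------------------------
# Fixture round trip
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(sim: SimulatedPanGenome, outdir: str | Path) -> dict[str, str]:
    """Write genomes (FASTA), gene calls (GFF3), truth JSON and a manifest.

    Returns the manifest: relative file name -> sha256.  Outputs are
    byte-stable under a fixed seed.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for strain in sim.strains:
        fa = outdir / "genomes" / f"{strain}.fasta"
        pio.write_genome_fasta(sim.genomes[strain], fa)
        gff = outdir / "annotations" / f"{strain}.gff3"
        pio.write_gff3(sim.genes[strain], gff)
        files.extend([fa, gff])
    truth_path = outdir / "truth.json"
    truth_path.write_text(sim.truth.to_json() + "\n")
    files.append(truth_path)
    manifest = {str(f.relative_to(outdir)): _sha256(f) for f in files}
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def verify_manifest(outdir: str | Path) -> list[str]:
    """Return the relative paths whose checksum no longer matches."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "MANIFEST.json").read_text())
    bad = []
    for rel, digest in sorted(manifest.items()):
        p = outdir / rel
        if not p.exists() or _sha256(p) != digest:
            bad.append(rel)
    return bad


def load_fixtures(outdir: str | Path):
    """Reload (genomes, genes, truth) written by :func:`write_fixtures`."""
    outdir = Path(outdir)
    truth = TruthSet.from_json((outdir / "truth.json").read_text())
    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[Gene]] = {}
    for fa in sorted((outdir / "genomes").glob("*.fasta")):
        strain = fa.stem
        genomes[strain] = pio.read_genome_fasta(fa)
        gff = outdir / "annotations" / f"{strain}.gff3"
        genes[strain] = pio.read_gff3_cds(gff, genomes[strain], genome_id=strain)
    return genomes, genes, truth
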
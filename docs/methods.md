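# Methods

`pancassette` analyses the evolution of a variable gene cassette inside a
bacterial subspecies pan-genome.  The cassette — a contiguous run of genes
bounded by two single-copy core anchor genes — is compared across strains
at three levels: strict nucleotide ortholog clusters (OGCs), protein-level
ortholog groups, and ordered gene patterns.  Discordance between
gene-content similarity and whole-genome nucleotide similarity is the
signal for horizontal acquisition of cassette material by homologous
recombination.

## Ortholog gene clusters and the pan-genome graph

Genes are clustered into OGCs from pairwise nucleotide homology.  A match
is retained when it reaches **90% identity over 90% of both genes'
lengths** — strict thresholds chosen to keep diverged cassette variants in
*separate* clusters, which is precisely what makes the cassette variation
visible.  OGCs are connected components of retained matches, with one
refinement: when a component holds two genes of one genome (a paralog
conflict), the component medoid is computed (minimum summed match
distance, 100 − identity, missing pairs penalized), each conflicted genome
keeps the gene with the higher bitscore to that medoid, and the evicted
genes are re-clustered among themselves.  The recursive re-clustering
matters: forcing evicted genes into singletons would mis-handle the case
of two genomes each carrying two paralogs, where the evicted copies form a
perfectly good second cluster.  All tie-breaks are lexicographic, so the
result is independent of input order.

The pan-genome graph (PGG) has OGCs as nodes and orientation-aware genome
adjacencies as edges.  Each gene exposes an intrinsic *tail* (5′ of its
coding strand) and *head* (3′); an edge key records which ends face each
other and is canonicalized so that reverse-complementing a contig maps
every junction to the same key.  Edge support counts adjacency
occurrences, so total support always equals
`Σ_contigs max(0, placements − 1)` and an independent recount reproduces
it exactly.  (An alternative convention counts supporting *genomes*; the
two differ only when one genome repeats an adjacency, and the
occurrence-count convention is the one that preserves the conservation
identity.)

Re-annotation against the graph uses a pluggable similarity-search
contract: a searcher receives the medoid index and a contig and returns
candidate placements with identity, coverage and score.  Overlapping
candidates are grouped and resolved by (1) the number of flanking
placements consistent with PGG edges, (2) score, (3) the smaller OGC id,
with two refinement passes so the context criterion is self-consistent.
The built-in searcher (`KmerEdlibSearch`) aligns each medoid against the
contig with edlib in infix mode on both strands; it reports only
best-scoring loci per medoid, which recovers multi-copy elements only when
the copies are identical (as IS transposons typically are).  A
seed-and-extend multi-locus search would be the upgrade path if diverged
repeats mattered.  Graph building and re-annotation alternate until the
multiset of per-contig OGC walks stops changing; convergence is defined on
walks rather than coordinates to avoid alignment jitter.

## Cassette extraction

A strain's cassette is the OGC walk strictly between the two anchors on
their shared contig, orientation-normalized so it always reads left anchor
→ right anchor (anchors in descending coordinate order mean the cassette
sits on the minus strand; the walk is reversed and strands flipped).
Anchors must be placed exactly once — anything else is an error naming the
anchor and genome.

A cassette split by an inversion between two inverted IS-element copies is
repaired explicitly, never automatically: the segment strictly between the
two copies is virtually re-inverted (an involution), after which ordinary
extraction applies and the interior IS copy sits at its pre-inversion
position in the walk.  Repair accepts a *set* of OGC ids for the IS
element because strict clustering can put the two identical copies in
different OGCs; in practice IS OGCs are identified the same way anchors
are — by their product annotation ("transposase") — not from ground truth.

## Gene-content clades, ANI, and concordance

The presence/absence of every cassette OGC (anchors excluded, copy number
ignored) feeds pairwise Jaccard distances and complete-linkage
agglomeration.  Complete linkage is implemented in-package with an
explicit tie rule — equal-distance merges pick the lexicographically
smallest pair of member-label tuples — because reproducibility of the tree
under permutation matters for everything downstream; scipy's
implementation serves as an independent oracle in the tests.  Clades are
cut either at the largest gap between consecutive merge heights (default;
with identical within-clade gene content the gap between ~0 within-clade
merges and the first between-clade merge is unambiguous), at a fixed
height, or into exactly k clusters.  Clade labels are Roman numerals by
descending size, ties by smallest member label.

ANI is estimated by bottom-s minhash: canonical (strand-minimum) 2-bit
packed k-mers (k = 21) hashed with a fixed 64-bit splitmix mix (documented
seed `0x5EEDCA55`), bottom-s of the union scored as in Mash, Jaccard j
converted by D = −(1/k)·ln(2j/(1+j)), ANI = 100·(1−D); zero sketch overlap
reports ANI 0 with an explicit flag rather than a fabricated value.  ANI
distances are percentage points (100 − ANI).  Dereplication cuts the
complete-linkage ANI tree at 0.01 percentage points (one difference per
10 kb) and keeps each cluster's medoid.

Concordance: for every gene-content clade the smallest ANI-dendrogram
subtree containing all members is located; members of other clades inside
it are intruders, and a clade is monophyletic iff there are none.

## Patterns, regions, and recombination candidates

A strain's OGC pattern is its cassette walk; conserved adjacent pairs —
ordered pairs (x, y) with x and y each exactly once and adjacent in
*every* strain — partition the anchored pattern into regions labelled by
their bounding OGCs.  Subpatterns are printed as parenthesized
comma-separated lists with maximal consecutive runs (ascending or
descending, length ≥ 2) compressed to "first−last"; "()" is the empty
subpattern.  Parsing is the exact inverse.  Subpattern equality is exact
ordered-token equality; per-region counts against clades form the
subpattern table, whose per-region column sums always equal the clade
sizes.

Two candidate classes are reported, mirroring the two recombination
scales:

- **Region candidates**: any (region, subpattern) with nonzero counts in
  ≥ 2 clades, listing clades, counts and the minority-clade strains.
- **Outlier strains** (whole-cassette transfers): strains whose
  gene-content clade does not appear *at all* among the clades of their
  q = 3 nearest ANI neighbours.  A majority vote was rejected: it flags
  every member of a 1–2 strain clade (such clades exist in the analysed
  configuration), whereas the absence rule keeps a 2-strain clade safe as
  long as the clade-mate is among the neighbours, and strains in
  singleton clades are skipped outright since they have no within-clade
  ANI expectation to violate.

The package reports sharing evidence and majority/minority status only;
deciding which subpattern is ancestral is an interpretive call left to the
analyst.

## The synthetic pan-genome

The generator emulates exactly the features the analysis relies on, and
no more:

- **Clade structure**: a caterpillar phylogeny of clades; each clade's
  core sequence derives from its predecessor at 0.004 substitutions/site,
  each strain from its clade at 0.0015.  Defaults mirror the analysed
  data set: seven clades of sizes 43, 2, 3, 1, 23, 35, 1 (108 strains).
  Total divergence stays well below the 10% clustering margin so core
  genes remain single OGCs across all clades.
- **Genome layout**: 80 core backbone genes (900–1500 bp) around an
  anchored cassette of short genes (150–300 bp) with fixed intergenic
  pads.  The backbone dominates the genome (~95%) so whole-genome ANI
  tracks vertical descent even after a whole-cassette transfer — the
  property the outlier detector depends on, and the reason backbone genes
  are long: with a cassette that is a large genome fraction, a transfer
  drags ANI toward the donor and the real-data signal disappears.
- **Cassette variants**: one per clade, sharing the anchors and three
  conserved adjacent pairs; region tokens are consecutive integers per
  (clade, region) block so subpatterns hyphen-compress realistically.
  Tokens at the same region index descend from a shared ancestral coding
  sequence at 15% nucleotide divergence per clade — far enough apart to
  stay distinct OGCs under the 90% rule with comfortable margin (realized
  pairwise identities scatter by a few points around their expectation;
  at 10% divergence the occasional pair crossed 90% and two clades'
  tokens collapsed into one OGC), while typical pairwise protein
  identities of 40–60% keep the ortholog groups connected at the
  protein level, reproducing the strict-nucleotide/relaxed-protein
  two-tier structure.  Individual protein pairs can fall below the 40%
  retention floor; component merging tolerates this as long as some
  links survive.
- **Substitution model**: uniform substitutions, no indels, applied
  codon-safely (start/stop protected, substitutions creating internal
  stops re-drawn) so every gene stays translatable.
- **Events**: whole-cassette transfers copy a donor strain's cassette
  genes wholesale; region swaps copy one region.  The *identifiable
  regime* used for acceptance restricts events to clades with ≥ 4
  strains, pairwise-distinct untouched donors/recipients, distinct
  donor→recipient clade pairs for whole transfers (two recipients of the
  same pair would form a two-strain content clade and shield each other
  as mutual ANI neighbours), and swaps of the smaller regions (swapping
  the large variable region can legitimately move the recipient's
  gene-content clade, at which point the event is a whole-cassette-like
  transfer, not a region swap).
- **Inversion**: one strain can carry two identical inverted IS copies —
  one inside the cassette, one outside — with the intervening segment
  inverted, reproducing the split-cassette geometry that `repair` undoes.

What the generator does **not** emulate: realistic base composition,
codon usage, indels, gene gain/loss outside the cassette, assembly
fragmentation, or annotation error.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated model,
not robustness to real-data artefacts such as mis-annotation, which
typically needs manual follow-up (e.g. translated-search rescue of
missing orthologs) outside this package's scope.

## Numerical choices and known limitations

- Problem sizes: the acceptance computations use the full 108-strain
  configuration for clade recovery and event detection, and a 7-strain
  configuration for graph-convergence and split-repair checks — sizes at
  which every quantity is exactly identifiable.
- The built-in nucleotide and protein matchers score global edit
  distance (identity = 1 − d/max(len), a conservative lower bound) with a
  shared-k-mer prefilter (CRC32-sampled, process-stable); tabular BLAST
  output can replace them at the match interfaces for real data.
- The paralog cut truncates each query's bitscore-ranked match list at
  the first repeated-clade subject (the repeat itself, being the
  higher-scoring of the pair, is kept).  An alternative reading — drop
  only repeated-clade matches and keep later novel-clade ones — is
  available as `paralog_rule="per_clade_best"`.  Note the truncation rule
  is deliberately not monotone in the identity floor: removing the match
  that triggers truncation can let lower-ranked matches survive.
- Weak protein matches (below the ortholog thresholds but above a looser
  floor) are reported separately and never merged.
- `minhash_ani` is exact whenever the sketch exceeds the k-mer universe;
  pipeline defaults (sketch 10 000 on ~100 kb simulated genomes) give a
  Mash-style estimate whose noise (≈ 0.05 ANI points) is an order of
  magnitude below the smallest distance the analysis must resolve.
- Degenerate inputs raise informative errors rather than guessing:
  missing/duplicated anchors, IS copies not in inverted two-copy
  geometry, all-empty presence vectors, distance matrices that are not
  symmetric-zero-diagonal.
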
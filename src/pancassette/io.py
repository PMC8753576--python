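"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 reading through gffutils (in-memory
database, CDS features with an ``ID`` attribute naming the gene), and the
tabular artifacts (OGC membership, PGG edge list, cassettes, presence
matrix, clades, subpattern table, candidates) are plain TSV via pandas.
GFF3 is 1-based inclusive on disk; everything in memory is 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthologs import ProteinMatch
from .pangraph import OGC, Gene, PanGenomeGraph, reverse_complement

__all__ = [
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gff3_cds",
    "write_gff3",
    "write_ogc_table",
    "read_ogc_table",
    "write_pgg_edges",
    "write_medoid_fasta",
    "write_presence_matrix",
    "write_clades",
    "write_cassettes",
    "write_subpattern_table",
    "write_candidates",
    "read_protein_matches_tsv",
    "write_ortholog_groups",
    "write_protein_matches",
    "write_collapsed_patterns",
]


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(contigs[cid]), id=cid, description="") for cid in sorted(contigs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff3_cds(
    gff_path: str | Path, contigs: Mapping[str, str], genome_id: str
) -> list[Gene]:
    """Parse CDS features into :class:`Gene` records.

    The ``ID`` attribute names the gene; ``product`` is carried through
    when present.  Sequences are sliced from ``contigs`` and reverse
    complemented for minus-strand genes.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        start0, end0 = feat.start - 1, feat.end
        raw = contigs[feat.seqid][start0:end0]
        seq = raw if feat.strand == "+" else reverse_complement(raw)
        genes.append(
            Gene(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand,
                sequence=seq,
                product=product,
            )
        )
    return genes


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
        attrs = f"ID={g.gene_id}"
        if g.product:
            attrs += f";product={g.product}"
        lines.append(
            "\t".join(
                [
                    g.contig_id,
                    "pancassette",
                    "CDS",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ogc_table(
    ogcs: Iterable[OGC], genes_by_id: Mapping[str, Gene], path: str | Path
) -> None:
    """OGC membership TSV: ogc_id, genome, gene, contig, start, end, strand."""
    rows = []
    for ogc in sorted(ogcs, key=lambda o: o.ogc_id):
        for gid in sorted(ogc.members):
            g = genes_by_id[gid]
            rows.append(
                {
                    "ogc_id": ogc.ogc_id,
                    "genome_id": g.genome_id,
                    "gene_id": gid,
                    "contig": g.contig_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "is_medoid": int(gid == ogc.medoid_gene_id),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ogc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pgg_edges(pgg: PanGenomeGraph, path: str | Path) -> None:
    rows = [
        {
            "ogc_a": a,
            "end_a": ea,
            "ogc_b": b,
            "end_b": eb,
            "support": support,
        }
        for (a, ea, b, eb), support in sorted(pgg.edge_support.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_medoid_fasta(
    medoid_sequences: Mapping[int, str], path: str | Path, prefix: str = "medoid"
) -> None:
    records = [
        SeqRecord(Seq(medoid_sequences[o]), id=f"{prefix}_{o}", description="")
        for o in sorted(medoid_sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_presence_matrix(presence, path: str | Path) -> None:
    presence.to_frame().astype(int).rename_axis("strain").to_csv(path, sep="\t")


def write_clades(assignment, path: str | Path) -> None:
    rows = [
        {"strain": s, "clade": c} for s, c in sorted(assignment.clades.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cassettes(cassettes, path: str | Path) -> None:
    rows = [
        {
            "genome_id": c.genome_id,
            "walk": ",".join(map(str, c.walk)),
            "strands": "".join(c.strands),
            "strand_normalized": int(c.strand_normalized),
            "split_repaired": int(c.split_repaired),
        }
        for c in sorted(cassettes, key=lambda c: c.genome_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_subpattern_table(table, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "qstart", "qend", "qlen",
    "sstart", "send", "slen", "evalue", "bitscore",
]


def read_protein_matches_tsv(path: str | Path, prefix: str = "") -> list[ProteinMatch]:
    """Read a tabular BLAST (outfmt-6-like) protein match table.

    Expected columns: qseqid sseqid pident qstart qend qlen sstart send
    slen evalue bitscore (no header).  Sequence ids are ``<prefix><ogc>``,
    e.g. ``medoid_4746``; the trailing integer is the OGC id.  Match
    length is taken from the query alignment span.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_OUTFMT6_COLUMNS)

    def ogc_id(name: str) -> int:
        stem = str(name)
        if prefix and stem.startswith(prefix):
            stem = stem[len(prefix):]
        return int(stem.rsplit("_", 1)[-1])

    return [
        ProteinMatch(
            query_ogc=ogc_id(r.qseqid),
            subject_ogc=ogc_id(r.sseqid),
            percent_identity=float(r.pident),
            match_len=abs(int(r.qend) - int(r.qstart)) + 1,
            query_len=int(r.qlen),
            subject_len=int(r.slen),
            bitscore=float(r.bitscore),
            evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def write_ortholog_groups(
    groups, group_counts: Mapping[int, int], path: str | Path,
    labels: Mapping[int, str] | None = None,
) -> None:
    """Ortholog-group TSV: label, member OGCs, strain count."""
    rows = [
        {
            "group_id": g.group_id,
            "label": (labels or {}).get(g.group_id, g.label or ""),
            "ogcs": ",".join(map(str, sorted(g.member_ogcs))),
            "strain_count": group_counts.get(g.group_id, ""),
        }
        for g in sorted(groups, key=lambda g: g.group_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_protein_matches(matches, path: str | Path) -> None:
    """Protein match TSV (e.g. ``weak_matches.tsv`` — matches too limited
    to be treated as orthologs, reported for inspection only)."""
    rows = [
        {
            "query_ogc": m.query_ogc,
            "subject_ogc": m.subject_ogc,
            "pident": m.percent_identity,
            "match_len": m.match_len,
            "qlen": m.query_len,
            "slen": m.subject_len,
            "bitscore": m.bitscore,
            "evalue": m.evalue,
        }
        for m in matches
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_collapsed_patterns(rows, path: str | Path) -> None:
    """Collapsed pattern TSV: pattern, multiplicity, member strains."""
    out = [
        {
            "pattern": ",".join(map(str, pattern)),
            "count": count,
            "strains": ",".join(strains),
        }
        for pattern, count, strains in rows
    ]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def write_candidates(candidates, path: str | Path) -> None:
    rows = [
        {
            "kind": c.kind,
            "strains": ",".join(c.strains),
            "region": c.region_label or "",
            "subpattern": c.subpattern or "",
            "clade_counts": ";".join(f"{cl}:{n}" for cl, n in c.clade_counts),
            "evidence": c.evidence,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
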
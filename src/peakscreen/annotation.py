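"""Readers/writers for genome sequence (FASTA), gene annotation (GFF3/BED6)
and plain interval BED6 files."""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .intervals import GeneModel, GenomeInterval

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_genes_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene features only, 1-based inclusive per the GFF3 spec."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = g.interval.to_1based()
            strand = g.interval.strand if g.interval.strand in "+-" else "."
            fh.write(
                f"{g.interval.chrom}\tpeakscreen\tgene\t{start1}\t{end1}\t.\t"
                f"{strand}\t.\tID={g.gene_id};length_bp={g.length_bp}\n"
            )


def read_genes_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene features from a GFF3 file (via gffutils, in-memory db)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        length = int(feat.attributes.get("length_bp", [feat.end - feat.start + 1])[0])
        strand = feat.strand if feat.strand in "+-" else "."
        iv = GenomeInterval(feat.seqid, feat.start - 1, feat.end, strand)
        genes.append(GeneModel(gene_id, iv, length))
    if not genes:
        raise FormatError(f"no gene features found in {path}")
    return genes


def write_bed6(intervals: Iterable[tuple[GenomeInterval, str, float]],
               path: str | os.PathLike) -> None:
    """Write (interval, name, score) triples as BED6."""
    rows = [
        (iv.chrom, iv.start, iv.end, name, score,
         iv.strand if iv.strand in "+-" else ".")
        for iv, name, score in intervals
    ]
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(path, sep="\t",
                                                    header=False, index=False)


def read_bed6(path: str | os.PathLike) -> list[tuple[GenomeInterval, str, float]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] > 5 and row[5] in "+-" else "."
        name = str(row[3]) if df.shape[1] > 3 else "."
        score = float(row[4]) if df.shape[1] > 4 and row[4] != "." else 0.0
        out.append((GenomeInterval(str(row[0]), int(row[1]), int(row[2]), strand),
                    name, score))
    return out
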
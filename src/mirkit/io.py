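"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; GFF3 parsing goes through gffutils
(1-based closed intervals on disk, 0-based half-open in memory); the
tabular registries are plain TSV via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import GeneModel


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[str]:
    """Read a FASTQ file, returning the read sequences in file order."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with uniform 'I' quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ----------------------------------------------------------------------- GFF3

def write_gff3(path: str | os.PathLike, models: list[GeneModel]) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS; 1-based closed)."""

    def line(chrom, ftype, start, end, strand, attrs):
        return (
            f"{chrom}\t.\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = f"gene:{m.transcript_id}"
            ts, te = m.transcript_interval
            fh.write(line(m.chrom, "gene", ts, te, m.strand, f"ID={gene_id}"))
            fh.write(
                line(
                    m.chrom, "mRNA", ts, te, m.strand,
                    f"ID={m.transcript_id};Parent={gene_id}",
                )
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    line(
                        m.chrom, "exon", s, e, m.strand,
                        f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                    )
                )
            if m.cds_interval is not None:
                cs, ce = m.cds_interval
                for s, e in m.exons:
                    s2, e2 = max(s, cs), min(e, ce)
                    if s2 < e2:
                        fh.write(
                            line(
                                m.chrom, "CDS", s2, e2, m.strand,
                                f"Parent={m.transcript_id}",
                            )
                        )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models back from GFF3 into 0-based half-open GeneModels."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        cds_interval = (
            (min(s for s, _ in cds), max(e for _, e in cds)) if cds else None
        )
        models.append(
            GeneModel(
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                transcript_interval=(mrna.start - 1, mrna.end),
                exons=exons,
                cds_interval=cds_interval,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.transcript_interval))
    return models


# ------------------------------------------------------------------ registries

REGISTRY_COLUMNS = [
    "precursor_id", "mature_start", "mature_end", "star_start", "star_end",
]


def write_registry(path: str | os.PathLike, rows: pd.DataFrame) -> None:
    """Write the known-miRNA registry (precursor-local, 0-based half-open)."""
    rows.to_csv(path, sep="\t", index=False, columns=REGISTRY_COLUMNS)


def read_registry(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    return df


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def spliced_sequence(genome: dict[str, str], model: GeneModel) -> str:
    """Spliced transcript sequence (reverse-complemented on the − strand)."""
    from .util import revcomp

    seq = "".join(genome[model.chrom][s:e] for s, e in model.exons)
    return revcomp(seq) if model.strand == "-" else seq
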
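"""Readers and writers for the pipeline's file interfaces.

FASTA/FASTQ go through Biopython; tables are plain TSV via pandas. All
interval files use 0-based half-open BED conventions.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragends import ViewpointSpec

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "read_viewpoints",
    "write_viewpoints",
    "read_gene_table",
    "write_gene_table",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, dtype={0: str}
    )
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False)


def read_viewpoints(path) -> list[ViewpointSpec]:
    """Viewpoint table TSV: snp_id, chrom, pos, primer, cell_types
    (comma-separated)."""
    df = pd.read_csv(str(path), sep="\t", dtype={"chrom": str})
    vps = []
    for rec in df.itertuples(index=False):
        cts = tuple(str(rec.cell_types).split(",")) if "cell_types" in df.columns else ()
        vps.append(
            ViewpointSpec(
                snp_id=str(rec.snp_id),
                chrom=str(rec.chrom),
                position=int(rec.pos),
                primer=str(rec.primer),
                cell_types=cts,
            )
        )
    return vps


def write_viewpoints(viewpoints: list[ViewpointSpec], path) -> None:
    rows = [
        (vp.snp_id, vp.chrom, vp.position, vp.primer, ",".join(vp.cell_types))
        for vp in viewpoints
    ]
    pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "primer", "cell_types"]
    ).to_csv(str(path), sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, tss, strand."""
    return pd.read_csv(str(path), sep="\t", dtype={"chrom": str})


def write_gene_table(genes: pd.DataFrame, path) -> None:
    cols = [c for c in ("gene_id", "chrom", "tss", "strand") if c in genes.columns]
    genes[cols].to_csv(str(path), sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
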
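"""Promoter sets: FASTA I/O and extraction of TSS−1 kb → exon-1 regions.

The promoter of a gene is the region from 1 kb upstream of the transcription
start site through the end of its first exon, taken on the gene's own strand.
Gene tables use 1-based inclusive coordinates; internally everything is
0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import reverse_complement

GENE_TABLE_COLUMNS = ["gene", "chrom", "strand", "tss", "exon1_end"]


@dataclass
class PromoterSet:
    """Mapping gene id -> promoter sequence over {A,C,G,T,N}."""

    sequences: dict[str, str]
    region_spec: str = "TSS-1000 through exon-1 end"
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty promoter sequence for gene {gene}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences.items())

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "PromoterSet":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate promoter id {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs, provenance=f"fasta:{path}", **kwargs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def subset(self, genes) -> "PromoterSet":
        missing = [g for g in genes if g not in self.sequences]
        if missing:
            raise KeyError(f"genes without promoters: {missing[:5]}")
        return PromoterSet(
            {g: self.sequences[g] for g in genes},
            region_spec=self.region_spec,
            provenance=self.provenance,
        )


def read_gene_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return table


def extract_promoters(
    genome: dict[str, str],
    gene_table: pd.DataFrame,
    upstream: int = 1000,
) -> PromoterSet:
    """Extract TSS−upstream → exon-1-end regions from contig sequences.

    For a plus-strand gene the region is ``[tss - upstream, exon1_end]`` in
    1-based inclusive coordinates; for a minus-strand gene it is
    ``[exon1_end, tss + upstream]`` reverse-complemented, so the returned
    sequence always reads 5'→3' on the gene's strand.  Regions running off a
    contig edge are truncated with a warning.
    """
    seqs: dict[str, str] = {}
    for row in gene_table.itertuples(index=False):
        contig = genome.get(row.chrom)
        if contig is None:
            raise KeyError(f"gene {row.gene}: contig {row.chrom} not in genome")
        if row.strand == "+":
            start0, end0 = int(row.tss) - 1 - upstream, int(row.exon1_end)
        elif row.strand == "-":
            start0, end0 = int(row.exon1_end) - 1, int(row.tss) + upstream
        else:
            raise ValueError(f"gene {row.gene}: bad strand {row.strand!r}")
        clipped_start, clipped_end = max(start0, 0), min(end0, len(contig))
        if (clipped_start, clipped_end) != (start0, end0):
            warnings.warn(
                f"gene {row.gene}: promoter truncated at contig edge", stacklevel=2
            )
        if clipped_end <= clipped_start:
            raise ValueError(f"gene {row.gene}: empty promoter region")
        region = contig[clipped_start:clipped_end].upper()
        seqs[row.gene] = region if row.strand == "+" else reverse_complement(region)
    return PromoterSet(seqs, provenance="extracted-from-genome")


def write_genome_fasta(genome: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()],
        str(path),
        "fasta",
    )
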
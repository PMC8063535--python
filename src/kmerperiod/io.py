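"""File I/O: FASTA sequence sets, BED intervals, and genome extraction."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .sequences import DnaSequence

__all__ = [
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "extract_sequences",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, mask_lowercase: bool = False) -> list[DnaSequence]:
    """Read a (possibly gzipped, line-wrapped) multi-record FASTA."""
    with _open_text(path) as fh:
        return [
            DnaSequence.from_raw(rec.id, str(rec.seq), mask_lowercase=mask_lowercase)
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(seqs: list[DnaSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path) -> list[GenomicInterval]:
    """Minimal BED3/BED6 reader (0-based half-open; strand from column 6)."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 fields")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(
                GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                )
            )
    return intervals


def extract_sequences(
    genome_fasta,
    intervals: list[GenomicInterval],
    mask_lowercase: bool = False,
) -> list[DnaSequence]:
    """Extract interval sequences from a genome FASTA.

    Minus-strand intervals are reverse-complemented so motifs are read 5'→3'
    on the annotated strand. A chromosome absent from the genome is a hard
    error naming it.
    """
    genome = Fasta(str(genome_fasta))
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} not found in {genome_fasta}")
        raw = genome[iv.chrom][iv.start : iv.end].seq
        seq = DnaSequence.from_raw(
            f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})",
            raw,
            mask_lowercase=mask_lowercase,
        )
        if iv.strand == "-":
            seq = seq.reverse_complement()
        out.append(seq)
    return out


def chrom_sizes(genome_fasta) -> list[tuple[str, int]]:
    """(chrom, length) pairs in genome order, via the FASTA index."""
    genome = Fasta(str(genome_fasta))
    return [(name, len(genome[name])) for name in genome.keys()]
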
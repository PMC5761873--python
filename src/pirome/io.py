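"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA/FASTQ go through Biopython; BED6 and bedGraph are 0-based
half-open; GMT is the usual tab-separated gene-set format.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Feature, GenomicInterval


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, DNA sequence) pairs from a Phred+33 FASTQ file."""
    for title, seq, _qual in SeqIO.QualityIO.FastqGeneralIterator(str(path)):
        yield title.split()[0], seq.upper()


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, DNA sequence) pairs with a constant high quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ----------------------------------------------------------------------- BED

def read_bed(path: str | os.PathLike) -> list[Feature]:
    """Read BED3/BED6 into Features (0-based half-open, strand '.' if absent)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(Feature(GenomicInterval(chrom, start, end, strand), name))
    return feats


def write_bed(path: str | os.PathLike, feats: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        for f in feats:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.name or '.'}\t0\t{iv.strand if iv.strand != '.' else '+'}\n"
            )


# ------------------------------------------------------------------ bedGraph

def write_bedgraph(
    path: str | os.PathLike, entries: Iterable[tuple[str, int, int, float]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in entries:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")


def read_bedgraph(path: str | os.PathLike) -> Iterator[tuple[str, int, int, float]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            yield chrom, int(start), int(end), float(value)


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read gene sets; duplicate set names are an error."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(path: str | os.PathLike, sets: dict[str, Iterable[str]], desc: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ------------------------------------------------------------ regulator table

def read_regulator_table(path: str | os.PathLike) -> dict[str, list[str]]:
    """TSV of gene -> comma-separated known upstream regulators (may be empty)."""
    table: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0]
            regs = [r for r in parts[1].split(",") if r] if len(parts) > 1 else []
            table[gene] = regs
    return table


def write_regulator_table(path: str | os.PathLike, table: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tregulators\n")
        for gene, regs in table.items():
            fh.write(f"{gene}\t{','.join(regs)}\n")
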
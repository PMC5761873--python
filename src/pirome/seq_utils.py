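"""Small sequence helpers.

piRNA sequences are handled in the RNA alphabet {A,C,G,U} internally;
FASTA/FASTQ files use DNA (T). Conversion happens at the I/O boundary.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over A/C/G/T/U characters."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGTU")
    if acgt == 0:
        raise ValueError("sequence has no A/C/G/T/U characters")
    return (s.count("G") + s.count("C")) / acgt


def is_watson_crick(p: str, t: str) -> bool:
    """True iff RNA bases p and t form a Watson-Crick pair."""
    return (p, t) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def is_wobble(p: str, t: str) -> bool:
    """True iff RNA bases p and t form a G:U wobble pair."""
    return (p, t) in {("G", "U"), ("U", "G")}
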
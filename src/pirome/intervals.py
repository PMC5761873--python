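"""Genomic interval primitives shared by every pipeline stage.

All internal coordinates are 0-based half-open (BED convention).
RepeatMasker ``.out`` files, which are 1-based inclusive, are converted
on ingest; 1-based inclusive lengths printed in reports equal
``end - start`` under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A coordinate span on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open span; ``start < end``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully within this span (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_1based_inclusive(
        cls, chrom: str, first: int, last: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (e.g. RepeatMasker, tables)."""
        return cls(chrom, first - 1, last, strand)

    def to_1based_inclusive(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass
class Feature:
    """An annotated interval: a track entry with a name/label."""

    interval: GenomicInterval
    name: str = ""
    attrs: dict = field(default_factory=dict)
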
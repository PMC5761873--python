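"""From raw small-RNA reads to uniquely mapped, annotated piRNA records.

Reads are converted to the RNA alphabet on ingest; mapping works on the
DNA genome.  "Uniquely mapped" means a single genomic location at the
read's best mismatch tier (0 or 1 substitutions, both strands), the
convention short-read aligners use when reporting unique hits.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from Bio import SeqIO

from .intervals import GenomicInterval
from .io import read_fastq
from .seq_utils import revcomp_dna, to_dna, to_rna

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")


@dataclass
class ReadAlignment:
    read_id: str
    interval: GenomicInterval      # strand carried on the interval
    mismatches: int                # 0 or 1
    unique: bool = True


@dataclass
class PiRNARecord:
    """A known piRNA with its per-sample read support."""

    id: str
    sequence: str                  # RNA alphabet
    loci: list[GenomicInterval] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    context: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def total_count(self) -> int:
        return sum(self.counts.values())


def load_reads(fastq_path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (read_id, RNA sequence) tuples."""
    return [(rid, to_rna(seq)) for rid, seq in read_fastq(fastq_path)]


def filter_by_length(
    reads: list[tuple[str, str]], min_len: int = 16, max_len: int = 40
) -> list[tuple[str, str]]:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    kept = [r for r in reads if min_len <= len(r[1]) <= max_len]
    n_dropped = len(reads) - len(kept)
    if not reads:
        logger.warning("filter_by_length received no reads")
    logger.info("length filter: kept %d, discarded %d", len(kept), n_dropped)
    return kept


# -------------------------------------------------------------------- mapping

def _find_all(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def _one_mismatch_hits(chrom_seq: str, query: str) -> list[int]:
    """Positions where query matches with exactly one substitution.

    Any such occurrence contains one of the two query halves exactly, so
    exact half-matches seed the candidate positions.
    """
    L = len(query)
    half = L // 2
    h1, h2 = query[:half], query[half:]
    candidates = set(_find_all(chrom_seq, h1))
    candidates.update(p - half for p in _find_all(chrom_seq, h2))
    out = []
    for p in candidates:
        if p < 0 or p + L > len(chrom_seq):
            continue
        window = chrom_seq[p:p + L]
        mm = sum(a != b for a, b in zip(window, query))
        if mm == 1:
            out.append(p)
    return sorted(out)


def _locate(genome: dict[str, str], dna: str) -> tuple[list, list]:
    """All (chrom, pos, strand) hits at 0 and exactly 1 mismatch."""
    rc = revcomp_dna(dna)
    exact, near = [], []
    for chrom, seq in genome.items():
        for pos in _find_all(seq, dna):
            exact.append((chrom, pos, "+"))
        for pos in _find_all(seq, rc):
            exact.append((chrom, pos, "-"))
        for pos in _one_mismatch_hits(seq, dna):
            near.append((chrom, pos, "+"))
        for pos in _one_mismatch_hits(seq, rc):
            near.append((chrom, pos, "-"))
    return exact, near


def map_unique(
    reads: list[tuple[str, str]], genome: dict[str, str]
) -> list[ReadAlignment]:
    """Map reads to the genome, returning only uniquely mapped reads.

    A read qualifies iff it has exactly one location at its minimal
    mismatch count (0 or 1); 0-mismatch hits make 1-mismatch hits
    irrelevant.  Reads with non-ACGTN characters are skipped.
    """
    genome = {c: s.upper() for c, s in genome.items()}
    by_seq: dict[str, list[str]] = defaultdict(list)
    for rid, seq in reads:
        by_seq[seq].append(rid)

    hits_cache: dict[str, tuple[int, tuple] | None] = {}
    for seq in by_seq:
        dna = to_dna(seq)
        if any(b not in "ACGTN" for b in dna):
            logger.warning("skipping read with non-ACGTN characters: %r", dna[:20])
            hits_cache[seq] = None
            continue
        exact, near = _locate(genome, dna)
        if len(exact) == 1:
            hits_cache[seq] = (0, exact[0])
        elif not exact and len(near) == 1:
            hits_cache[seq] = (1, near[0])
        else:
            hits_cache[seq] = None

    out: list[ReadAlignment] = []
    for seq, rids in by_seq.items():
        hit = hits_cache[seq]
        if hit is None:
            continue
        mm, (chrom, pos, strand) = hit
        for rid in rids:
            out.append(ReadAlignment(
                rid, GenomicInterval(chrom, pos, pos + len(seq), strand), mm))
    return out


# ----------------------------------------------------------------- annotation

def read_reference_fasta(path) -> dict[str, str]:
    """Load a known-piRNA reference FASTA (RNA alphabet); duplicate ids error."""
    ref: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ref:
            raise ValueError(f"duplicate reference piRNA id {rec.id!r}")
        ref[rec.id] = to_rna(str(rec.seq))
    return ref


def _match_reference(seq: str, reference: dict[str, str],
                     by_len: dict[int, list[str]]) -> str | None:
    """Reference id for a read: identical, or one substitution away from
    exactly one reference (ambiguous 1-mismatch matches stay unassigned)."""
    for rid in by_len.get(len(seq), ()):
        if reference[rid] == seq:
            return rid
    near = []
    for rid in by_len.get(len(seq), ()):
        mm = 0
        for a, b in zip(seq, reference[rid]):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        if mm == 1:
            near.append(rid)
    return near[0] if len(near) == 1 else None


def annotate_known_pirnas(
    samples: dict[str, list[tuple[str, str]]],
    reference: dict[str, str],
) -> tuple[list[PiRNARecord], dict[str, int]]:
    """Aggregate per-sample read counts onto known piRNAs.

    A read counts toward a reference piRNA iff its sequence is identical
    or one substitution away (no indels); reads matching several
    references equally are reported as unassigned.

    Returns (records for piRNAs with at least one read, per-sample
    unassigned-read counts).
    """
    by_len: dict[int, list[str]] = defaultdict(list)
    for rid, seq in reference.items():
        by_len[len(seq)].append(rid)

    records: dict[str, PiRNARecord] = {}
    unassigned: dict[str, int] = {}
    assign_cache: dict[str, str | None] = {}
    for sample, reads in samples.items():
        unassigned[sample] = 0
        counts: Counter[str] = Counter()
        for _rid, seq in reads:
            if seq not in assign_cache:
                assign_cache[seq] = _match_reference(seq, reference, by_len)
            target = assign_cache[seq]
            if target is None:
                unassigned[sample] += 1
            else:
                counts[target] += 1
        for rid, n in counts.items():
            rec = records.setdefault(rid, PiRNARecord(rid, reference[rid]))
            rec.counts[sample] = rec.counts.get(sample, 0) + n
    for rec in records.values():
        for sample in samples:
            rec.counts.setdefault(sample, 0)
    return list(records.values()), unassigned


# -------------------------------------------------------- composition profiles

def length_histogram(records: list[PiRNARecord]) -> dict[int, int]:
    """Distinct-piRNA counts per sequence length."""
    return dict(sorted(Counter(r.length for r in records).items()))


def positional_base_freq(records: list[PiRNARecord], position: int) -> dict[str, float]:
    """Base fractions at a 1-based position; shorter sequences are
    excluded from the denominator."""
    if position < 1:
        raise ValueError("position is 1-based")
    counts = Counter(
        r.sequence[position - 1] for r in records if r.length >= position
    )
    total = sum(counts.values())
    if total == 0:
        return {b: 0.0 for b in RNA_BASES}
    return {b: counts.get(b, 0) / total for b in RNA_BASES}


def biogenesis_signature(
    records: list[PiRNARecord],
) -> tuple[dict[str, str], dict[str, float]]:
    """Label each piRNA by its biogenesis hallmark.

    10A (the ping-pong hallmark) takes precedence: secondary-like iff
    base 10 is A; primary-like iff base 1 is U and base 10 is not A;
    ambiguous otherwise.  Returns (per-record labels, cohort fractions).
    """
    labels: dict[str, str] = {}
    for r in records:
        base1 = r.sequence[0] if r.length >= 1 else ""
        base10 = r.sequence[9] if r.length >= 10 else ""
        if base10 == "A":
            labels[r.id] = "secondary-like"
        elif base1 == "U":
            labels[r.id] = "primary-like"
        else:
            labels[r.id] = "ambiguous"
    n = len(labels)
    fractions = {
        lab: (sum(1 for v in labels.values() if v == lab) / n if n else 0.0)
        for lab in ("primary-like", "secondary-like", "ambiguous")
    }
    return labels, fractions
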
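"""Genomic-context assignment for piRNA loci.

Each locus receives a single category by a fixed priority over
annotation tracks (ncRNA classes above genic features, ``intergenic``
when nothing overlaps), so the genomic-architecture percentages are
disjoint.  Overlap is strand-agnostic and counted at >= 1 shared base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .intervals import Feature, GenomicInterval
from .io import read_bed
from .read_processing import PiRNARecord

#: highest to lowest; repeat subtypes (repeat:SINE, ...) share the
#: priority of their "repeat" base category
DEFAULT_PRIORITY = (
    "tRNA", "rRNA", "srpRNA", "other-sncRNA", "repeat", "pseudogene",
    "lncRNA", "5UTR", "CDS", "3UTR", "intron", "intergenic",
)


def base_category(category: str) -> str:
    return category.split(":", 1)[0]


@dataclass
class AnnotationTrack:
    """A searchable interval collection for one annotation category."""

    category: str
    features: list[Feature] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in self.features:
            self._add_to_tree(f)

    def _add_to_tree(self, f: Feature) -> None:
        self._trees.setdefault(f.interval.chrom, IntervalTree()).addi(
            f.interval.start, f.interval.end, f
        )

    def add(self, f: Feature) -> None:
        self.features.append(f)
        self._add_to_tree(f)

    @classmethod
    def from_bed(cls, category: str, path) -> "AnnotationTrack":
        feats = read_bed(path)
        for f in feats:
            f.attrs.setdefault("category", category)
        return cls(category, feats)

    def overlap(self, query: GenomicInterval) -> list[Feature]:
        """Every track feature sharing >= 1 bp with query (strand ignored);
        unknown chromosomes give an empty list."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(query.start, query.end),
                      key=lambda iv: (iv.begin, iv.end))
        return [iv.data for iv in hits]


def overlap(query: GenomicInterval, track: AnnotationTrack) -> list[Feature]:
    return track.overlap(query)


def assign_context(
    locus: GenomicInterval,
    tracks: list[AnnotationTrack],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> str:
    """Highest-priority category whose track overlaps the locus.

    Returns the track's own (sub)category, e.g. ``repeat:SINE``;
    ``intergenic`` when no track overlaps.
    """
    rank = {cat: i for i, cat in enumerate(priority)}
    best: tuple[int, str] | None = None
    for track in tracks:
        key = base_category(track.category)
        if key not in rank:
            raise ValueError(f"category {track.category!r} missing from priority order")
        if track.overlap(locus):
            cand = (rank[key], track.category)
            if best is None or cand < best:
                best = cand
    return best[1] if best else "intergenic"


def annotate_records(
    records: list[PiRNARecord],
    tracks: list[AnnotationTrack],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> None:
    """Assign a context to each record from its first locus, in place."""
    for rec in records:
        if rec.loci:
            rec.context = assign_context(rec.loci[0], tracks, priority)
        else:
            rec.context = "unmapped"


def architecture_summary(
    records: list[PiRNARecord],
) -> dict[str, tuple[int, float]]:
    """Genomic-architecture breakdown: category -> (count, fraction)."""
    if not records:
        return {}
    counts: dict[str, int] = {}
    for r in records:
        counts[r.context] = counts.get(r.context, 0) + 1
    n = len(records)
    return {cat: (c, c / n) for cat, c in sorted(counts.items())}


def derive_introns(genes: list[Feature], exons: list[Feature]) -> list[Feature]:
    """Intron intervals as gene minus exon, for annotation sources that
    ship only gene and exon tracks."""
    exon_track = AnnotationTrack("exon", list(exons))
    introns: list[Feature] = []
    for g in genes:
        giv = g.interval
        cuts = sorted(
            (max(f.interval.start, giv.start), min(f.interval.end, giv.end))
            for f in exon_track.overlap(giv)
        )
        cursor = giv.start
        k = 0
        for s, e in cuts:
            if s > cursor:
                k += 1
                introns.append(Feature(
                    GenomicInterval(giv.chrom, cursor, s, giv.strand),
                    f"{g.name}-intron{k}", {"category": "intron"}))
            cursor = max(cursor, e)
        if cursor < giv.end:
            introns.append(Feature(
                GenomicInterval(giv.chrom, cursor, giv.end, giv.strand),
                f"{g.name}-intron{k + 1}", {"category": "intron"}))
    return introns


def trna_half_mapping(
    records: list[PiRNARecord], trna_track: AnnotationTrack
) -> dict[str, dict[str, int]]:
    """Per-tRNA-species counts of 5'- vs 3'-half derived piRNAs.

    A tRNA-derived locus is 5'-half if its midpoint lies in the 5' half
    of the gene, strand-aware; a midpoint exactly at the center counts as
    5'-half.  Returns {species: {"5-half": n, "3-half": n}}.
    """
    out: dict[str, dict[str, int]] = {}
    for rec in records:
        for locus in rec.loci:
            for f in trna_track.overlap(locus):
                giv = f.interval
                mid = locus.midpoint
                center = (giv.start + giv.end) / 2
                if giv.strand == "-":
                    label = "5-half" if mid >= center else "3-half"
                else:
                    label = "5-half" if mid <= center else "3-half"
                species = f.name
                out.setdefault(species, {"5-half": 0, "3-half": 0})[label] += 1
    return out
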
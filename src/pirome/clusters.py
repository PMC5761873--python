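"""Sliding-window piRNA cluster detection.

A window of ``window`` bp (default 20 kb), advanced in ``step`` bp
increments (default 1 kb) from each chromosome origin, qualifies when at
least ``min_distinct`` different piRNAs (non-redundant ids, strands
pooled) have a locus overlapping it.  Overlapping or adjacent qualifying
windows merge into one cluster whose span is trimmed to the extent of
its member loci, so reported cluster lengths are not multiples of the
step.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .annotation import AnnotationTrack, base_category
from .intervals import Feature, GenomicInterval

Locus = tuple[str, GenomicInterval]   # (piRNA id, locus)


@dataclass
class Cluster:
    interval: GenomicInterval
    members: dict[str, list[GenomicInterval]]
    strand_counts: tuple[int, int]              # (n_plus, n_minus)
    contained_features: dict[str, list[str]] = field(default_factory=dict)
    repeat_exclusive: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


def scan_windows(
    loci: list[Locus],
    window: int = 20_000,
    step: int = 1_000,
    min_distinct: int = 10,
) -> list[tuple[str, int]]:
    """Qualifying window starts, per chromosome, anchored at multiples of
    ``step`` from the chromosome origin.

    A locus is "in" a window when it overlaps it by >= 1 bp; a window
    qualifies when >= ``min_distinct`` distinct piRNA ids are in it.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    ids_at: dict[tuple[str, int], set[str]] = defaultdict(set)
    for pid, iv in loci:
        # window [s, s+window) overlaps [start, end) iff s in (start-window, end)
        first = max(0, (iv.start - window) // step + 1)
        last = (iv.end - 1) // step
        for k in range(first, last + 1):
            ids_at[(iv.chrom, k * step)].add(pid)
    return sorted(s for s, ids in ids_at.items() if len(ids) >= min_distinct)


def merge_windows(
    windows: list[tuple[str, int]],
    loci: list[Locus],
    window: int = 20_000,
) -> list[Cluster]:
    """Merge overlapping/adjacent qualifying windows into clusters.

    The cluster interval is [min member-locus start, max member-locus
    end] over piRNAs overlapping the merged window span; members are all
    ids with a locus overlapping that span.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, s in windows:
        by_chrom[chrom].append(s)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        starts = sorted(by_chrom[chrom])
        spans: list[tuple[int, int]] = []
        cur_s, cur_e = starts[0], starts[0] + window
        for s in starts[1:]:
            if s <= cur_e:            # overlapping or touching
                cur_e = max(cur_e, s + window)
            else:
                spans.append((cur_s, cur_e))
                cur_s, cur_e = s, s + window
        spans.append((cur_s, cur_e))
        for s, e in spans:
            members: dict[str, list[GenomicInterval]] = defaultdict(list)
            for pid, iv in loci:
                if iv.chrom == chrom and iv.start < e and s < iv.end:
                    members[pid].append(iv)
            all_loci = [iv for ivs in members.values() for iv in ivs]
            lo = min(iv.start for iv in all_loci)
            hi = max(iv.end for iv in all_loci)
            n_plus = sum(1 for iv in all_loci if iv.strand == "+")
            n_minus = sum(1 for iv in all_loci if iv.strand == "-")
            clusters.append(Cluster(
                GenomicInterval(chrom, lo, hi), dict(members), (n_plus, n_minus)))
    return clusters


def detect_clusters(
    loci: list[Locus],
    window: int = 20_000,
    step: int = 1_000,
    min_distinct: int = 10,
) -> list[Cluster]:
    windows = scan_windows(loci, window, step, min_distinct)
    if not windows:
        return []
    return merge_windows(windows, loci, window)


def cluster_length(cluster: Cluster | GenomicInterval) -> int:
    """Cluster length in nucleotides (1-based inclusive: last - first + 1,
    which equals end - start in half-open coordinates)."""
    iv = cluster.interval if isinstance(cluster, Cluster) else cluster
    return iv.end - iv.start


def annotate_cluster_contents(
    cluster: Cluster, tracks: list[AnnotationTrack]
) -> dict[str, list[str]]:
    """Group features overlapping the cluster span by category and flag
    the cluster repeat-exclusive when every member locus lies inside a
    repeat interval."""
    contents: dict[str, list[str]] = {}
    repeat_feats: list[Feature] = []
    for track in tracks:
        hits = track.overlap(cluster.interval)
        if hits:
            contents.setdefault(track.category, []).extend(f.name for f in hits)
        if base_category(track.category) == "repeat":
            repeat_feats.extend(
                f for f in track.features if f.interval.chrom == cluster.interval.chrom
            )
    all_loci = [iv for ivs in cluster.members.values() for iv in ivs]
    cluster.repeat_exclusive = bool(all_loci) and all(
        any(f.interval.contains(iv) for f in repeat_feats) for iv in all_loci
    )
    cluster.contained_features = contents
    return contents
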
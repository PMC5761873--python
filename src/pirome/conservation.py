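"""Per-base conservation scoring of piRNA loci, summarized by context.

Scores (phastCons-style posterior probabilities in [0,1]) load from a
bedGraph into dense per-chromosome arrays with NaN marking uncovered
bases.  A locus score is the arithmetic mean over its covered bases;
uncovered bases are excluded from the denominator by default (matching
standard bigWig interval-averaging tools), with zero-fill available as
an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .io import read_bedgraph


class ConservationTrack:
    """Dense per-base score arrays keyed by chromosome; NaN = uncovered."""

    def __init__(self, scores: dict[str, np.ndarray]):
        self.scores = scores
        for chrom, arr in scores.items():
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr, initial=1.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
                    raise ValueError(f"scores outside [0,1] on {chrom}")

    @classmethod
    def from_bedgraph(cls, path, chrom_lengths: dict[str, int] | None = None
                      ) -> "ConservationTrack":
        entries = list(read_bedgraph(path))
        lengths: dict[str, int] = dict(chrom_lengths or {})
        for chrom, _s, e, _v in entries:
            lengths[chrom] = max(lengths.get(chrom, 0), e)
        arrays = {c: np.full(n, np.nan) for c, n in lengths.items()}
        for chrom, s, e, v in entries:
            arrays[chrom][s:e] = v
        return cls(arrays)

    def covered(self, locus: GenomicInterval) -> np.ndarray:
        arr = self.scores.get(locus.chrom)
        if arr is None:
            return np.empty(0)
        window = arr[locus.start:min(locus.end, len(arr))]
        return window[~np.isnan(window)]


def mean_conservation(
    locus: GenomicInterval, track: ConservationTrack, zero_fill: bool = False
) -> float | None:
    """Mean score over the locus; None when no base is covered.

    With ``zero_fill`` uncovered bases count as 0 in the denominator.
    Strand plays no role.
    """
    vals = track.covered(locus)
    if zero_fill:
        return float(vals.sum()) / len(locus)
    if vals.size == 0:
        return None
    return float(vals.mean())


@dataclass
class ContextSummary:
    category: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    ci90_low: float
    ci90_high: float
    min: float
    max: float


def summarize_by_context(
    scores: list[tuple[str, str, float]],
) -> list[ContextSummary]:
    """Order statistics and mean with a normal-approximation 90% CI
    (mean +/- 1.645 sd/sqrt(n)) per context category.

    ``scores`` holds (piRNA id, context, score) triples; categories with
    no scores are omitted; a single score gives a degenerate CI.
    """
    by_cat: dict[str, list[float]] = {}
    for _pid, ctx, s in scores:
        if s is not None:
            by_cat.setdefault(ctx, []).append(float(s))
    out = []
    for cat in sorted(by_cat):
        vals = np.asarray(by_cat[cat])
        n = vals.size
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        half = 1.645 * sd / math.sqrt(n)
        mean = float(vals.mean())
        out.append(ContextSummary(
            category=cat,
            n=n,
            median=float(np.median(vals)),
            q1=float(np.percentile(vals, 25)),
            q3=float(np.percentile(vals, 75)),
            mean=mean,
            ci90_low=mean - half,
            ci90_high=mean + half,
            min=float(vals.min()),
            max=float(vals.max()),
        ))
    return out
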
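"""Synthetic small-RNA study generator with planted ground truth.

Emulates the statistical structure of a piRNA profiling experiment in
tumor vs. normal tissue so every downstream stage can be tested without
external downloads:

* a small multi-chromosome genome with non-overlapping annotation
  features (tRNA, rRNA, lncRNA, 5'UTR/CDS/3'UTR, intron, repeats,
  pseudogenes) laid out on a spaced grid;
* 26-32 nt piRNA loci with a 1U bias and 10A depletion, implanted into
  the genome so each read maps uniquely;
* planted piRNA clusters (>= 10 distinct loci within a 20 kb span) on a
  background whose locus spacing guarantees no spurious cluster;
* a per-base conservation track drawn from context-specific Beta
  distributions (e.g. tRNA ~ 0.99, intron ~ 0.02);
* two-condition read counts from a negative-binomial model with planted
  fold-changes (including "anomalous" piRNAs that are silent in one
  condition);
* transcripts embedding SINE-like elements that carry near-perfect
  complementary sites for designated piRNAs, together with the
  expression matrix, gene sets and regulator table the target cascade
  consumes.  Decoy sites violate exactly one cascade rule each.

Files use the DNA alphabet; analysis modules convert to RNA on ingest.
Identical config + seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .intervals import Feature, GenomicInterval
from .seq_utils import revcomp_dna, to_dna, to_rna

REGIONS = ("5UTR", "CDS", "3UTR")
DECOY_KINDS = (None, "no_rte", "seed", "regulator", "not_down", "no_pathway")

#: categories treated as retrotransposable-element repeat classes
RTE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "SVA", "Retroposon")


class ConfigurationError(ValueError):
    """Raised when a simulation config cannot be realized."""


# --------------------------------------------------------------------- config

@dataclass(frozen=True)
class ContextSpec:
    """How many features of a category to place and their length range."""

    category: str
    count: int
    length_range: tuple[int, int]


@dataclass(frozen=True)
class PlantedCluster:
    chrom: str
    start: int
    end: int
    n_loci: int


@dataclass(frozen=True)
class PlantedSite:
    """A complementary site for ``pirna_id`` embedded in a transcript region.

    ``n_gu``/``n_mismatches`` G:U wobble and mismatch edits are applied to
    the otherwise perfect reverse-complement site, at ``edit_positions``
    (1-based piRNA positions; G:U positions listed first) or at drawn
    positions when not given.  ``decoy`` plants a single-rule violation:
    one of ``no_rte``, ``seed``, ``regulator``, ``not_down``,
    ``no_pathway``.
    """

    pirna_id: str
    transcript_id: str
    region: str = "3UTR"
    n_mismatches: int = 0
    n_gu: int = 0
    edit_positions: tuple[int, ...] = ()
    decoy: str | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    context_layout: list[ContextSpec] = field(default_factory=list)
    n_pirnas: int = 150
    pirna_length_range: tuple[int, int] = (26, 32)
    u1_freq: float = 0.8
    a10_freq: float = 0.1
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    planted_anomalous: list[str] = field(default_factory=list)
    conservation_by_context: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    samples: dict[str, str] = field(
        default_factory=lambda: {"normal": "control", "tumor": "case"}
    )
    nb_dispersion: float = 0.05
    mean_count_log: float = float(np.log(300.0))
    mean_count_sigma: float = 0.5
    n_junk_reads: int = 40
    n_background_genes: int = 200
    n_background_transcripts: int = 20
    expr_group_size: int = 5
    expr_noise_sd: float = 0.3
    expr_planted_log2fc: float = -2.0
    region_lengths: dict[str, int] = field(
        default_factory=lambda: {"5UTR": 200, "CDS": 700, "3UTR": 500}
    )

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ConfigurationError("need >=1 chromosome of >=1 kb")
        lo, hi = self.pirna_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid pirna_length_range")
        for f in (self.u1_freq, self.a10_freq):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("base-frequency parameters must lie in [0,1]")
        for fc in self.planted_fold_changes.values():
            if fc <= 0:
                raise ConfigurationError("fold changes must be positive")
        for site in self.planted_sites:
            if site.region not in REGIONS:
                raise ConfigurationError(f"unknown region {site.region!r}")
            if site.decoy not in DECOY_KINDS:
                raise ConfigurationError(f"unknown decoy kind {site.decoy!r}")


def default_context_layout() -> list[ContextSpec]:
    return [
        ContextSpec("tRNA", 10, (72, 72)),
        ContextSpec("rRNA", 4, (110, 130)),
        ContextSpec("lncRNA", 6, (800, 1200)),
        ContextSpec("5UTR", 8, (150, 250)),
        ContextSpec("CDS", 8, (800, 1200)),
        ContextSpec("3UTR", 8, (250, 400)),
        ContextSpec("intron", 10, (1500, 2500)),
        ContextSpec("repeat:SINE", 16, (280, 320)),
        ContextSpec("repeat:LINE", 6, (800, 1200)),
        ContextSpec("pseudogene", 4, (600, 900)),
    ]


def default_conservation() -> dict[str, tuple[float, float]]:
    """(median, concentration) of the per-base Beta score by context."""
    return {
        "tRNA": (0.99, 100.0),
        "rRNA": (0.02, 100.0),
        "lncRNA": (0.02, 100.0),
        "5UTR": (0.30, 100.0),
        "CDS": (0.60, 100.0),
        "3UTR": (0.30, 100.0),
        "intron": (0.02, 100.0),
        "repeat:SINE": (0.02, 100.0),
        "repeat:LINE": (0.02, 100.0),
        "pseudogene": (0.02, 100.0),
        "intergenic": (0.02, 100.0),
    }


def _pid(i: int) -> str:
    return f"piR-sim-{i:04d}"


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions used throughout the test-bed."""
    fcs: dict[str, float] = {}
    for i in range(1, 12):
        # site-carrying piRNAs: strongly (6-fold) up-regulated, the
        # regime where a single library per condition detects them
        # unambiguously
        fcs[_pid(i)] = 6.0
    fcs[_pid(12)] = 4.0             # planted up, |log2FC| = 2
    for i in range(13, 21):
        fcs[_pid(i)] = 0.25         # planted down
    sites = [
        PlantedSite(_pid(1), "TX-G001", "3UTR", 0, 0),
        PlantedSite(_pid(2), "TX-G002", "3UTR", 1, 0),
        PlantedSite(_pid(3), "TX-G003", "3UTR", 0, 1, edit_positions=(15,)),
        PlantedSite(_pid(4), "TX-G004", "CDS", 0, 0),
        PlantedSite(_pid(5), "TX-G005", "5UTR", 0, 0),
        PlantedSite(_pid(6), "TX-G006", "3UTR", 1, 1),
        PlantedSite(_pid(7), "TX-G007", "3UTR", 0, 0, decoy="no_rte"),
        PlantedSite(_pid(8), "TX-G008", "3UTR", 2, 0, decoy="seed"),
        PlantedSite(_pid(9), "TX-G009", "3UTR", 0, 0, decoy="regulator"),
        PlantedSite(_pid(10), "TX-G010", "3UTR", 0, 0, decoy="not_down"),
        PlantedSite(_pid(11), "TX-G011", "3UTR", 0, 0, decoy="no_pathway"),
    ]
    return SimulationConfig(
        seed=seed,
        context_layout=default_context_layout(),
        planted_clusters=[
            PlantedCluster("chr1", 50_000, 70_000, 12),
            PlantedCluster("chr2", 150_000, 170_000, 15),
        ],
        planted_fold_changes=fcs,
        planted_anomalous=[_pid(21), _pid(22)],
        conservation_by_context=default_conservation(),
        planted_sites=sites,
    )


# --------------------------------------------------------------- ground truth

@dataclass
class PiRNATruth:
    pirna_id: str
    sequence: str                  # RNA alphabet
    locus: GenomicInterval
    context: str
    in_cluster: bool
    fold_change: float
    de_status: str                 # up | down | unchanged | anomalous
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SiteTruth:
    site: PlantedSite
    transcript_start: int          # 0-based in transcript coordinates
    transcript_end: int
    gu_positions: tuple[int, ...]  # 1-based piRNA positions
    mm_positions: tuple[int, ...]


@dataclass
class GroundTruth:
    config: SimulationConfig
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    pirnas: dict[str, PiRNATruth] = field(default_factory=dict)
    cluster_spans: list[PlantedCluster] = field(default_factory=list)
    sites: list[SiteTruth] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    paths: dict[str, str] = field(default_factory=dict)
    genome: dict[str, str] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | os.PathLike) -> None:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        payload = {
            "chrom_lengths": self.chrom_lengths,
            "pirnas": {k: dataclasses.asdict(v) for k, v in self.pirnas.items()},
            "cluster_spans": [dataclasses.asdict(c) for c in self.cluster_spans],
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "down_genes": self.down_genes,
            "paths": self.paths,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=enc)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ------------------------------------------------------------- genome layout

_MARGIN = 3_000
_GAP_RANGE = (2_400, 3_400)   # inter-feature gap: keeps background loci sparse
_MIN_LOCUS_SEP = 2_400        # at most 9 loci fit in any 20 kb window


def _layout_features(config: SimulationConfig, rng: np.random.Generator) -> list[Feature]:
    """Place annotation features on a spaced, non-overlapping grid.

    Planted cluster spans are skipped so cluster membership stays under
    the generator's control; two SINE features are added inside each
    planted span afterwards so clusters harbor repeat elements.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for pc in config.planted_clusters:
        if pc.chrom not in spans_by_chrom:
            raise ConfigurationError(f"planted cluster on unknown chromosome {pc.chrom}")
        if pc.end > config.chrom_length:
            raise ConfigurationError("planted cluster exceeds chromosome length")
        spans_by_chrom[pc.chrom].append((pc.start, pc.end))

    # round-robin assignment of features to chromosomes
    queue: list[ContextSpec] = []
    for spec in config.context_layout:
        queue.extend([spec] * spec.count)
    per_chrom: dict[str, list[ContextSpec]] = {c: [] for c in chroms}
    for i, spec in enumerate(queue):
        per_chrom[chroms[i % len(chroms)]].append(spec)

    features: list[Feature] = []
    counters: dict[str, int] = {}
    trna_species = ["Val-CAC", "Val-AAC", "Gly-GCC", "Met-CAT", "Lys-CTT"]
    for chrom in chroms:
        cursor = _MARGIN
        blocked = sorted(spans_by_chrom[chrom])
        for spec in per_chrom[chrom]:
            lo, hi = spec.length_range
            length = int(rng.integers(lo, hi + 1))
            # jump past planted-cluster spans
            for bs, be in blocked:
                if cursor < be and bs < cursor + length:
                    cursor = be + int(rng.integers(*_GAP_RANGE))
            if cursor + length > config.chrom_length - _MARGIN:
                raise ConfigurationError(
                    f"context layout for category {spec.category!r} exceeds "
                    f"{chrom} length {config.chrom_length}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            k = counters.get(spec.category, 0)
            counters[spec.category] = k + 1
            if spec.category == "tRNA":
                name = f"tRNA-{trna_species[k % len(trna_species)]}-{k + 1}"
            else:
                name = f"{spec.category.replace(':', '_')}-{k + 1}"
            features.append(
                Feature(GenomicInterval(chrom, cursor, cursor + length, strand),
                        name, {"category": spec.category})
            )
            cursor += length + int(rng.integers(*_GAP_RANGE))
    # repeats inside planted cluster spans
    for j, pc in enumerate(config.planted_clusters):
        for off in (2_000, 9_000):
            start = pc.start + off
            features.append(
                Feature(
                    GenomicInterval(pc.chrom, start, start + 300, "+"),
                    f"repeat_SINE-cluster{j + 1}-{off}",
                    {"category": "repeat:SINE"},
                )
            )
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return features


def _draw_pirna_sequence(rng: np.random.Generator, length: int,
                         u1_freq: float, a10_freq: float) -> str:
    """RNA sequence with the configured 1U bias and 10A level."""
    bases = np.array(list("ACGU"))
    seq = list(bases[rng.integers(0, 4, size=length)])
    seq[0] = "U" if rng.random() < u1_freq else str(rng.choice(["A", "C", "G"]))
    if length >= 10:
        seq[9] = "A" if rng.random() < a10_freq else str(rng.choice(["C", "G", "U"]))
    return "".join(seq)


def sample_pirna_sequences(config: SimulationConfig, n: int) -> list[str]:
    """Draw n piRNA sequences from the generator's composition model
    (length range, 1U bias, 10A level), without building a genome.

    Deterministic for a fixed config seed; intended for composition
    estimates at sample sizes larger than a single simulated study.
    """
    rng = _rng(config, 7)
    lo, hi = config.pirna_length_range
    return [
        _draw_pirna_sequence(rng, int(rng.integers(lo, hi + 1)),
                             config.u1_freq, config.a10_freq)
        for _ in range(n)
    ]


def _place_pirna_loci(
    config: SimulationConfig,
    features: list[Feature],
    rng: np.random.Generator,
) -> list[tuple[GenomicInterval, str, bool]]:
    """Return (locus, context, in_cluster) triples.

    Cluster loci go inside planted spans.  Background loci sit either
    fully inside a feature or fully between features, at pairwise
    distances of at least ``_MIN_LOCUS_SEP`` so that no 20 kb window off
    a planted span can ever collect 10 distinct loci, and at least 20 kb
    away from every planted span so detected clusters never absorb
    background loci.  Feature-anchor spacing is guaranteed by the layout
    gap; extra loci come from a spaced intergenic grid.
    """
    import bisect

    lo_len, hi_len = config.pirna_length_range
    out: list[tuple[GenomicInterval, str, bool]] = []

    cluster_feats = [f for f in features if "cluster" in f.name]
    for pc in config.planted_clusters:
        if (pc.end - pc.start) < pc.n_loci * (hi_len + 10):
            raise ConfigurationError(
                f"cluster span {pc.chrom}:{pc.start}-{pc.end} too small for "
                f"{pc.n_loci} non-overlapping loci"
            )
        used: list[int] = []
        for _ in range(pc.n_loci):
            length = int(rng.integers(lo_len, hi_len + 1))
            while True:
                start = int(rng.integers(pc.start, pc.end - hi_len))
                # implanted loci must not overlap, or later implants
                # would overwrite earlier piRNA sequences in the genome
                if all(abs(start - u) > hi_len + 1 for u in used):
                    used.append(start)
                    break
            iv = GenomicInterval(pc.chrom, start, start + length,
                                 "+" if rng.random() < 0.7 else "-")
            ctx = "intergenic"
            for f in cluster_feats:
                if f.interval.overlaps(iv):
                    ctx = f.attrs["category"]
            out.append((iv, ctx, True))

    n_cluster = len(out)
    n_background = config.n_pirnas - n_cluster
    if n_background < 0:
        raise ConfigurationError("n_pirnas smaller than the planted cluster loci")

    buffer = 20_000
    blocked = [(pc.chrom, pc.start - buffer, pc.end + buffer)
               for pc in config.planted_clusters]

    def is_blocked(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in blocked)

    kept: dict[str, list[int]] = {}   # sorted anchor starts per chromosome

    def fits(chrom: str, pos: int) -> bool:
        row = kept.setdefault(chrom, [])
        i = bisect.bisect_left(row, pos)
        if i > 0 and pos - row[i - 1] < _MIN_LOCUS_SEP:
            return False
        if i < len(row) and row[i] - pos < _MIN_LOCUS_SEP:
            return False
        return True

    # one anchor per feature; their pairwise spacing is >= the layout gap
    candidates: list[tuple[str, int, str, str]] = []  # chrom, start, context, strand
    plain = [f for f in features if "cluster" not in f.name]
    for f in plain:
        iv = f.interval
        if len(iv) < hi_len:
            continue
        cat = f.attrs["category"]
        if cat == "tRNA":
            # tRNA-derived piRNAs come from the 5' half of the gene
            if iv.strand == "+":
                start = iv.start + int(rng.integers(0, 4))
            else:
                start = iv.end - hi_len - int(rng.integers(0, 4))
            candidates.append((iv.chrom, start, cat, iv.strand))
        else:
            start = int(rng.integers(iv.start, iv.end - hi_len + 1))
            candidates.append((iv.chrom, start, cat,
                               "+" if rng.random() < 0.5 else "-"))
    candidates = [c for c in candidates if not is_blocked(c[0], c[1])]

    # select n_background anchors, cycling over categories so every
    # context is represented; grid positions top up when features run out
    by_cat: dict[str, list[tuple[str, int, str, str]]] = {}
    for c in candidates:
        by_cat.setdefault(c[2], []).append(c)

    grid: list[tuple[str, int, str, str]] = []
    feat_sorted = sorted(plain, key=lambda f: (f.interval.chrom, f.interval.start))
    for chrom in sorted({f.interval.chrom for f in feat_sorted} | set(
            f"chr{i + 1}" for i in range(config.n_chromosomes))):
        chrom_feats = [f.interval for f in feat_sorted if f.interval.chrom == chrom]
        for pos in range(_MARGIN, config.chrom_length - _MARGIN - hi_len,
                         _MIN_LOCUS_SEP + 200):
            if is_blocked(chrom, pos):
                continue
            inside = [iv for iv in chrom_feats
                      if iv.start < pos + hi_len and pos < iv.end]
            if inside:
                continue  # straddles or lies in a feature; feature anchors cover those
            grid.append((chrom, pos, "intergenic", "+" if rng.random() < 0.5 else "-"))
    by_cat.setdefault("intergenic", []).extend(grid)

    chosen: list[tuple[str, int, str, str]] = []
    order = sorted(by_cat)
    progress = True
    while len(chosen) < n_background and progress:
        progress = False
        for cat in order:
            while by_cat[cat]:
                cand = by_cat[cat].pop(0)
                if fits(cand[0], cand[1]):
                    bisect.insort(kept[cand[0]], cand[1])
                    chosen.append(cand)
                    progress = True
                    break
            if len(chosen) >= n_background:
                break
    if len(chosen) < n_background:
        raise ConfigurationError(
            f"layout supports only {len(chosen)} background loci, "
            f"need {n_background}; enlarge chromosomes or context counts"
        )
    for chrom, start, cat, strand in sorted(chosen, key=lambda c: (c[0], c[1])):
        length = int(rng.integers(lo_len, hi_len + 1))
        out.append((GenomicInterval(chrom, start, start + length, strand), cat, False))
    return out


# ----------------------------------------------------------------- operations

def generate_genome(config: SimulationConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Emit genome FASTA, per-category BED tracks, RepeatMasker-style
    ``.out``, a bedGraph conservation track, and the piRNA reference
    FASTA; return the ground truth (piRNA loci, contexts, clusters)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 0)

    features = _layout_features(config, rng)
    loci = _place_pirna_loci(config, features, rng)

    # random genome, then implant piRNA sequences at their loci
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome: dict[str, np.ndarray] = {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=config.chrom_length)].copy()
        for i in range(config.n_chromosomes)
    }

    truth = GroundTruth(config=config)
    truth.chrom_lengths = {c: config.chrom_length for c in genome}
    truth.features = features
    truth.cluster_spans = list(config.planted_clusters)

    seen: set[str] = set()
    for i, (iv, ctx, in_cluster) in enumerate(loci, start=1):
        while True:
            seq = _draw_pirna_sequence(rng, len(iv), config.u1_freq, config.a10_freq)
            if seq not in seen:
                seen.add(seq)
                break
        dna = to_dna(seq)
        segment = dna if iv.strand == "+" else revcomp_dna(dna)
        genome[iv.chrom][iv.start:iv.end] = np.frombuffer(segment.encode(), dtype="S1")
        pid = _pid(i)
        fc = config.planted_fold_changes.get(pid, 1.0)
        if pid in config.planted_anomalous:
            status = "anomalous"
        elif fc >= 1.5:
            status = "up"
        elif fc <= 1 / 1.5:
            status = "down"
        else:
            status = "unchanged"
        truth.pirnas[pid] = PiRNATruth(pid, seq, iv, ctx, in_cluster, fc, status)

    for pid in list(config.planted_fold_changes) + list(config.planted_anomalous):
        if pid not in truth.pirnas:
            raise ConfigurationError(f"planted fold-change for unknown piRNA {pid!r}")

    truth.genome = {c: arr.tobytes().decode() for c, arr in genome.items()}
    fa = outdir / "genome.fa"
    pio.write_fasta(fa, truth.genome)
    truth.paths["genome"] = str(fa)

    # per-category BED tracks
    by_cat: dict[str, list[Feature]] = {}
    for f in features:
        by_cat.setdefault(f.attrs["category"], []).append(f)
    for cat, feats in sorted(by_cat.items()):
        path = outdir / f"track_{cat.replace(':', '_')}.bed"
        pio.write_bed(path, feats)
        truth.paths[f"track:{cat}"] = str(path)

    # RepeatMasker-style .out for repeat features plus excluded-class decoys
    rm_path = outdir / "genome_repeats.out"
    rm_rows = []
    for f in by_cat.get("repeat:SINE", []) + by_cat.get("repeat:LINE", []):
        klass = "SINE/Alu" if "SINE" in f.attrs["category"] else "LINE/L1"
        name = "AluSyn" if "SINE" in f.attrs["category"] else "L1Syn"
        rm_rows.append((f.interval, name, klass))
    _write_repeatmasker_out(rm_path, rm_rows)
    truth.paths["repeats_out"] = str(rm_path)

    _write_conservation(config, truth, features, outdir, _rng(config, 3))

    ref = outdir / "pirna_reference.fa"
    pio.write_fasta(ref, {pid: to_dna(p.sequence) for pid, p in truth.pirnas.items()})
    truth.paths["pirna_reference"] = str(ref)
    truth.to_json(outdir / "ground_truth.json")
    truth.paths["ground_truth"] = str(outdir / "ground_truth.json")
    return truth


def _write_repeatmasker_out(
    path: Path, rows: list[tuple[GenomicInterval, str, str]]
) -> None:
    """Write a minimal standard-layout RepeatMasker .out (1-based inclusive)."""
    header = (
        "   SW  perc perc perc  query     position in query    matching  repeat         position in repeat\n"
        "score  div. del. ins.  sequence  begin  end  (left)   repeat    class/family   begin  end (left)  ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, (iv, name, klass) in enumerate(rows, start=1):
            first, last = iv.to_1based_inclusive()
            left = 0
            fh.write(
                f" 1000 10.0 0.0 0.0 {iv.chrom} {first} {last} ({left}) + "
                f"{name} {klass} 1 {len(iv)} (0) {i}\n"
            )


def _beta_params(median: float, conc: float) -> tuple[float, float]:
    m = min(max(median, 1e-4), 1 - 1e-4)
    return m * conc, (1 - m) * conc


def _write_conservation(
    config: SimulationConfig,
    truth: GroundTruth,
    features: list[Feature],
    outdir: Path,
    rng: np.random.Generator,
) -> None:
    """bedGraph covering every base: per-base scores inside features,
    200 bp constant chunks elsewhere, drawn per-context from Beta laws."""
    spec = dict(default_conservation())
    spec.update(config.conservation_by_context)
    inter_a, inter_b = _beta_params(*spec.get("intergenic", (0.02, 100.0)))
    entries: list[tuple[str, int, int, float]] = []
    for chrom, length in truth.chrom_lengths.items():
        cursor = 0
        for f in [f for f in features if f.interval.chrom == chrom]:
            iv = f.interval
            while cursor < iv.start:
                end = min(cursor + 200, iv.start)
                entries.append((chrom, cursor, end, float(rng.beta(inter_a, inter_b))))
                cursor = end
            a, b = _beta_params(*spec.get(f.attrs["category"], (0.02, 100.0)))
            scores = rng.beta(a, b, size=len(iv))
            for off, s in enumerate(scores):
                entries.append((chrom, iv.start + off, iv.start + off + 1, float(s)))
            cursor = iv.end
        while cursor < length:
            end = min(cursor + 200, length)
            entries.append((chrom, cursor, end, float(rng.beta(inter_a, inter_b))))
            cursor = end
    path = outdir / "conservation.bedGraph"
    pio.write_bedgraph(path, entries)
    truth.paths["conservation"] = str(path)


def generate_pirna_reads(
    config: SimulationConfig, truth: GroundTruth, outdir: str | os.PathLike
) -> GroundTruth:
    """Emit one FASTQ per sample realizing the planted fold-changes under
    a negative-binomial count model; record realized counts in the truth."""
    if not truth.pirnas:
        raise ConfigurationError("generate_genome must run before generate_pirna_reads")
    outdir = Path(outdir)
    rng = _rng(config, 1)
    disp = config.nb_dispersion
    nsize = 1.0 / disp

    base_mean = {
        pid: float(rng.lognormal(config.mean_count_log, config.mean_count_sigma))
        for pid in truth.pirnas
    }
    case_samples = [s for s, c in config.samples.items() if c == "case"]
    control_samples = [s for s, c in config.samples.items() if c == "control"]
    if not case_samples or not control_samples:
        raise ConfigurationError("need at least one case and one control sample")

    for sample, condition in config.samples.items():
        reads: list[tuple[str, str]] = []
        for pid, p in truth.pirnas.items():
            mu = base_mean[pid]
            if p.de_status == "anomalous":
                mu = 0.0 if condition == "control" else max(mu, 200.0)
            elif condition == "case":
                mu = mu * p.fold_change
            if mu <= 0:
                count = 0
            else:
                count = int(rng.negative_binomial(nsize, nsize / (nsize + mu)))
            p.counts[sample] = count
            dna = to_dna(p.sequence)
            for k in range(count):
                reads.append((f"{sample}:{pid}:{k}", dna))
        # off-range junk reads exercising the length filter
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for j in range(config.n_junk_reads):
            length = int(rng.choice([12, 14, 44, 50]))
            seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
            reads.append((f"{sample}:junk:{j}", seq))
        path = outdir / f"reads_{sample}.fastq"
        pio.write_fastq(path, reads)
        truth.paths[f"reads:{sample}"] = str(path)

    counts_path = outdir / "true_counts.tsv"
    with open(counts_path, "w") as fh:
        samples = list(config.samples)
        fh.write("pirna_id\t" + "\t".join(samples) + "\tfold_change\tde_status\n")
        for pid, p in truth.pirnas.items():
            row = "\t".join(str(p.counts[s]) for s in samples)
            fh.write(f"{pid}\t{row}\t{p.fold_change}\t{p.de_status}\n")
    truth.paths["true_counts"] = str(counts_path)
    return truth


# ------------------------------------------------------------- transcriptome

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _apply_site_edits(
    site_rna: list[str], pirna: str, site: PlantedSite, rng: np.random.Generator
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Edit the perfect complementary site in place.

    ``site_rna`` is the target site 5'->3'; piRNA position i (1-based)
    pairs with site position L-i (0-based).  Returns the realized G:U and
    mismatch positions (1-based piRNA coordinates).
    """
    L = len(pirna)
    wanted = site.n_gu + site.n_mismatches
    positions = list(site.edit_positions)
    # drawn edits for sites meant to pass the seed rule stay in 9-21 and
    # at least 3 nt apart: in the heavily weighted 2-8 span (and next to
    # another edit) an aligner can profitably bulge the edited target
    # base out and pair the position Watson-Crick with a flank base,
    # which would fail the no-gap seed rule the site should satisfy
    lo = 2 if site.decoy == "seed" else 9
    pool = [p for p in range(lo, min(L, 21) + 1) if p not in positions]
    rng.shuffle(pool)

    gu_pos: list[int] = []
    mm_pos: list[int] = []

    def spaced(p: int) -> bool:
        return all(abs(p - other) >= 3 for other in gu_pos + mm_pos)

    # G:U edits need a piRNA G or U at the position
    for k in range(site.n_gu):
        pos = positions[k] if k < len(positions) else None
        if pos is None or pirna[pos - 1] not in "GU":
            pos = next((p for p in pool if pirna[p - 1] in "GU" and spaced(p)), None)
            if pos is None:
                raise ConfigurationError(
                    f"no G/U piRNA position available for a wobble edit in {site.pirna_id}"
                )
            pool.remove(pos)
        site_rna[L - pos] = "U" if pirna[pos - 1] == "G" else "G"
        gu_pos.append(pos)
    for k in range(site.n_mismatches):
        idx = site.n_gu + k
        pos = positions[idx] if idx < len(positions) else None
        if pos is None or pos in gu_pos:
            pos = next((p for p in pool if spaced(p)), None)
            if pos is None:
                raise ConfigurationError(
                    f"no piRNA position available for a mismatch edit in {site.pirna_id}"
                )
            pool.remove(pos)
        p = pirna[pos - 1]
        bad = [b for b in "ACGU" if b != _WC[p] and {p, b} != {"G", "U"}]
        site_rna[L - pos] = bad[int(rng.integers(0, len(bad)))]
        mm_pos.append(pos)
    if len(gu_pos) + len(mm_pos) != wanted:
        raise ConfigurationError("could not realize the configured site edits")
    return tuple(gu_pos), tuple(mm_pos)


def generate_transcripts(
    config: SimulationConfig, truth: GroundTruth, outdir: str | os.PathLike
) -> GroundTruth:
    """Emit transcript FASTA + region TSV + transcript-coordinate repeat
    ``.out`` + expression matrix + gene sets + regulator table.

    Each planted site sits inside a SINE-like repeat in its stated
    region, built as the reverse complement of the piRNA with the
    configured G:U/mismatch edits.  Target-gene expression realizes the
    planted down-regulation; decoy genes violate exactly one cascade rule.
    """
    for site in config.planted_sites:
        if site.pirna_id not in truth.pirnas:
            raise ConfigurationError(f"planted site references unknown piRNA {site.pirna_id!r}")
    outdir = Path(outdir)
    rng = _rng(config, 2)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    region_lengths = dict(config.region_lengths)
    tx_sites: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites:
        tx_sites.setdefault(site.transcript_id, []).append(site)

    seqs: dict[str, str] = {}
    regions: list[tuple[str, str, int, int]] = []
    repeats: list[tuple[GenomicInterval, str, str]] = []
    gene_of: dict[str, str] = {}

    def rand_dna(n: int) -> str:
        return bases[rng.integers(0, 4, size=n)].tobytes().decode()

    for tx_id in sorted(tx_sites):
        gene = tx_id.split("-", 1)[1] if "-" in tx_id else tx_id
        gene_of[tx_id] = gene
        parts: dict[str, list[str]] = {r: list(rand_dna(region_lengths[r])) for r in REGIONS}
        offset = 0
        bounds: dict[str, tuple[int, int]] = {}
        for r in REGIONS:
            bounds[r] = (offset, offset + region_lengths[r])
            offset += region_lengths[r]
        for site in tx_sites[tx_id]:
            pirna = truth.pirnas[site.pirna_id].sequence
            L = len(pirna)
            rlen = region_lengths[site.region]
            if rlen < L + 24:
                raise ConfigurationError(
                    f"region {site.region} of {tx_id} too short for a planted site"
                )
            site_rna = list(to_rna(revcomp_dna(to_dna(pirna))))
            gu_pos, mm_pos = _apply_site_edits(site_rna, pirna, site, rng)
            local = 12 + int(rng.integers(0, rlen - L - 24))
            parts[site.region][local:local + L] = list(to_dna("".join(site_rna)))
            start = bounds[site.region][0] + local
            end = start + L
            truth.sites.append(SiteTruth(site, start, end, gu_pos, mm_pos))
            # repeat interval around the site
            if site.decoy == "no_rte":
                repeats.append((GenomicInterval(tx_id, max(0, start - 8), end + 8),
                                "SimpleSyn", "Simple_repeat"))
                # a non-excluded repeat elsewhere keeps the gene RTE-containing
                repeats.append((GenomicInterval(tx_id, 5, 80), "AluSyn", "SINE/Alu"))
            else:
                repeats.append((GenomicInterval(tx_id, max(0, start - 8), end + 8),
                                "AluSyn", "SINE/Alu"))
        seqs[tx_id] = "".join("".join(parts[r]) for r in REGIONS)
        for r in REGIONS:
            regions.append((tx_id, r, bounds[r][0], bounds[r][1]))

    # background transcripts: RTE-containing but without planted sites
    bg_tx = []
    for i in range(1, config.n_background_transcripts + 1):
        tx_id = f"TX-B{i:03d}"
        bg_tx.append(tx_id)
        gene_of[tx_id] = f"B{i:03d}"
        seqs[tx_id] = rand_dna(1400)
        for r, (s, e) in zip(REGIONS, ((0, 200), (200, 900), (900, 1400))):
            regions.append((tx_id, r, s, e))
        repeats.append((GenomicInterval(tx_id, 950, 1250), "AluSyn", "SINE/Alu"))

    fa = outdir / "transcripts.fa"
    pio.write_fasta(fa, seqs)
    truth.paths["transcripts"] = str(fa)
    reg_path = outdir / "transcript_regions.tsv"
    with open(reg_path, "w") as fh:
        fh.write("transcript_id\tregion\tstart\tend\n")
        for tx_id, r, s, e in regions:
            fh.write(f"{tx_id}\t{r}\t{s}\t{e}\n")
    truth.paths["transcript_regions"] = str(reg_path)
    rm_path = outdir / "transcript_repeats.out"
    _write_repeatmasker_out(rm_path, repeats)
    truth.paths["transcript_repeats"] = str(rm_path)

    # gene-to-transcript map
    map_path = outdir / "gene_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx_id in sorted(gene_of):
            fh.write(f"{tx_id}\t{gene_of[tx_id]}\n")
    truth.paths["gene_map"] = str(map_path)

    _write_expression_and_sets(config, truth, gene_of, outdir, rng)
    truth.to_json(Path(truth.paths["ground_truth"]))
    return truth


def _write_expression_and_sets(
    config: SimulationConfig,
    truth: GroundTruth,
    gene_of: dict[str, str],
    outdir: Path,
    rng: np.random.Generator,
) -> None:
    site_genes = {gene_of[s.site.transcript_id]: s.site for s in truth.sites}
    down_genes = sorted(
        g for g, s in site_genes.items() if s.decoy != "not_down"
    )
    bg_genes = [f"BG{i:03d}" for i in range(1, config.n_background_genes + 1)]
    bg_tx_genes = sorted({g for g in gene_of.values() if g.startswith("B") and not g.startswith("BG")})
    extra_down = bg_tx_genes[: len(bg_tx_genes) // 2]
    down_genes_all = sorted(set(down_genes) | set(extra_down))
    truth.down_genes = down_genes_all

    genes = sorted(set(site_genes) | set(bg_tx_genes) | set(bg_genes))
    n = config.expr_group_size
    cols = [f"N{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]
    base = rng.uniform(6.0, 12.0, size=len(genes))
    # planted target genes are well expressed so the 20th-percentile
    # intensity floor never removes them
    for i, g in enumerate(genes):
        if g in site_genes or g in bg_tx_genes:
            base[i] = rng.uniform(9.5, 12.0)
    mat = np.tile(base[:, None], (1, 2 * n)) + rng.normal(
        0.0, config.expr_noise_sd, size=(len(genes), 2 * n)
    )
    for i, g in enumerate(genes):
        if g in down_genes_all:
            mat[i, n:] += config.expr_planted_log2fc
    expr_path = outdir / "expression_log2.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cols) + "\n")
        for i, g in enumerate(genes):
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in mat[i]) + "\n")
    truth.paths["expression"] = str(expr_path)
    groups_path = outdir / "expression_groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for c in cols:
            fh.write(f"{c}\t{'control' if c.startswith('N') else 'case'}\n")
    truth.paths["expression_groups"] = str(groups_path)

    # gene sets: a disease set enriched for the planted targets, plus
    # canonical-pathway/network sets lacking the no_pathway decoy genes
    no_pathway = {g for g, s in site_genes.items() if s.decoy == "no_pathway"}
    disease = {
        "Cancer_process": sorted(set(site_genes) | set(bg_genes[:10])),
        "Unrelated_disease": sorted(bg_genes[20:60]),
    }
    pathways = {
        "Pathway_X": sorted((set(site_genes) - no_pathway) | set(bg_genes[10:15])),
        "Network_Y": sorted(set(list(site_genes)[: len(site_genes) // 2]) - no_pathway
                            | set(bg_genes[15:20])),
        "Pathway_bg": sorted(bg_genes[60:100]),
    }
    d_path, p_path = outdir / "disease_sets.gmt", outdir / "pathway_sets.gmt"
    pio.write_gmt(d_path, disease)
    pio.write_gmt(p_path, pathways)
    truth.paths["disease_sets"] = str(d_path)
    truth.paths["pathway_sets"] = str(p_path)

    regulators: dict[str, list[str]] = {}
    for g, s in site_genes.items():
        regulators[g] = ["TP53"] if s.decoy == "regulator" else []
    for g in bg_genes[:30]:
        regulators[g] = ["MYC"]
    reg_path = outdir / "regulators.tsv"
    pio.write_regulator_table(reg_path, regulators)
    truth.paths["regulators"] = str(reg_path)


def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Run the three generators in order and return the full ground truth."""
    outdir = Path(outdir)
    truth = generate_genome(config, outdir)
    generate_pirna_reads(config, truth, outdir)
    generate_transcripts(config, truth, outdir)
    return truth
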
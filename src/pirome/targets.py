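"""piRNA -> mRNA target prediction cascade.

The aligner is a miRanda-style Smith-Waterman local complementarity
search: the piRNA (5'->3') is aligned against the reversed transcript so
that pairing is antiparallel, with Watson-Crick, G:U-wobble, mismatch
and affine gap scores (an optional miRanda-like scale factor boosts
piRNA positions 2-8).  Duplex free energy is a simplified
nearest-neighbor stacking sum over consecutive pairs using a packaged
parameter table, with a constant penalty per internal interruption.

Candidate sites must clear the published thresholds (alignment score
>= 170 and energy <= -20 kcal/mol), sit inside a retrotransposable
element, satisfy Watson-Crick pairing across the primary (2-11) and
secondary (12-21) seed regions with at most one G:U and one mismatch,
and the target genes must be down-regulated, enriched in disease gene
sets, lack known upstream regulators, and belong to a canonical pathway
or network set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .io import read_fasta
from .seq_utils import is_watson_crick, is_wobble, to_rna

RTE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "SVA", "Retroposon")
EXCLUDED_REPEAT_CLASSES = ("Simple_repeat", "Low_complexity")
SEED_RANGE = (2, 21)


# ------------------------------------------------------------------- scoring

@dataclass(frozen=True)
class DuplexScoring:
    """Pair/gap weights for the complementarity alignment.

    ``seed_scale`` multiplies pair scores at piRNA positions 2-8
    (miRanda applies such a scale in its seed region); the library
    default leaves it at 1 so scores are plain sums, while the pipeline
    preset uses 4.0.
    """

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_scale: float = 1.0
    report_floor: float = 60.0
    max_sites: int = 10


#: preset used by the end-to-end pipeline; the seed scale makes the
#: published score threshold (170) reachable for 26-32 nt piRNAs, and
#: the reporting floor sits just under that threshold to skip rescans
#: for sites that could never pass it
PIPELINE_SCORING = DuplexScoring(seed_scale=4.0, report_floor=160.0)


@dataclass
class DuplexAlignment:
    """A local piRNA:transcript duplex.

    ``pairing`` covers piRNA positions ``pirna_start..pirna_end``
    (1-based) with ``|`` Watson-Crick, ``:`` G:U wobble, ``.`` mismatch,
    ``-`` piRNA base opposite a gap.  ``insertions_after`` lists piRNA
    positions followed by unpaired target bases (target-side bulges).
    ``pair_bases`` holds (piRNA position, piRNA base, target base) for
    the paired positions.
    """

    pirna_id: str
    transcript_id: str
    target_start: int
    target_end: int
    pirna_start: int
    pirna_end: int
    pairing: str
    score: float
    pirna_length: int = 0
    pair_bases: list[tuple[int, str, str]] = field(default_factory=list)
    insertions_after: set[int] = field(default_factory=set)
    energy: float | None = None

    def pairing_at(self, position: int) -> str:
        """Pairing symbol at a 1-based piRNA position ('-' outside span)."""
        if self.pirna_start <= position <= self.pirna_end:
            return self.pairing[position - self.pirna_start]
        return "-"

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.transcript_id, self.target_start, self.target_end)


def _check_rna(seq: str, what: str) -> str:
    seq = to_rna(seq)
    if any(b not in "ACGU" for b in seq):
        raise ValueError(f"{what} contains non-ACGU symbols")
    return seq


def _pair_class(p: str, t: str) -> str:
    if is_watson_crick(p, t):
        return "|"
    if is_wobble(p, t):
        return ":"
    return "."


def duplex_align(
    pirna_id: str,
    pirna: str,
    transcript_id: str,
    transcript: str,
    scoring: DuplexScoring = DuplexScoring(),
) -> list[DuplexAlignment]:
    """All non-overlapping local duplex optima above the reporting floor.

    Smith-Waterman with affine gaps of the piRNA versus the reversed
    transcript (antiparallel pairing); alignments end on a paired
    position.  Ties break deterministically: highest score, then
    leftmost target start, then shortest.  Found sites mask their target
    bases and the search repeats, so reported sites never overlap.
    """
    p = _check_rna(pirna, "piRNA")
    t = _check_rna(transcript, "transcript")
    if not p or not t:
        return []
    trev = t[::-1]
    n, m = len(p), len(trev)
    NEG = float("-inf")

    weight = {"|": scoring.match, ":": scoring.wobble, ".": scoring.mismatch}
    pscore = [
        [
            weight[_pair_class(p[i], trev[k])]
            * (scoring.seed_scale if 2 <= i + 1 <= 8 else 1.0)
            for k in range(m)
        ]
        for i in range(n)
    ]

    masked = np.zeros(m, dtype=bool)
    out: list[DuplexAlignment] = []
    for _round in range(scoring.max_sites):
        # DP matrices: M pair state, X piRNA-base-vs-gap, Y target-base-vs-gap
        M = [[0.0] * (m + 1) for _ in range(n + 1)]
        X = [[NEG] * (m + 1) for _ in range(n + 1)]
        Y = [[NEG] * (m + 1) for _ in range(n + 1)]
        ptrM = [[0] * (m + 1) for _ in range(n + 1)]   # 0 stop, 1 M, 2 X, 3 Y
        for i in range(1, n + 1):
            Mi, Xi, Yi, Pi = M[i], X[i], Y[i], ptrM[i]
            Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
            srow = pscore[i - 1]
            for k in range(1, m + 1):
                Xi[k] = max(Mu[k] + scoring.gap_open, Xu[k] + scoring.gap_extend)
                if masked[k - 1]:
                    Yi[k] = NEG
                    Mi[k] = 0.0
                    Pi[k] = 0
                    continue
                Yi[k] = max(Mi[k - 1] + scoring.gap_open, Yi[k - 1] + scoring.gap_extend)
                best, ptr = 0.0, 0
                dm, dx, dy = Mu[k - 1], Xu[k - 1], Yu[k - 1]
                if dm > best:
                    best, ptr = dm, 1
                if dx > best:
                    best, ptr = dx, 2
                if dy > best:
                    best, ptr = dy, 3
                v = best + srow[k - 1]
                if v <= 0.0:
                    Mi[k] = 0.0
                    Pi[k] = 0
                else:
                    Mi[k] = v
                    Pi[k] = ptr

        # best end cell: max score, then leftmost target start (max k),
        # then shortest piRNA extent (min i)
        best_score, bi, bk = NEG, -1, -1
        for i in range(1, n + 1):
            Mi = M[i]
            for k in range(1, m + 1):
                v = Mi[k]
                if v > best_score or (
                    v == best_score and (k > bk or (k == bk and i < bi))
                ):
                    best_score, bi, bk = v, i, k
        if best_score < scoring.report_floor:
            break

        # traceback from (bi, bk) through pair states
        pairs: list[tuple[int | None, int | None]] = []
        i, k, state = bi, bk, 1
        while i > 0 and k > 0:
            if state == 1:
                pairs.append((i, k))
                nxt = ptrM[i][k]
                i, k = i - 1, k - 1
                if nxt == 0:
                    break
                state = nxt
            elif state == 2:   # piRNA base vs gap
                pairs.append((i, None))
                state = 1 if X[i][k] == M[i - 1][k] + scoring.gap_open else 2
                i -= 1
            else:              # target base vs gap
                pairs.append((None, k))
                state = 1 if Y[i][k] == M[i][k - 1] + scoring.gap_open else 3
                k -= 1
        pairs.reverse()

        p_positions = [pi for pi, _ in pairs if pi is not None]
        k_positions = [kk for _, kk in pairs if kk is not None]
        p_lo, p_hi = min(p_positions), max(p_positions)
        k_lo, k_hi = min(k_positions), max(k_positions)
        sym: dict[int, str] = {}
        pair_bases: list[tuple[int, str, str]] = []
        insertions: set[int] = set()
        last_p = None
        for pi, kk in pairs:
            if pi is not None and kk is not None:
                c = _pair_class(p[pi - 1], trev[kk - 1])
                sym[pi] = c
                pair_bases.append((pi, p[pi - 1], trev[kk - 1]))
                last_p = pi
            elif pi is not None:
                sym[pi] = "-"
                last_p = pi
            elif last_p is not None:
                insertions.add(last_p)
        pairing = "".join(sym.get(pos, "-") for pos in range(p_lo, p_hi + 1))
        # transcript coordinates (trev index k is transcript position m-k)
        t_start, t_end = m - k_hi, m - k_lo + 1
        out.append(DuplexAlignment(
            pirna_id, transcript_id, t_start, t_end, p_lo, p_hi,
            pairing, float(best_score), n, pair_bases, insertions))
        masked[k_lo - 1:k_hi] = True
        if masked.all():
            break
    out.sort(key=lambda a: (a.target_start, a.pirna_start))
    return out


# -------------------------------------------------------------------- energy

def _load_nn_table() -> dict:
    with resources.files("pirome.data").joinpath("nn_stacks.json").open() as fh:
        return json.load(fh)


_NN = _load_nn_table()


def _stack_energy(p1: str, t1: str, p2: str, t2: str) -> float:
    """dG of the 5'p1p2 / 3't1t2 stack; both pairs must be WC or wobble."""
    key = f"{p1}{p2}/{t1}{t2}"
    alt = f"{t2}{t1}/{p2}{p1}"   # same duplex read from the other strand
    for k in (key, alt):
        if k in _NN["wc"]:
            return _NN["wc"][k]
    for k in (key, alt):
        if k in _NN["gu"]:
            return _NN["gu"][k]
    return _NN["gu"]["default"]


def duplex_energy(alignment: DuplexAlignment,
                  loop_penalty: float | None = None) -> float | None:
    """Nearest-neighbor free energy of the duplex in kcal/mol.

    Consecutive paired positions contribute their stacking term; every
    internal interruption (mismatch, bulge or gap between helices) adds
    a constant penalty; one helix-initiation term applies.  Returns None
    when nothing pairs (undefined marker).
    """
    paired = [(pos, pb, tb) for pos, pb, tb in alignment.pair_bases
              if _pair_class(pb, tb) in "|:"]
    if not paired:
        return None
    penalty = _NN["loop_penalty"] if loop_penalty is None else loop_penalty
    energy = _NN["initiation"]
    n_break = 0
    for (pos_a, pa, ta), (pos_b, pb, tb) in zip(paired, paired[1:]):
        # antiparallel: consecutive piRNA positions pair consecutive
        # target bases; anything else interrupts the helix
        contiguous = (
            pos_b == pos_a + 1
            and pos_a not in alignment.insertions_after
            and alignment.pairing_at(pos_a) in "|:"
            and alignment.pairing_at(pos_b) in "|:"
        )
        if contiguous:
            energy += _stack_energy(pa, ta, pb, tb)
        else:
            n_break += 1
    energy += n_break * penalty
    return float(energy)


def attach_energies(alignments: list[DuplexAlignment]) -> None:
    for a in alignments:
        a.energy = duplex_energy(a)


# ------------------------------------------------------------- binding sites

@dataclass
class BindingSite:
    alignment: DuplexAlignment
    region: str = ""
    within_rte: bool = False
    gu_2_21: int = 0
    mm_2_21: int = 0
    seed_pass: bool = False

    @property
    def gene(self) -> str | None:
        return getattr(self, "_gene", None)


def region_of_midpoint(
    position: int, regions: Mapping[str, tuple[int, int]]
) -> str:
    for name, (s, e) in regions.items():
        if s <= position < e:
            return name
    return "unassigned"


def threshold_filter(
    alignments: Iterable[DuplexAlignment],
    regions_by_transcript: Mapping[str, Mapping[str, tuple[int, int]]],
    sc_min: float = 170.0,
    en_max: float = -20.0,
) -> list[BindingSite]:
    """Keep duplexes with score >= sc_min AND energy <= en_max (bounds
    inclusive, as published); label the region from the site midpoint."""
    sites = []
    for a in alignments:
        if a.energy is None:
            raise ValueError("energies must be attached before threshold_filter")
        if a.score >= sc_min and a.energy <= en_max:
            mid = (a.target_start + a.target_end) // 2
            region = region_of_midpoint(
                mid, regions_by_transcript.get(a.transcript_id, {}))
            sites.append(BindingSite(a, region=region))
    return sites


# ---------------------------------------------------------------- seed rules

@dataclass(frozen=True)
class SeedResult:
    ok: bool
    gu: int
    mismatch: int


def seed_filter(
    site: BindingSite | DuplexAlignment | str,
    rule: str = "gu_and_mismatch",
) -> SeedResult:
    """Seed-region screen over piRNA positions 2-21.

    Gaps (and target-side bulges) are forbidden in the range; G:U
    wobbles (g) and mismatches (m) are counted, and the site passes with
    g <= 1 and m <= 1 under the default rule, or g + m <= 1 under the
    stricter ``combined`` rule.  A plain pairing string indexed from
    piRNA position 1 is also accepted.
    """
    if rule not in ("gu_and_mismatch", "combined"):
        raise ValueError(f"unknown seed rule {rule!r}")
    if isinstance(site, BindingSite):
        aln: DuplexAlignment | None = site.alignment
    elif isinstance(site, DuplexAlignment):
        aln = site
    else:
        aln = None

    lo, hi = SEED_RANGE
    g = m = 0
    gapped = False
    if aln is None:
        pairing = str(site)
        for pos in range(lo, min(hi, len(pairing)) + 1):
            c = pairing[pos - 1]
            if c == "-":
                gapped = True
            elif c == ":":
                g += 1
            elif c == ".":
                m += 1
    else:
        if aln.pirna_length:
            hi = min(hi, aln.pirna_length)
        for pos in range(lo, hi + 1):
            c = aln.pairing_at(pos)
            if c == "-":
                gapped = True
            elif c == ":":
                g += 1
            elif c == ".":
                m += 1
            if pos < hi and pos in aln.insertions_after:
                gapped = True
    if gapped:
        ok = False
    elif rule == "combined":
        ok = g + m <= 1
    else:
        ok = g <= 1 and m <= 1
    result = SeedResult(ok, g, m)
    if isinstance(site, BindingSite):
        site.gu_2_21, site.mm_2_21, site.seed_pass = g, m, ok
    return result


# --------------------------------------------------------------- RepeatMasker

@dataclass
class RepeatHit:
    interval: GenomicInterval      # chrom = query sequence name
    name: str
    klass: str

    @property
    def excluded(self) -> bool:
        return self.klass.split("/")[0] in EXCLUDED_REPEAT_CLASSES

    @property
    def is_rte(self) -> bool:
        return self.klass.split("/")[0] in RTE_CLASSES


def parse_repeatmasker_out(path) -> dict[str, list[RepeatHit]]:
    """Parse a standard RepeatMasker ``.out`` (3 header lines, whitespace
    fields, 1-based inclusive query coordinates -> converted to 0-based
    half-open).  Simple repeats and low-complexity records are kept but
    flagged ``excluded``.  Malformed data lines raise with the line number.
    """
    out: dict[str, list[RepeatHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if lineno <= 3 and not tokens[0].replace(".", "").isdigit():
                continue   # header
            try:
                query = tokens[4]
                begin, end = int(tokens[5]), int(tokens[6])
                name, klass = tokens[9], tokens[10]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed RepeatMasker line {lineno}: {line!r}") from exc
            out.setdefault(query, []).append(
                RepeatHit(GenomicInterval.from_1based_inclusive(query, begin, end),
                          name, klass))
    return out


def rte_containment(site: BindingSite, repeats: Iterable[RepeatHit]) -> bool:
    """True iff the site's target interval is fully contained in a
    non-excluded retrotransposable-element interval."""
    iv = site.alignment.target_interval
    site.within_rte = any(
        r.is_rte and not r.excluded and r.interval.contains(iv) for r in repeats
    )
    return site.within_rte


# ------------------------------------------------------------ gene-level screens

def regulator_filter(
    genes: Iterable[str], table: Mapping[str, list[str]]
) -> list[str]:
    """Genes with no known upstream regulator (absent from the table or
    listed with an empty regulator set)."""
    return [g for g in genes if not table.get(g)]


def ora_enrichment(
    genes: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Returns one row per gene set with overlap counts, p, q and the
    overlapping genes; ``enriched`` flags q <= alpha.
    """
    genes = set(genes)
    universe = set(universe) | genes
    cols = ["gene_set", "n_set", "n_overlap", "p_value", "q_value",
            "enriched", "overlap_genes"]
    if not genes or not gene_sets:
        return pd.DataFrame(columns=cols)
    M, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        members_u = members & universe
        overlap = sorted(genes & members_u)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, len(members_u), n)) if k else 1.0
        rows.append((name, len(members_u), k, p, overlap))
    pvals = [r[3] for r in rows]
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        [(name, ns, k, p, q, q <= alpha, ov)
         for (name, ns, k, p, ov), q in zip(rows, qvals)],
        columns=cols)


# ------------------------------------------------------------------ cascade

@dataclass
class Transcript:
    """A transcript with region boundaries in transcript coordinates."""

    id: str
    gene_id: str
    sequence: str                                  # RNA alphabet
    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        spans = [self.regions[r] for r in ("5UTR", "CDS", "3UTR") if r in self.regions]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping/unordered regions in {self.id}")


def load_transcripts(
    fasta_path, regions_path, gene_map: Mapping[str, str] | None = None
) -> dict[str, Transcript]:
    seqs = read_fasta(fasta_path)
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    tbl = pd.read_csv(regions_path, sep="\t")
    for row in tbl.itertuples(index=False):
        regions.setdefault(row.transcript_id, {})[row.region] = (
            int(row.start), int(row.end))
    out = {}
    for tx_id, seq in seqs.items():
        gene = (gene_map or {}).get(tx_id) or tx_id
        out[tx_id] = Transcript(tx_id, gene, to_rna(seq), regions.get(tx_id, {}))
    return out


@dataclass
class StageLog:
    stage: str
    genes_in: int
    genes_out: int


def run_cascade(
    up_pirnas: Mapping[str, str],
    down_genes: Iterable[str],
    transcripts: Mapping[str, Transcript],
    repeats: Mapping[str, list[RepeatHit]],
    regulator_table: Mapping[str, list[str]],
    disease_sets: Mapping[str, set[str]],
    pathway_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    scoring: DuplexScoring = PIPELINE_SCORING,
    sc_min: float = 170.0,
    en_max: float = -20.0,
    seed_rule: str = "gu_and_mismatch",
    ora_alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[StageLog]]:
    """Seven-stage target-prediction cascade.

    (1) down-regulated genes whose transcripts harbor a non-excluded
    repeat; (2) complementarity alignment + score/energy thresholds;
    (3) genes belonging to a disease/cancer gene set enriched in the
    candidate list; (4) no known upstream regulator; (5) binding site
    inside an RTE; (6) seed-region rule; (7) membership in a canonical
    pathway or network set.  Each stage logs gene counts in/out.

    Returns (final site table, stage logs).
    """
    logs: list[StageLog] = []
    down = set(down_genes)

    def log(stage: str, before: set[str], after: set[str]) -> None:
        logs.append(StageLog(stage, len(before), len(after)))

    # stage 1: down-regulated RTE-containing genes
    gene_tx: dict[str, list[Transcript]] = {}
    for tx in transcripts.values():
        gene_tx.setdefault(tx.gene_id, []).append(tx)
    stage1 = {
        g for g in down
        if any(
            any(r.is_rte and not r.excluded for r in repeats.get(tx.id, []))
            for tx in gene_tx.get(g, [])
        )
    }
    log("down_rte_genes", down, stage1)

    # stage 2: alignment + thresholds
    regions_by_tx = {tx.id: tx.regions for tx in transcripts.values()}
    sites: list[BindingSite] = []
    for g in sorted(stage1):
        for tx in gene_tx[g]:
            for pid in sorted(up_pirnas):
                alns = duplex_align(pid, up_pirnas[pid], tx.id, tx.sequence, scoring)
                attach_energies(alns)
                for site in threshold_filter(alns, regions_by_tx, sc_min, en_max):
                    site._gene = g
                    sites.append(site)
    stage2 = {s._gene for s in sites}
    log("alignment_thresholds", stage1, stage2)

    # stage 3: disease-set enrichment
    ora = ora_enrichment(stage2, disease_sets, universe, alpha=ora_alpha)
    enriched_members: set[str] = set()
    for row in ora.itertuples(index=False):
        if row.enriched:
            enriched_members.update(row.overlap_genes)
    stage3 = stage2 & enriched_members
    sites = [s for s in sites if s._gene in stage3]
    log("disease_enrichment", stage2, stage3)

    # stage 4: no known upstream regulator
    stage4 = set(regulator_filter(stage3, regulator_table))
    sites = [s for s in sites if s._gene in stage4]
    log("no_upstream_regulator", stage3, stage4)

    # stage 5: binding site within an RTE
    sites = [s for s in sites
             if rte_containment(s, repeats.get(s.alignment.transcript_id, []))]
    stage5 = {s._gene for s in sites}
    log("rte_containment", stage4, stage5)

    # stage 6: seed rule
    sites = [s for s in sites if seed_filter(s, rule=seed_rule).ok]
    stage6 = {s._gene for s in sites}
    log("seed_rule", stage5, stage6)

    # stage 7: canonical pathway / network membership
    cp_members = set().union(*pathway_sets.values()) if pathway_sets else set()
    sites = [s for s in sites if s._gene in cp_members]
    stage7 = {s._gene for s in sites}
    log("pathway_membership", stage6, stage7)

    rows = []
    for s in sites:
        a = s.alignment
        rows.append({
            "pirna_id": a.pirna_id,
            "gene_id": s._gene,
            "transcript_id": a.transcript_id,
            "region": s.region,
            "site_start": a.target_start,
            "site_end": a.target_end,
            "score": a.score,
            "energy": a.energy,
            "gu_2_21": s.gu_2_21,
            "mm_2_21": s.mm_2_21,
            "pairing": a.pairing,
        })
    table = pd.DataFrame(
        rows, columns=["pirna_id", "gene_id", "transcript_id", "region",
                       "site_start", "site_end", "score", "energy",
                       "gu_2_21", "mm_2_21", "pairing"])
    return table, logs
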
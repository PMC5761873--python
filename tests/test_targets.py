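"""Duplex alignment, energy model, seed rules, RTE parsing, ORA, cascade."""

import numpy as np
import pytest

from pirome import targets as tg
from pirome.intervals import GenomicInterval
from pirome.seq_utils import revcomp_rna, to_rna

RNA = np.array(list("ACGU"))


def rc_rna(seq):
    return revcomp_rna(seq)


# ---------------------------------------------------------------- DP oracle

def oracle_best_local_score(pirna, transcript, sc: tg.DuplexScoring):
    """Independent affine-gap local alignment on the reversed transcript,
    maximizing over alignments that end on a paired position."""
    WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    GU = {("G", "U"), ("U", "G")}
    p, t = pirna, transcript[::-1]
    n, m = len(p), len(t)

    def pscore(i, k):
        pair = (p[i], t[k])
        w = sc.match if pair in WC else (sc.wobble if pair in GU else sc.mismatch)
        return w * (sc.seed_scale if 2 <= i + 1 <= 8 else 1.0)

    NEG = float("-inf")
    best = 0.0
    M = {}
    X = {}
    Y = {}
    for i in range(n):
        for k in range(m):
            diag = [0.0]
            if i > 0 and k > 0:
                diag += [M.get((i - 1, k - 1), NEG), X.get((i - 1, k - 1), NEG),
                         Y.get((i - 1, k - 1), NEG)]
            M[(i, k)] = max(diag) + pscore(i, k)
            xs = [NEG]
            if i > 0:
                xs = [M.get((i - 1, k), NEG) + sc.gap_open,
                      X.get((i - 1, k), NEG) + sc.gap_extend]
            X[(i, k)] = max(xs)
            ys = [NEG]
            if k > 0:
                ys = [M.get((i, k - 1), NEG) + sc.gap_open,
                      Y.get((i, k - 1), NEG) + sc.gap_extend]
            Y[(i, k)] = max(ys)
            best = max(best, M[(i, k)])
    return best


def rand_rna(rng, n):
    return "".join(rng.choice(RNA, size=n))


def test_perfect_complement_scores_five_per_pair():
    rng = np.random.default_rng(1)
    pirna = rand_rna(rng, 30)
    (aln,) = tg.duplex_align("p", pirna, "t", rc_rna(pirna))
    assert aln.score == 150.0
    assert aln.pairing == "|" * 30
    assert (aln.pirna_start, aln.pirna_end) == (1, 30)
    assert aln.target_start == 0 and aln.target_end == 30


def test_empty_transcript_gives_no_alignments():
    assert tg.duplex_align("p", "ACGUACGUACGUACGUACGU", "t", "") == []


def test_non_acgu_symbols_rejected():
    with pytest.raises(ValueError):
        tg.duplex_align("p", "ACGN", "t", "ACGU")


@pytest.mark.parametrize("seed_scale", [1.0, 4.0])
def test_alignment_matches_dp_oracle_on_random_pairs(seed_scale):
    rng = np.random.default_rng(int(seed_scale * 10))
    sc = tg.DuplexScoring(seed_scale=seed_scale, report_floor=1.0, max_sites=1)
    for _ in range(40):
        pirna = rand_rna(rng, int(rng.integers(18, 33)))
        if rng.random() < 0.5:
            transcript = rand_rna(rng, int(rng.integers(20, 61)))
        else:
            # embed a noisy complement so high-scoring paths exist
            core = list(rc_rna(pirna))
            for _i in range(int(rng.integers(0, 5))):
                core[int(rng.integers(0, len(core)))] = str(rng.choice(RNA))
            transcript = (rand_rna(rng, int(rng.integers(0, 15)))
                          + "".join(core) + rand_rna(rng, int(rng.integers(0, 15))))
        want = oracle_best_local_score(pirna, transcript, sc)
        alns = tg.duplex_align("p", pirna, "t", transcript, sc)
        got = max((a.score for a in alns), default=0.0)
        assert got == pytest.approx(want)


def test_planted_wobble_appears_in_pairing_string(sim):
    _config, truth, _ = sim
    from pirome.io import read_fasta
    seqs = {k: to_rna(v) for k, v in read_fasta(truth.paths["transcripts"]).items()}
    wobble_sites = [s for s in truth.sites if s.gu_positions and s.site.decoy is None]
    assert wobble_sites
    for st in wobble_sites:
        pirna = truth.pirnas[st.site.pirna_id].sequence
        alns = tg.duplex_align(st.site.pirna_id, pirna, st.site.transcript_id,
                               seqs[st.site.transcript_id], tg.PIPELINE_SCORING)
        hit = next(a for a in alns
                   if a.target_start >= st.transcript_start - 2
                   and a.target_end <= st.transcript_end + 2)
        for pos in st.gu_positions:
            assert hit.pairing_at(pos) == ":"
        for pos in st.mm_positions:
            assert hit.pairing_at(pos) == "."


# -------------------------------------------------------------------- energy

def perfect_alignment(pirna):
    sc = tg.DuplexScoring(report_floor=1.0, max_sites=1)
    (aln,) = tg.duplex_align("p", pirna, "t", rc_rna(pirna), sc)
    return aln


def test_energy_monotone_in_duplex_length():
    e20 = tg.duplex_energy(perfect_alignment("GCAU" * 5))
    e10 = tg.duplex_energy(perfect_alignment("GCAU" * 5)[:] if False else
                           perfect_alignment("GCAUGCAUGC"))
    assert e20 < e10 < 0


def test_gc_rich_duplex_is_more_stable():
    egc = tg.duplex_energy(perfect_alignment("GC" * 10))
    eau = tg.duplex_energy(perfect_alignment("AU" * 10))
    assert egc < eau


def test_single_pair_has_no_stacking_contribution():
    aln = tg.DuplexAlignment("p", "t", 0, 1, 1, 1, "|", 5.0, 20,
                             pair_bases=[(1, "G", "C")])
    assert tg.duplex_energy(aln) == pytest.approx(tg._NN["initiation"])


def test_no_paired_positions_is_undefined():
    aln = tg.DuplexAlignment("p", "t", 0, 2, 1, 2, "..", -6.0, 20,
                             pair_bases=[(1, "A", "A"), (2, "C", "C")])
    assert tg.duplex_energy(aln) is None


def test_known_stack_arithmetic():
    # 5'-GG-3' / 3'-CC-5' twice in GGG/CCC plus initiation
    aln = perfect_alignment("GGG")
    sc = tg.duplex_energy(aln)
    assert sc == pytest.approx(tg._NN["initiation"] + 2 * tg._NN["wc"]["GG/CC"])


# ---------------------------------------------------------------- thresholds

def site_with(score, energy, t0=0, t1=30, tx="t"):
    aln = tg.DuplexAlignment("p", tx, t0, t1, 1, 30, "|" * 30, score, 30)
    aln.energy = energy
    return aln


def test_threshold_bounds_inclusive():
    regions = {"t": {"5UTR": (0, 100), "CDS": (100, 700), "3UTR": (700, 1100)}}
    kept = tg.threshold_filter([site_with(170.0, -20.0)], regions)
    assert len(kept) == 1
    assert kept[0].region == "5UTR"
    assert tg.threshold_filter([site_with(171.0, -19.0)], regions) == []
    assert tg.threshold_filter([site_with(169.9, -25.0)], regions) == []
    in_3utr = tg.threshold_filter([site_with(200.0, -30.0, 800, 830)], regions)
    assert in_3utr[0].region == "3UTR"


# ---------------------------------------------------------------- seed rules

def test_seed_rule_examples():
    assert tg.seed_filter("|" * 30).ok
    # one G:U at 15 and one mismatch at 22 (outside 2-21): passes
    s = list("|" * 30)
    s[14] = ":"
    s[21] = "."
    r = tg.seed_filter("".join(s))
    assert r.ok and r.gu == 1 and r.mismatch == 0
    # two mismatches within 2-21: fails
    s = list("|" * 30)
    s[5] = s[10] = "."
    assert not tg.seed_filter("".join(s)).ok
    # one G:U and one mismatch: passes default, fails combined rule
    s = list("|" * 30)
    s[5], s[10] = ":", "."
    assert tg.seed_filter("".join(s)).ok
    assert not tg.seed_filter("".join(s), rule="combined").ok
    # any gap in 2-21 fails
    s = list("|" * 30)
    s[10] = "-"
    assert not tg.seed_filter("".join(s)).ok
    with pytest.raises(ValueError):
        tg.seed_filter("|" * 30, rule="bogus")


def test_seed_filter_matches_brute_force_counting():
    rng = np.random.default_rng(8)
    symbols = np.array(list("|:.-"))
    for _ in range(2000):
        L = int(rng.integers(22, 33))
        pairing = "".join(rng.choice(symbols, size=L, p=[0.7, 0.1, 0.1, 0.1]))
        got = tg.seed_filter(pairing)
        window = pairing[1:21]
        g, m = window.count(":"), window.count(".")
        ok = ("-" not in window) and g <= 1 and m <= 1
        assert (got.ok, got.gu, got.mismatch) == (ok, g, m)


# ------------------------------------------------------------- RepeatMasker

RM_TEXT = """   SW  perc perc perc  query    position in query   matching repeat  position in repeat
score  div. del. ins.  sequence begin end (left)    repeat  class/family  begin end (left) ID

 1306 15.6 6.2 0.0 TX1 11 50 (0) + AluY SINE/Alu 1 40 (0) 1
  500 10.0 0.0 0.0 TX1 60 90 (0) + (TTAGGG)n Simple_repeat 1 31 (0) 2
  800 12.0 0.0 0.0 TX2 5 120 (0) C L1M5 LINE/L1 1 116 (0) 3
"""


def test_parse_repeatmasker_out(tmp_path):
    path = tmp_path / "r.out"
    path.write_text(RM_TEXT)
    hits = tg.parse_repeatmasker_out(path)
    assert set(hits) == {"TX1", "TX2"}
    alu, simple = hits["TX1"]
    assert (alu.interval.start, alu.interval.end) == (10, 50)
    assert alu.is_rte and not alu.excluded
    assert simple.excluded and not simple.is_rte
    assert hits["TX2"][0].klass == "LINE/L1"


def test_parse_repeatmasker_empty_and_malformed(tmp_path):
    empty = tmp_path / "e.out"
    empty.write_text("\n")
    assert tg.parse_repeatmasker_out(empty) == {}
    bad = tmp_path / "b.out"
    bad.write_text("header\nheader\n\n 100 1.0 0.0 0.0 TX1 ten 50\n")
    with pytest.raises(ValueError, match="line 4"):
        tg.parse_repeatmasker_out(bad)


def test_rte_containment_requires_full_containment():
    alu = tg.RepeatHit(GenomicInterval("t", 100, 400), "AluY", "SINE/Alu")
    simple = tg.RepeatHit(GenomicInterval("t", 0, 600), "(A)n", "Simple_repeat")
    inside = tg.BindingSite(site_with(200, -30, 150, 180))
    assert tg.rte_containment(inside, [alu, simple])
    half = tg.BindingSite(site_with(200, -30, 380, 420))
    assert not tg.rte_containment(half, [alu, simple])
    only_simple = tg.BindingSite(site_with(200, -30, 450, 480))
    assert not tg.rte_containment(only_simple, [alu, simple])


# ------------------------------------------------------------ gene screens

def test_regulator_filter():
    table = {"A": ["TP53"], "B": [], "C": ["MYC", "E2F1"]}
    assert tg.regulator_filter(["A", "B", "C", "D"], table) == ["B", "D"]
    assert tg.regulator_filter(["A"], {}) == ["A"]


def test_ora_enrichment_hypergeometric():
    universe = [f"u{i}" for i in range(100)]
    hit_set = {f"u{i}" for i in range(10)}
    sets = {"hits": hit_set, "misses": {f"u{i}" for i in range(50, 90)}}
    res = tg.ora_enrichment(list(hit_set), sets, universe)
    res = res.set_index("gene_set")
    assert res.loc["hits", "p_value"] < 1e-10
    assert res.loc["hits", "enriched"]
    assert res.loc["misses", "p_value"] == pytest.approx(1.0)
    assert tg.ora_enrichment([], sets, universe).empty


# -------------------------------------------------------------- cascade

def test_cascade_recovers_planted_sites_and_rejects_decoys(pipeline_run):
    """Every planted valid site chain survives all 7 stages; every
    single-rule-violating decoy is eliminated; stages only shrink."""
    import pandas as pd
    _cfg, _m, truth, results = pipeline_run
    final = pd.read_csv(results / "targets.tsv", sep="\t")
    trace = pd.read_csv(results / "cascade_trace.tsv", sep="\t")

    assert (trace["genes_out"] <= trace["genes_in"]).all()

    valid = {(s.site.pirna_id, s.site.transcript_id)
             for s in truth.sites if s.site.decoy is None}
    decoys = {(s.site.pirna_id, s.site.transcript_id)
              for s in truth.sites if s.site.decoy is not None}
    got = set(zip(final["pirna_id"], final["transcript_id"]))
    assert valid <= got
    assert not (decoys & got)
    # every reported site passed the published thresholds
    assert (final["score"] >= 170).all()
    assert (final["energy"] <= -20).all()
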
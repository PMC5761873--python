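"""Read filtering, unique mapping, known-piRNA annotation, composition."""

import math

import numpy as np
import pytest

from pirome import read_processing as rp
from pirome.seq_utils import revcomp_dna, to_rna


def mk_reads(*seqs):
    return [(f"r{i}", to_rna(s)) for i, s in enumerate(seqs)]


# ------------------------------------------------------------- length filter

def test_length_filter_bounds_inclusive():
    reads = mk_reads("A" * 15, "A" * 16, "A" * 40, "A" * 41)
    kept = rp.filter_by_length(reads)
    assert [len(s) for _r, s in kept] == [16, 40]


def test_length_filter_enumerated_example():
    reads = mk_reads(*["C" * n for n in range(14, 24)])
    assert len(rp.filter_by_length(reads)) == 8


def test_length_filter_empty_input_is_empty_output():
    assert rp.filter_by_length([]) == []


# ------------------------------------------------------------------- mapping

GENOME = {
    "chrA": "TTTTCCGGAATTACGGATCGGCTAGCTAGGATCCGTACGTAGCTAGCTTACG"
            "GCATGCATGGCCTAGGCCTTAAGGCCTTGGACCGGTTACGCCGGAATTACGG",
    #        repeated motif CCGGAATTACGG occurs at 4 and 92
}


def test_multi_hit_read_is_excluded():
    reads = mk_reads("CCGGAATTACGG")
    assert rp.map_unique(reads, GENOME) == []


def test_reverse_complement_read_maps_minus_strand():
    sub = GENOME["chrA"][20:48]
    reads = mk_reads(revcomp_dna(sub))
    (aln,) = rp.map_unique(reads, GENOME)
    assert (aln.interval.start, aln.interval.end) == (20, 48)
    assert aln.interval.strand == "-"
    assert aln.mismatches == 0


def test_one_substitution_read_maps_with_mismatch_one():
    sub = GENOME["chrA"][20:48]
    mutated = sub[:10] + ("A" if sub[10] != "A" else "C") + sub[11:]
    (aln,) = rp.map_unique(mk_reads(mutated), GENOME)
    assert aln.mismatches == 1
    assert (aln.interval.start, aln.interval.end) == (20, 48)


def test_exact_hit_shadows_one_mismatch_hits():
    # an exact hit at one locus ignores any 1-mismatch hits elsewhere
    sub = GENOME["chrA"][56:80]
    (aln,) = rp.map_unique(mk_reads(sub), GENOME)
    assert aln.mismatches == 0


def test_non_acgt_read_is_skipped():
    assert rp.map_unique(mk_reads("ACGXACGTACGTACGT"), GENOME) == []


def test_map_unique_agrees_with_exhaustive_scan():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    genome = {"c1": "".join(rng.choice(bases, 3000)),
              "c2": "".join(rng.choice(bases, 2000))}

    def oracle(dna):
        hits0, hits1 = [], []
        for chrom, seq in genome.items():
            for strand, query in (("+", dna), ("-", revcomp_dna(dna))):
                for pos in range(len(seq) - len(query) + 1):
                    mm = sum(a != b for a, b in zip(seq[pos:pos + len(query)], query))
                    if mm == 0:
                        hits0.append((chrom, pos, strand))
                    elif mm == 1:
                        hits1.append((chrom, pos, strand))
        best = hits0 or hits1
        mmtier = 0 if hits0 else 1
        return (best[0], mmtier) if len(best) == 1 else None

    for trial in range(40):
        if trial % 2 == 0:
            # read drawn from the genome, possibly mutated
            start = int(rng.integers(0, 2960))
            seq = genome["c1"][start:start + 24]
            if trial % 4 == 0:
                i = int(rng.integers(0, 24))
                seq = seq[:i] + str(rng.choice(bases)) + seq[i + 1:]
        else:
            seq = "".join(rng.choice(bases, 24))
        got = rp.map_unique([("r", to_rna(seq))], genome)
        want = oracle(seq)
        if want is None:
            assert got == []
        else:
            (chrom, pos, strand), mm = want
            assert len(got) == 1
            a = got[0]
            assert (a.interval.chrom, a.interval.start, a.interval.strand,
                    a.mismatches) == (chrom, pos, strand, mm)


# ---------------------------------------------------------------- annotation

REF = {"p1": "UGGCAGUCGAGGCUCAGCCAUGACAUUCGA",
       "p2": "UACGGUAGCCAUGGAUCGUUACGGCAGAUU"}


def test_identical_read_counts_toward_reference():
    records, unassigned = rp.annotate_known_pirnas(
        {"s1": [("r1", REF["p1"]), ("r2", REF["p1"])]}, REF)
    (rec,) = records
    assert rec.id == "p1" and rec.counts == {"s1": 2}
    assert unassigned == {"s1": 0}


def test_ambiguous_one_mismatch_read_is_unassigned():
    ref = {"a": "ACGUACGUACGUACGUACGU", "b": "ACGUACGUACGUACGUACGA"}
    # read at hamming distance 1 from both references
    read = "ACGUACGUACGUACGUACGC"
    records, unassigned = rp.annotate_known_pirnas({"s": [("r", read)]}, ref)
    assert records == [] and unassigned == {"s": 1}


def test_empty_reference_leaves_all_unassigned():
    records, unassigned = rp.annotate_known_pirnas(
        {"s": [("r", "ACGUACGUACGUACGU")]}, {})
    assert records == [] and unassigned == {"s": 1}


def test_duplicate_reference_ids_raise(tmp_path):
    fa = tmp_path / "ref.fa"
    fa.write_text(">p1\nACGT\n>p1\nACGG\n")
    with pytest.raises(ValueError, match="duplicate"):
        rp.read_reference_fasta(fa)


# ------------------------------------------------------------- composition

def recs(*seqs):
    return [rp.PiRNARecord(f"p{i}", to_rna(s)) for i, s in enumerate(seqs)]


def test_length_histogram_counts_and_sum():
    assert rp.length_histogram(recs("A" * 26, "C" * 26, "G" * 31)) == {26: 2, 31: 1}
    assert rp.length_histogram([]) == {}
    r = recs(*["A" * n for n in (26, 27, 28, 28)])
    assert sum(rp.length_histogram(r).values()) == len(r)


def test_positional_base_freq_rules():
    r = recs("U" + "C" * 25, "U" + "G" * 25)
    assert rp.positional_base_freq(r, 1) == {"A": 0.0, "C": 0.0, "G": 0.0, "U": 1.0}
    r2 = recs("C" * 9 + "A" + "C" * 16, "C" * 9 + "G" + "C" * 16)
    f = rp.positional_base_freq(r2, 10)
    assert f["A"] == 0.5 and f["G"] == 0.5
    # shorter sequences drop out of the denominator
    r3 = recs("A" * 20, "U" * 30)
    f = rp.positional_base_freq(r3, 25)
    assert f["U"] == 1.0
    assert math.isclose(sum(f.values()), 1.0)


@pytest.mark.parametrize("seq,expected", [
    ("U" + "C" * 8 + "C" + "G" * 16, "primary-like"),    # 1U, 10 not A
    ("U" + "C" * 8 + "A" + "G" * 16, "secondary-like"),  # 10A wins
    ("G" + "C" * 8 + "G" + "G" * 16, "ambiguous"),
])
def test_biogenesis_signature_rules(seq, expected):
    labels, fractions = rp.biogenesis_signature(recs(seq))
    assert labels["p0"] == expected
    assert math.isclose(sum(fractions.values()), 1.0)


def test_u1_frequency_recovered_on_synthetic_reads(sim):
    config, truth, _ = sim
    n = len(truth.pirnas)
    u1 = sum(p.sequence.startswith("U") for p in truth.pirnas.values()) / n
    se = math.sqrt(config.u1_freq * (1 - config.u1_freq) / n)
    assert abs(u1 - config.u1_freq) <= 3 * se
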
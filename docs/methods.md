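# Methods

This note records the scientific and numerical choices behind
`pirome`, stage by stage, the way the package itself is written: the
model each stage assumes, the parameters that matter, and what the
synthetic test-bed does and does not establish.

## Coordinates and alphabets

All internal coordinates are 0-based half-open (BED convention).
RepeatMasker `.out` files are converted on ingest (begin − 1); lengths
printed in 1-based inclusive terms equal `end − start` internally,
which is why the reported length of a cluster spanning 1-based
*a–b* is *b − a + 1*. Sequence files use DNA (T); analysis code uses
RNA (U) internally, with conversion at the I/O boundary.

## Read processing

Reads outside 16–40 nt are discarded (bounds inclusive). Unique
mapping is judged at the read's best mismatch tier: a read with one
perfect genomic location is kept even if one-mismatch locations exist;
a read with no perfect location is kept only if exactly one
one-mismatch location exists (both strands searched). This mirrors the
convention short-read aligners use when reporting "uniquely mapped"
reads. The mapper is an exact scan (substring search seeded by read
halves for the one-mismatch tier), which is the appropriate tool at
test-bed scale; it is oracle-checked against an all-positions scan.

Assignment to known piRNAs requires identical sequence or one
substitution with no indels. A read one mismatch from several
references is left unassigned rather than fractionally counted — the
references are near-identical in that case and any attribution would
be arbitrary. Biogenesis labels: position 10 adenine (the ping-pong
hallmark) takes precedence, so a read with 1U *and* 10A is
secondary-like.

## Genomic context

One category per locus, assigned by a configurable priority with small
ncRNA classes above repeats, repeats above genic features, and intron
last before intergenic. A deterministic single assignment is required
for the architecture percentages to be disjoint; the default order
encodes the biological convention that a locus inside a tRNA or rRNA
gene is named for that gene regardless of overlapping transcripts.
Overlap is strand-agnostic and counted at ≥ 1 shared base. tRNA-half
labels use the locus midpoint against the strand-aware gene center,
ties going to the 5' half.

## Clusters

Windows of 20 kb at 1 kb steps, anchored at multiples of the step from
the chromosome origin (the step phase is otherwise undefined; a fixed
phase keeps results deterministic). Membership is any-overlap;
distinctness is by piRNA id with strands pooled. Merged spans are
trimmed to the extent of member loci so cluster lengths are data
lengths, not multiples of the step. The scan is equivalent to brute
force enumeration of every step-anchored window (tested on random
fixtures), and lowering `min_distinct` can only grow the qualifying
window set.

## Conservation

Locus score = arithmetic mean of per-base scores over covered bases.
Uncovered bases are excluded from the denominator, matching the
behavior of the standard bigWig interval-averaging utilities;
zero-fill is available as a flag because some historical tools did
that instead. Context summaries report n, quartiles, min/max, and a
90% CI of the mean as mean ± 1.645·sd/√n; a single observation yields
a degenerate CI rather than NaN.

## Differential expression

*piRNA counts, no replicates.* Size factors are median-of-ratios over
features with nonzero counts in every sample. With one library per
condition there is no within-condition replication, so dispersion is
estimated "blind": the two conditions are pooled as if replicates,
per-feature method-of-moments dispersions are computed after
subtracting shot noise, and a gamma-family GLM trend α(q) = a₀ + a₁/q
is fitted. Each feature then uses only its fitted trend value
(fit-only sharing) — using per-feature blind estimates would count the
condition effect itself as noise and destroy all power. The trend fit
is iterated with outlier trimming (raw dispersion > 4× the current
trend, starting from the flat median), because a minority of genuinely
differential features would otherwise inflate the shared dispersion of
the majority. The test is a two-sided exact-style test: given the
observed total, every split at least as improbable as the observed one
contributes its probability, with condition totals modeled as negative
binomials matched in mean and variance. The all-zero feature gets
p = 1. Calls: up at FC ≥ 1.5 and p ≤ 0.05 (raw p, inclusive bounds);
"anomalous" marks features with zero total counts in exactly one
condition, whose fold-change is undefined — these are excluded from
up/down rather than forced through a pseudocount.

*Expression matrices.* Input is a normalized log2 matrix. Features
below the 20th percentile of overall mean intensity are removed; a
Welch (unequal-variance) t-test per feature, BH adjustment, and calls
at |FC| ≥ 2 with q ≤ 0.05. Welch is chosen because the groups are
small and variance equality is not defensible.

## Target prediction

*Alignment.* A Smith–Waterman local alignment of the piRNA (5'→3')
against the reversed transcript, so pairing is antiparallel. Defaults:
Watson–Crick +5, G:U wobble +1, mismatch −3, gap open −8, gap extend
−2. An optional scale factor multiplies pair scores at piRNA positions
2–8, as miRanda weights its seed span; the pipeline preset uses 4.0,
without which no 26–32 nt piRNA can reach the score threshold of 170
(a perfect 30-mer at unscaled weights scores 150). Alignments end on a
paired position; non-overlapping suboptimal sites are found by masking
the target span of each reported site and re-scanning, with
deterministic tie-breaks (highest score, then leftmost target start,
then shortest). The aligner is checked against an independently
written DP oracle on random pairs.

*Energy.* A simplified nearest-neighbor model: consecutive paired
positions contribute a Turner-style RNA/RNA stacking term from a
packaged table (Watson–Crick stacks at standard values, G:U stacks
approximated, weak default for missing entries), one helix-initiation
term (+4.09), and a flat +3.0 per internal interruption. This is an
approximation of a full thermodynamic folding computation; it is
monotone in duplex length and orders GC-rich above AU-rich duplexes,
which is what the −20 kcal/mol threshold needs from it.

*Thresholds and rules.* Sites need score ≥ 170 AND energy ≤ −20
(inclusive, as printed). Region labels come from the site midpoint
against the transcript's 5'UTR/CDS/3'UTR boundaries. The seed rule
examines piRNA positions 2–21: gaps (including target-side bulges) are
forbidden; the default rule allows up to one G:U *and* up to one
mismatch — the reading consistent with an accepted duplex carrying one
wobble inside the region and a mismatch outside it — while a stricter
combined ≤ 1 rule is selectable. RTE containment demands the site
fully inside a SINE/LINE/LTR/DNA/SVA interval; simple repeats and
low-complexity regions never qualify. Over-representation is a
one-sided hypergeometric test per gene set with BH adjustment;
"canonical pathway or network" membership is a plain membership test
against user-supplied GMT collections, since the proprietary ontology
such screens originally used cannot be redistributed.

*Cascade order.* (1) down-regulated RTE-containing genes, (2)
alignment + thresholds, (3) disease-set enrichment, (4) no known
upstream regulator, (5) RTE containment, (6) seed rule, (7)
pathway/network membership. Stages only remove genes; each logs
in/out counts so the funnel is auditable.

## Synthetic study design

The generator is the package's study definition, not a tuning knob.
Defaults: 2 chromosomes × 300 kb; ~80 annotation features per genome
laid on a spaced grid (gaps 2.4–3.4 kb) so features never overlap and
every context has unambiguous ground truth; 150 piRNAs of 26–32 nt
with u1_freq = 0.8 and a10_freq = 0.1; two planted clusters (12 and 15
loci in 20 kb spans); negative-binomial counts with dispersion 0.05
around lognormal base means (median ≈ 300); planted fold-changes of
6 for the eleven site-carrying piRNAs (strong up-regulation, the
regime in which a single library per condition detects a piRNA
unambiguously), 4 and 0.25 for the remaining up/down piRNAs, and two
anomalous piRNAs silent in the control library; conservation drawn
per-context from Beta laws with concentration 100 (tRNA median 0.99,
CDS 0.60, UTRs 0.30, everything else 0.02).

Three placement rules make the planted truth exactly recoverable
rather than probably recoverable:

- implanted piRNA loci never overlap (an overlap would overwrite an
  earlier piRNA's genome sequence and silently break unique mapping);
- background loci keep ≥ 2.4 kb pairwise spacing and a 20 kb buffer
  around planted cluster spans, so no 20 kb window off a planted span
  can ever reach 10 distinct loci, for any seed;
- drawn binding-site edits for sites meant to pass the seed rule go to
  piRNA positions 9–21 with ≥ 3 nt spacing: inside the ×4-weighted 2–8
  span (or adjacent to another edit) an optimal aligner profitably
  bulges the edited target base out and pairs the position
  Watson–Crick with a flank base, which would fail the no-gap seed
  rule the site is supposed to satisfy. Decoy sites built to violate
  the seed rule are free of this restriction, since either realization
  fails.

Planted target genes are drawn well expressed (log2 baseline 9.5–12)
so the 20th-percentile intensity floor never removes them; decoy genes
each violate exactly one cascade rule.

The generator does **not** emulate sequencing error, adapter content,
quality decay, multi-mapping repeat-derived reads, overlapping
annotation, or real-genome base composition. Passing the planted-truth
suites therefore shows the *logic* of every stage is correct under the
stated statistical structure; it does not measure robustness to the
artifacts of real libraries.

## Problem sizes

The default test-bed analyzes 150 piRNAs over a 600 kb genome with two
count libraries, a 231-gene × 10-sample expression matrix, and ~30
transcripts; the null-calibration simulation uses 2000 features. These
sizes make the whole suite and the acceptance script run in minutes on
one CPU while keeping every statistical check non-trivial (binomial
tolerances and recovery rates are computed at these n, which the
reports state alongside each value).

## Known limitations

- The exact-style NB test approximates condition totals by
  moment-matched negative binomials; it is conservative rather than
  exactly calibrated (the test suite bounds its null p ≤ 0.05 rate at
  0.10).
- The energy model is a stacking-sum approximation, not a partition
  function; absolute kcal/mol values are comparable within this
  package, not against folding software.
- The packaged known-piRNA FASTA contains synthetic stand-ins matching
  the documented length/GC/composition of the named piRNAs, suitable
  for worked-value checks and demos, not for annotating real
  libraries.
- Cluster counts from real studies depend on the underlying read sets
  and are not reproduced here; the package reproduces the definition
  (window, step, distinctness, merging, trimming) exactly.
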
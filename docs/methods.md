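# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward genomic
strand. GFF3/GTF files and printed region strings
(`chrom:start-end:strand`) are 1-based inclusive and converted at the
I/O boundary; all emitted tables are BED-style (0-based half-open). A
junction is the skipped (intronic) interval of a split read or the gap
between consecutive exons of a transcript model. Junction equality
requires identical chrom/start/end and compatible strand; an unstranded
junction (from reads whose protocol does not encode transcript strand)
matches either strand, and strand is resolved from the host transcript
model when splice-site sequence is needed.

## Detection model

The detector formalises an asymmetry between protocols: reverse
transcription can manufacture junctions, direct RNA sequencing cannot.
A junction is a falsitron candidate iff (i) cDNA-type split support
≥ `min_coverage`, (ii) it is absent from the dRNA junction set,
(iii) dRNA coverage over the interval ≥ `min_coverage`, (iv) it lies
within one dRNA exon (path 1a, checked first) or spans two adjacent
dRNA exons (path 1b), and (v) its terminal dinucleotides are not in
`canonical_pairs`.

Parameter defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 5 reads | support and coverage floor; below this, absence in dRNA is uninformative |
| `canonical_pairs` | {GT–AG} | donor–acceptor pairs excluded as canonical; {GT–AG, GC–AG} available for stricter exclusion of the minor donor |
| `require_absent_in_drna` | true | the defining filter; switchable off for diagnostics |
| `drna_absence_slack` | 0 nt | optional fuzzy absence (junction counted present in dRNA within ± slack on both ends); exact matching is the default because artifact and genuine junctions at the same locus are distinguished by coordinates |

Absence (ii) is tested at read level against all junctions extracted
from the dRNA alignments, not against assembled isoforms: read-level
absence is stricter, well-defined, and independent of any assembler.
Coverage (iii) is direct junction-local read counting — a read whose
aligned span (including skips) intersects the interval by ≥ 1 nt counts
— rather than a transcript-level coverage figure from an assembler; the
same overlap rule defines the abundance denominator, so both
junction-spanning and junction-crossing reads are informative. A
junction satisfying both 1a and 1b is recorded as 1a (containment is
the stricter, lead case). No maximum junction length is imposed
(observed artifacts exceed 2 kb); the minimum is 1 nt by type
invariant.

## Direct-repeat search

For each junction, two windows of `window` = 40 nt (20 nt on each side
of each boundary) are cut and, for minus-strand junctions,
reverse-complemented so the search always runs in transcript
orientation. The splice-site motifs are the first two and last two
intronic bases, located inside their windows. The search returns the
largest k in [`k_min`, `k_max`] = [4, 20] such that some k-mer occurs
in the 5' window overlapping ≥ 1 nt of the donor motif and in the 3'
window overlapping ≥ 1 nt of the acceptor motif. `k_min = 3` is a
supported variant for cataloguing shorter repeats. Ties among equal-k
occurrences break deterministically: smallest combined distance of
occurrence starts to motif starts, then lexicographic k-mer, then
positions. Windows truncated at contig edges shrink with a warning and
the motif offsets shift accordingly; a junction whose motif itself
falls outside the contig is an error.

Two structural notes, both verified by property tests:

* The search is strand-symmetric: a junction and its
  reverse-complement mirror yield identical repeat lengths.
* "Qualifying at k implies qualifying at k−1" holds only
  conditionally. A shared k-mer that touches the donor motif with its
  first base only and the acceptor motif with its last base only has no
  (k−1)-substring keeping both overlaps, because the same end must be
  trimmed in both windows. Closure does hold whenever some qualifying
  occurrence pair overlaps each motif by ≥ 2 nt (trimming one end
  shrinks each overlap by at most 1). The test suite asserts the
  conditional form and relies on exhaustive-enumeration equivalence for
  the search itself.

Summaries over interval sets report the fraction with repeat length
≥ 4 and the lower median among those (even-count medians take the
smaller middle value, keeping the statistic an attained length).

## Quantification

Long-read relative abundance of junction J is split(J) / overlap(J)
with the overlap rule above; it is undefined (reported missing, not 0)
when nothing overlaps. Short-read abundance divides a spliced-read
count by the arithmetic mean of per-base coverage over J — the two
estimators suit the two data shapes (read lists vs coverage vectors)
and are kept distinct.

External junction tables may record a repeat-flanked junction with
boundaries shifted into the repeat copies. The matcher accepts an
observed junction O for query Q with repeat length r iff
O.start = Q.start − s5 and O.end = Q.end + s3 with s5, s3 ∈ [0, r]
(outward only — repeat ambiguity enlarges the apparent intron, never
shrinks it) and |len(O) − len(Q)| ≤ r. The per-side bound and the
length-delta bound are independent constraints: shifts (2, 3) at r = 4
satisfy the former and fail the latter.

## Splice-site composition

For each stranded intron-like interval, 15-nt windows at both sites
(3 exonic + 12 intronic nt, transcript orientation). Position labels:
5' site −3..−1 / +1..+12, 3' site −12..−1 / +1..+3; there is no
position 0. Frequencies are per position over A/C/G/T with ambiguous
bases excluded from that position's denominator (dropping whole
sequences would bias composition toward N-free regions). Intervals
shorter than 12 nt, or whose windows leave the contig, are dropped with
a warning. The output is the count/frequency matrix itself (long-format
TSV); logo rendering is deliberately out of scope — the matrix is the
testable object.

## Synthetic-data generator

The generator emulates the artifact mechanism, not a sequencing
platform. Each gene is a single transcript of 4–6 exons (150–350 nt)
with canonical introns (100–250 nt): GT donor, 14-nt C/T
polypyrimidine tract, AG acceptor. Genes alternate strands along one
chromosome with 300-nt intergenic gaps. A planted locus inside a
middle exon is `R S R` — two identical repeat copies R (configured
length, 0 or 3–16 nt) flanking an intervening segment S, optionally
containing an 8-nt inverted-repeat stem (structural decoration only;
no thermodynamics). The apparent "intron" after slippage is R[1:]+S+R[0]
— length |R| + |S|, drawn uniformly from 150–600 nt.

**Junction register.** A deletion across direct repeats is
coordinate-ambiguous over |R| + 1 registers. Truth intervals and read
skips are both emitted at the register one base into the repeat, so
each repeat copy overlaps its splice-site dinucleotide motif — the
placement actually observed for such artifacts, whose junctions end
inside repetitive sequence. (Under the fully left-shifted register the
downstream copy would start exactly at the junction end and could never
overlap the acceptor motif, making the planted repeat invisible to the
motif-anchored search.) Reads and truth share the register, so
recovery is testable by exact coordinate equality.

Construction is rejection-sampled (≤ 500 attempts per locus) until:
the register is pinned (the base before the locus differs from the last
segment base, and the first segment base differs from the base after
the locus, so neither the gap placement nor the repeat can extend);
the boundary dinucleotides match the requested `canonical_boundaries`
flag (donor = R[1:3], acceptor = S[−1]+R[0], forced to GT/AG when
canonical, resampled away from it otherwise); and the repeat search on
the finished windows returns exactly the planted repeat — in
particular, repeat-length-0 loci are guaranteed free of chance ≥ 4-nt
motif-overlapping repeats. This makes planted truth exact by
construction, not approximately true.

Reads are emitted pre-aligned (SAM, MAPQ 60, one alignment per
molecule): dRNA reads are faithful mature transcripts (true introns as
N skips); cDNA/dcDNA molecules additionally acquire the artifact skip
per planted locus with probability `p_slip` (default 0.3) — dRNA
ignores `p_slip` with a logged warning. PCR amplification is modelled
only as an optional duplication factor on slipped cDNA molecules
(default 1, i.e. off), since the artifact originates at the RT step
common to both cDNA modes. Substitution errors (default 2%) are applied
to base calls from an RNG stream separate from the slippage stream, so
alignment geometry is independent of the error model; indel noise is
deliberately absent because it would perturb CIGARs without exercising
any junction logic. Defaults: 10 genes, 5 planted loci with repeat
lengths 4/6/8/12/16 nt, depth 100 reads per transcript, seed 0;
everything is deterministic given the configuration.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: alignment ambiguity and mapping error
(reads are born aligned; on real data the junction register is the
aligner's choice), ONT error profiles and basecalling artifacts,
multi-isoform genes and expression variation, chance non-canonical
junctions from noisy alignment (the zero-false-positive results hold
in a world where the only junctions are true introns and planted
artifacts), and genome-scale repeat content. The pipeline's behaviour
on those fronts must be judged on real alignments.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at desk scale, chosen as the smallest sizes at which the checked
properties are meaningful: 20 replicate cohorts of 10 genes × 100
reads × 2–3 protocols for recovery; 1000 random window pairs against
brute-force substring enumeration; 100 seeds × 200 reads per slippage
probability (0.05/0.3/0.9) for abundance calibration against the
4·√(p(1−p)/n) binomial bound; exhaustive (shift5, shift3) enumeration
for repeat lengths 0–20 for the matcher.

## Known limitations

* Absence in dRNA is exact-coordinate by default; a genuinely shifted
  representation of the same event in dRNA would defeat it (the
  `drna_absence_slack` option exists for this).
* The candidate deduplication unit is the exact junction; merging
  near-identical candidates across samples is left to the caller.
* The repeat search is exact-match only; mismatch-tolerant repeats,
  inverted-repeat scoring and folding energies are out of scope.
* No statistical test or FDR control is attached to candidacy: the
  cascade is a deterministic filter, and cohort-level statistics are
  the caller's concern.
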
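"""Direct-repeat search: window arithmetic, oracle equivalence,
strand symmetry, closure, planted-truth recovery."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from falsitron import (
    GenomeInterval,
    RepeatSearchParams,
    SimConfig,
    SpliceJunction,
    annotate_repeats,
    max_direct_repeat,
    repeat_for_junction,
    revcomp,
    simulate_genome,
    splice_windows,
)
from conftest import brute_force_max_repeat, random_window_pair


# ---------------------------------------------------------------------------
# window extraction

def _genome_1000(seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])}


def test_splice_windows_plus_strand_arithmetic():
    genome = _genome_1000()
    sw = splice_windows(SpliceJunction("chr1", 200, 300, "+"), genome, window=40)
    assert sw.w5 == genome["chr1"][180:220]
    assert sw.w3 == genome["chr1"][280:320]
    assert sw.motif5 == (20, 22)
    assert sw.motif3 == (18, 20)


def test_splice_windows_minimal_window():
    genome = _genome_1000()
    sw = splice_windows(SpliceJunction("chr1", 200, 300, "+"), genome, window=4)
    assert sw.w5 == genome["chr1"][198:202]
    assert sw.motif5 == (2, 4)
    assert sw.motif3 == (0, 2)


def test_splice_windows_minus_strand_mirrors_plus():
    genome = _genome_1000()
    sw_minus = splice_windows(SpliceJunction("chr1", 200, 300, "-"), genome, 40)
    assert sw_minus.w5 == revcomp(genome["chr1"][280:320])
    assert sw_minus.w3 == revcomp(genome["chr1"][180:220])
    assert sw_minus.motif5 == (20, 22)
    assert sw_minus.motif3 == (18, 20)


def test_splice_windows_truncation_warns():
    genome = _genome_1000()
    with pytest.warns(UserWarning, match="truncated"):
        sw = splice_windows(SpliceJunction("chr1", 10, 300, "+"), genome, 40)
    assert sw.w5 == genome["chr1"][0:30]
    assert sw.motif5 == (10, 12)


# ---------------------------------------------------------------------------
# k-mer search

def test_no_shared_kmer_gives_zero():
    w5 = "A" * 40
    w3 = "C" * 40
    ann = max_direct_repeat(w5, w3, (20, 22), (18, 20))
    assert ann.repeat_length == 0 and not ann.overlaps_motifs


def test_planted_eight_mer_found():
    rng = np.random.default_rng(11)
    for _ in range(20):
        w5, w3, m5, m3 = random_window_pair(rng, shared="ACCTCAGT")
        if brute_force_max_repeat(w5, w3, m5, m3) != 8:
            continue  # chance longer repeat; only the clean plant is asserted
        ann = max_direct_repeat(w5, w3, m5, m3)
        assert ann.repeat_length == 8
        assert ann.kmer == "ACCTCAGT"
        assert w5[ann.pos5 : ann.pos5 + 8] == ann.kmer
        assert w3[ann.pos3 : ann.pos3 + 8] == ann.kmer


def test_kmer_must_overlap_both_motifs():
    # shared 6-mer far from the motifs on the 3' side does not qualify
    w5 = "T" * 14 + "GGGGCC" + "T" * 20
    w3 = "GGGGCC" + "A" * 34
    m5, m3 = (20, 22), (18, 20)
    assert w5[14:20] == "GGGGCC" and w3[0:6] == "GGGGCC"
    ann = max_direct_repeat(w5, w3, m5, m3, RepeatSearchParams(k_min=4, k_max=6))
    assert ann.repeat_length == 0


def test_oracle_equivalence_random_windows():
    rng = np.random.default_rng(42)
    params = RepeatSearchParams()
    for i in range(300):
        shared = None
        if i % 3 == 0:  # mix in planted repeats so non-zero lengths occur
            k = int(rng.integers(4, 17))
            shared = "".join(np.array(list("ACGT"))[rng.integers(0, 4, k)])
        w5, w3, m5, m3 = random_window_pair(rng, shared=shared)
        expected = brute_force_max_repeat(w5, w3, m5, m3)
        assert max_direct_repeat(w5, w3, m5, m3, params).repeat_length == expected


def _qualifying_pairs(w5, w3, m5, m3, k):
    """All (i5, i3) occurrence pairs of a shared k-mer overlapping both
    motifs, with their per-side motif overlap widths."""
    pairs = []
    for i5 in range(len(w5) - k + 1):
        ov5 = min(i5 + k, m5[1]) - max(i5, m5[0])
        if ov5 < 1:
            continue
        for i3 in range(len(w3) - k + 1):
            ov3 = min(i3 + k, m3[1]) - max(i3, m3[0])
            if ov3 < 1 or w5[i5 : i5 + k] != w3[i3 : i3 + k]:
                continue
            pairs.append((i5, i3, ov5, ov3))
    return pairs


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_conditional_substring_closure(seed):
    """Trimming one base off a qualifying k-mer keeps it qualifying
    whenever some occurrence pair overlaps each motif by >= 2 nt
    (removing an end base shrinks each motif overlap by at most 1).
    Closure does NOT hold unconditionally: a k-mer touching the donor
    motif only with its first base and the acceptor motif only with its
    last base has no qualifying (k-1)-substring."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(5, 17))
    shared = "".join(np.array(list("ACGT"))[rng.integers(0, 4, k)])
    w5, w3, m5, m3 = random_window_pair(rng, shared=shared)
    best = brute_force_max_repeat(w5, w3, m5, m3, k_min=2)
    for kk in range(best, 2, -1):
        if any(
            ov5 >= 2 and ov3 >= 2
            for _, _, ov5, ov3 in _qualifying_pairs(w5, w3, m5, m3, kk)
        ):
            assert brute_force_max_repeat(w5, w3, m5, m3, k_min=kk - 1, k_max=kk - 1) > 0


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_strand_invariance(seed):
    """A junction and its reverse-complement mirror give equal repeat
    lengths."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    genome = {"chr1": seq}
    mirror = {"chr1": revcomp(seq)}
    j = SpliceJunction("chr1", 150, 280, "+")
    jm = SpliceJunction("chr1", 400 - 280, 400 - 150, "-")
    a = repeat_for_junction(j, genome)
    b = repeat_for_junction(jm, mirror)
    assert a.repeat_length == b.repeat_length
    assert a.kmer == b.kmer


# ---------------------------------------------------------------------------
# annotation of interval sets

def test_annotate_repeats_empty():
    annotations, summary = annotate_repeats([], {"chr1": "A" * 100})
    assert annotations == []
    assert summary["fraction_repeat_ge4"] is None
    assert summary["median_repeat_length"] is None


def test_annotate_repeats_planted_mixture():
    """Loci planted with repeat lengths {4,4,6,8,12} plus 5 repeat-free
    loci: fraction 5/10, lower-median 6."""
    cfg = SimConfig(
        n_genes=10,
        n_falsitron_loci=10,
        repeat_lengths=(4, 4, 6, 8, 12, 0, 0, 0, 0, 0),
        seed=5,
    )
    sim = simulate_genome(cfg)
    annotations, summary = annotate_repeats(
        [t.junction for t in sim.truths], sim.genome
    )
    assert [a.repeat_length for a in annotations[:5]] == [4, 4, 6, 8, 12]
    assert all(a.repeat_length == 0 for a in annotations[5:])
    assert summary["fraction_repeat_ge4"] == pytest.approx(0.5)
    assert summary["median_repeat_length"] == 6


def test_planted_repeats_recovered_exactly(sim):
    annotations, _ = annotate_repeats([t.junction for t in sim.truths], sim.genome)
    for t, a in zip(sim.truths, annotations):
        assert a.repeat_length == t.repeat_length
        assert a.kmer == t.repeat_seq


def test_canonical_introns_rarely_repeat_flanked(sim):
    """Annotated canonical introns of the synthetic genes carry >=4-nt
    motif-overlapping repeats far less often than planted artifact loci
    (all of which carry them)."""
    introns = [j for m in sim.models for j in m.introns()]
    _, intron_summary = annotate_repeats(introns, sim.genome)
    _, locus_summary = annotate_repeats([t.junction for t in sim.truths], sim.genome)
    assert locus_summary["fraction_repeat_ge4"] == 1.0
    assert intron_summary["fraction_repeat_ge4"] < 0.5


def test_k_min_three_variant():
    cfg = SimConfig(n_genes=1, n_falsitron_loci=1, repeat_lengths=(3,), seed=9)
    sim = simulate_genome(cfg)
    j = sim.truths[0].junction
    assert repeat_for_junction(j, sim.genome).repeat_length == 0
    found = repeat_for_junction(j, sim.genome, RepeatSearchParams(k_min=3))
    assert found.repeat_length == 3
    assert found.kmer == sim.truths[0].repeat_seq
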
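"""Format I/O: coordinate conversions, round trips, error reporting."""
import pytest

from falsitron import (
    AlignedRead,
    FalsitronCandidate,
    GenomeInterval,
    RepeatAnnotation,
    SpliceJunction,
    TranscriptModel,
)
from falsitron import genome_io


# ---------------------------------------------------------------------------
# FASTA

def test_read_genome_empty_file(tmp_path):
    path = tmp_path / "empty.fa"
    path.write_text("")
    assert genome_io.read_genome(str(path)) == {}


def test_read_genome_single_record(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">c1\nacgt\n")
    genome = genome_io.read_genome(str(path))
    assert genome == {"c1": "ACGT"}


def test_genome_round_trip(tmp_path, sim):
    path = tmp_path / "genome.fa"
    genome_io.write_genome(sim.genome, str(path))
    assert genome_io.read_genome(str(path)) == sim.genome


def test_read_genome_duplicate_id(tmp_path):
    path = tmp_path / "dup.fa"
    path.write_text(">c1\nACGT\n>c1\nTTTT\n")
    with pytest.raises(ValueError, match="duplicate"):
        genome_io.read_genome(str(path))


def test_read_genome_malformed_names_line(tmp_path):
    path = tmp_path / "bad.fa"
    path.write_text("ACGT\n>c1\nACGT\n")
    with pytest.raises(ValueError, match="line 1"):
        genome_io.read_genome(str(path))


# ---------------------------------------------------------------------------
# GFF3 / GTF

TOY_GTF = (
    'chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\ttoy\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


def test_read_annotation_empty_file(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("")
    assert genome_io.read_annotation(str(path)) == []


def test_read_annotation_gtf_coordinate_conversion(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    models = genome_io.read_annotation(str(path), source_label="dRNA")
    assert len(models) == 1
    m = models[0]
    assert m.transcript_id == "t1" and m.gene_id == "g1"
    assert [(e.start, e.end) for e in m.exons] == [(100, 200), (300, 400), (500, 600)]
    assert [(j.start, j.end) for j in m.introns()] == [(200, 300), (400, 500)]
    assert m.source_label == "dRNA"


def test_annotation_round_trip(tmp_path, sim):
    path = tmp_path / "models.gff3"
    genome_io.write_annotation(sim.models, str(path))
    models = genome_io.read_annotation(str(path))
    by_id = {m.transcript_id: m for m in models}
    assert set(by_id) == {m.transcript_id for m in sim.models}
    for orig in sim.models:
        got = by_id[orig.transcript_id]
        assert got.exons == orig.exons
        assert got.strand == orig.strand
        assert got.gene_id == orig.gene_id


def test_read_annotation_exon_without_transcript(tmp_path):
    path = tmp_path / "orphan.gff3"
    path.write_text("##gff-version 3\nchr1\ttoy\texon\t101\t200\t.\t+\t.\tID=e1\n")
    with pytest.raises(ValueError, match="transcript_id nor Parent"):
        genome_io.read_annotation(str(path))


# ---------------------------------------------------------------------------
# Region strings

PRINTED_REGIONS = [
    ("chr5:126625543-126625746:+", ("chr5", 126625542, 126625746, "+")),
    ("chr11:60842626-60842700:+", ("chr11", 60842625, 60842700, "+")),
    ("chr12:49351611-49353978:+", ("chr12", 49351610, 49353978, "+")),
    ("chr12:100626865-100627488:+", ("chr12", 100626864, 100627488, "+")),
    ("chr17:47118517-47118594:−", ("chr17", 47118516, 47118594, "-")),
    ("chr22:37807089-37807354:+", ("chr22", 37807088, 37807354, "+")),
]


@pytest.mark.parametrize("text,expected", PRINTED_REGIONS)
def test_parse_region_string_printed_coordinates(text, expected):
    iv = genome_io.parse_region_string(text)
    assert (iv.chrom, iv.start, iv.end, iv.strand) == expected
    # format-back reproduces the printed string (ASCII minus)
    assert genome_io.format_region_string(iv) == text.replace("−", "-")


def test_parse_region_string_minimal_interval():
    iv = genome_io.parse_region_string("c1:1-1:+")
    assert (iv.start, iv.end, iv.length) == (0, 1, 1)


@pytest.mark.parametrize("bad", ["chr1:100-50:+", "chr1:100", "chr1:0-5:+", "100-200:+"])
def test_parse_region_string_rejects(bad):
    with pytest.raises(ValueError):
        genome_io.parse_region_string(bad)


# ---------------------------------------------------------------------------
# SAM

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"


def test_read_alignments_unmapped_only(tmp_path):
    path = tmp_path / "unmapped.sam"
    path.write_text(SAM_HEADER + "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
    assert genome_io.read_alignments(str(path)) == []


def test_read_alignments_cigar_blocks(tmp_path):
    path = tmp_path / "split.sam"
    path.write_text(
        SAM_HEADER + "r1\t0\tchr1\t101\t60\t50M200N50M\t*\t0\t0\t*\t*\n"
    )
    reads = genome_io.read_alignments(str(path))
    assert len(reads) == 1
    r = reads[0]
    assert (r.start, r.end) == (100, 400)
    assert r.skips == ((150, 350),)
    assert r.blocks == ((100, 150), (350, 400))


def test_read_alignments_excludes_secondary_by_default(tmp_path):
    path = tmp_path / "sec.sam"
    path.write_text(
        SAM_HEADER
        + "r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\t*\t*\n"
        + "r1\t256\tchr1\t201\t60\t10M\t*\t0\t0\t*\t*\n"
    )
    assert len(genome_io.read_alignments(str(path))) == 1
    assert len(genome_io.read_alignments(str(path), include_secondary=True)) == 2


def test_alignment_round_trip(tmp_path, sim, cdna_reads):
    path = tmp_path / "reads.sam"
    lengths = {name: len(seq) for name, seq in sim.genome.items()}
    genome_io.write_alignments(cdna_reads[:200], lengths, str(path))
    back = genome_io.read_alignments(str(path))
    assert [(r.name, r.chrom, r.strand, r.blocks) for r in back] == [
        (r.name, r.chrom, r.strand, r.blocks) for r in cdna_reads[:200]
    ]


def test_read_alignments_no_zero_length_skip(cdna_reads):
    for r in cdna_reads:
        for s, e in r.skips:
            assert e - s >= 1


# ---------------------------------------------------------------------------
# Candidate tables

def _candidate():
    return FalsitronCandidate(
        junction=SpliceJunction("chr1", 150, 350, "+"),
        filter_path="1a",
        host_transcript_id="t1",
        cdna_split_support=12,
        drna_coverage=40,
        donor_dinucleotide="CA",
        acceptor_dinucleotide="GG",
        repeat=RepeatAnnotation(8, "ACCTCAGT", 16, 14, True),
        relative_abundance=0.3,
    )


def test_write_candidates_empty(tmp_path):
    path = tmp_path / "empty.tsv"
    genome_io.write_candidates([], str(path))
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1
    assert lines[0].split("\t") == genome_io.CANDIDATE_COLUMNS


def test_write_candidates_round_trip(tmp_path):
    path = tmp_path / "cand.tsv"
    genome_io.write_candidates([_candidate()], str(path))
    assert len(path.read_text().strip().splitlines()) == 2
    df = genome_io.read_candidates(str(path))
    row = df.iloc[0]
    assert (row["chrom"], row["start"], row["end"], row["strand"]) == ("chr1", 150, 350, "+")
    assert row["filter_path"] == "1a"
    assert row["cdna_split_support"] == 12 and row["drna_coverage"] == 40
    assert (row["donor_dinucleotide"], row["acceptor_dinucleotide"]) == ("CA", "GG")
    assert row["repeat_length"] == 8 and row["repeat_kmer"] == "ACCTCAGT"
    # abundance carries at least 4 significant digits in the file
    assert "\t0.300000" in path.read_text()
    assert float(row["relative_abundance"]) == pytest.approx(0.3)


def test_bed_reader(tmp_path):
    path = tmp_path / "in.bed"
    path.write_text("# comment\nchr1\t100\t200\tx\t0\t-\nchr2\t5\t10\n")
    ivs = genome_io.read_bed(str(path))
    assert ivs == [
        GenomeInterval("chr1", 100, 200, "-"),
        GenomeInterval("chr2", 5, 10, "."),
    ]
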
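"""Readers and writers for the standard formats the pipeline touches.

This is the only module that knows about file coordinate conventions:
FASTA sequences are returned as plain uppercase strings, GFF3/GTF and
printed region strings (1-based inclusive) are converted to the internal
0-based half-open convention, and candidate/junction tables are emitted
BED-style (0-based half-open).
"""
from __future__ import annotations

import os
import re
from typing import Dict, Iterable, List, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AlignedRead, GenomeInterval, SpliceJunction, TranscriptModel

CANDIDATE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "filter_path",
    "cdna_split_support",
    "drna_coverage",
    "donor_dinucleotide",
    "acceptor_dinucleotide",
    "repeat_length",
    "repeat_kmer",
    "relative_abundance",
]

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "split", "overlapping", "dataset"]


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str) -> Dict[str, str]:
    """Read a FASTA file into ``{sequence_id: uppercase sequence}``.

    Raises ``ValueError`` for sequence data before the first header
    (naming the offending line) and for duplicate record ids.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} precedes any header: "
                    f"{stripped[:40]!r}"
                )
            break
    genome: Dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in genome:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    return genome


def write_genome(genome: Dict[str, str], path: str) -> str:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")
    return path


# ---------------------------------------------------------------------------
# GFF3 / GTF

def _transcript_id_of(feature, dialect: str) -> Optional[str]:
    attrs = feature.attributes
    if "transcript_id" in attrs:
        return attrs["transcript_id"][0]
    if "Parent" in attrs:
        return attrs["Parent"][0]
    return None


def read_annotation(
    path: str,
    source_label: Optional[str] = None,
    annotation_format: str = "auto",
) -> List[TranscriptModel]:
    """Read transcript models from a GFF3 or GTF file.

    Exons are grouped by ``transcript_id`` (GTF) or ``Parent`` (GFF3) and
    sorted; file coordinates (1-based inclusive) become 0-based half-open.
    """
    if os.path.getsize(path) == 0:
        return []
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: Dict[str, list] = {}
    meta: Dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = _transcript_id_of(exon, annotation_format)
        if tid is None:
            raise ValueError(
                f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} has neither "
                "transcript_id nor Parent attribute"
            )
        if exon.start > exon.end or exon.start < 1:
            raise ValueError(
                f"{path}: exon with invalid coordinates "
                f"{exon.seqid}:{exon.start}-{exon.end} (transcript {tid})"
            )
        grouped.setdefault(tid, []).append(
            GenomeInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
        if tid not in meta:
            gene = None
            if "gene_id" in exon.attributes:
                gene = exon.attributes["gene_id"][0]
            meta[tid] = {"gene_id": gene, "strand": exon.strand, "chrom": exon.seqid}
    # fall back to the transcript feature's Parent for the gene id
    for tid, info in meta.items():
        if info["gene_id"] is None:
            try:
                parent_feature = db[tid]
                parents = parent_feature.attributes.get("Parent", [])
                info["gene_id"] = parents[0] if parents else tid
            except gffutils.FeatureNotFoundError:
                info["gene_id"] = tid
    models = []
    for tid in sorted(grouped):
        exons = tuple(sorted(grouped[tid], key=lambda e: e.start))
        info = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons,
                source_label=source_label,
            )
        )
    return models


def write_annotation(models: Iterable[TranscriptModel], path: str) -> str:
    """Write transcript models as GFF3 (gene/mRNA/exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\tfalsitron\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tfalsitron\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, exon in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chrom}\tfalsitron\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id}.exon{i};"
                    f"Parent={m.transcript_id};gene_id={m.gene_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# Region strings

_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+.\-−])$")


def parse_region_string(text: str) -> GenomeInterval:
    """Parse ``chrom:start-end:strand`` (printed 1-based inclusive) into an
    internal interval. The Unicode minus sign is accepted for ``-``."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {text!r}")
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 < 1 or start1 > end1:
        raise ValueError(f"region string {text!r}: require 1 <= start <= end")
    strand = m.group("strand").replace("−", "-")
    return GenomeInterval(m.group("chrom"), start1 - 1, end1, strand)


def format_region_string(interval: GenomeInterval) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive output)."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}:{interval.strand}"


# ---------------------------------------------------------------------------
# SAM / BAM

def read_alignments(
    path: str,
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> List[AlignedRead]:
    """Read spliced alignments from SAM/BAM into :class:`AlignedRead`.

    Unmapped records are skipped; secondary and supplementary alignments
    are excluded by default, since artifact junctions must come from
    primary read placements.
    """
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for i, rec in enumerate(af):
            if rec.is_unmapped:
                continue
            if rec.is_secondary and not include_secondary:
                continue
            if rec.is_supplementary and not include_supplementary:
                continue
            blocks = _reference_blocks(rec, i)
            reads.append(
                AlignedRead(
                    name=rec.query_name,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    blocks=blocks,
                    sequence=rec.query_sequence,
                )
            )
    return reads


_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_SKIP = 3  # N


def _reference_blocks(rec, index: int):
    if rec.cigartuples is None:
        raise ValueError(f"record {index} ({rec.query_name}): missing CIGAR")
    pos = rec.reference_start
    blocks = []
    block_start = pos
    for op, length in rec.cigartuples:
        if op in _REF_CONSUMING:
            pos += length
        elif op == _SKIP:
            if length < 1:
                raise ValueError(
                    f"record {index} ({rec.query_name}): zero-length N operation"
                )
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
    if pos > block_start:
        blocks.append((block_start, pos))
    if not blocks:
        raise ValueError(f"record {index} ({rec.query_name}): no aligned bases")
    return tuple(blocks)


def write_alignments(
    reads: Iterable[AlignedRead],
    reference_lengths: Dict[str, int],
    path: str,
) -> str:
    """Write :class:`AlignedRead` objects as a SAM file with proper header.

    The CIGAR is reconstructed from the aligned blocks (M segments joined
    by N skips); the stored read sequence is emitted when available.
    """
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.name
            seg.flag = 16 if read.strand == "-" else 0
            seg.reference_id = tid[read.chrom]
            seg.reference_start = read.start
            seg.mapping_quality = 60
            cigar = []
            prev_end = None
            for s, e in read.blocks:
                if prev_end is not None:
                    cigar.append((_SKIP, s - prev_end))
                cigar.append((0, e - s))
                prev_end = e
            seg.cigartuples = cigar
            if read.sequence is not None:
                seg.query_sequence = read.sequence
            out.write(seg)
    return path


# ---------------------------------------------------------------------------
# Tables

def write_candidates(candidates: Iterable, path: str) -> str:
    """Write falsitron candidates as a BED-style TSV (header row, 0-based
    half-open coordinates). Relative abundance is formatted with six
    decimal places; missing abundance is emitted as ``NA``."""
    rows = []
    for c in candidates:
        j = c.junction
        rep = c.repeat
        rows.append(
            {
                "chrom": j.chrom,
                "start": j.start,
                "end": j.end,
                "strand": j.strand,
                "filter_path": c.filter_path,
                "cdna_split_support": c.cdna_split_support,
                "drna_coverage": c.drna_coverage,
                "donor_dinucleotide": c.donor_dinucleotide,
                "acceptor_dinucleotide": c.acceptor_dinucleotide,
                "repeat_length": rep.repeat_length if rep is not None else 0,
                "repeat_kmer": rep.kmer if rep is not None else "",
                "relative_abundance": (
                    "NA" if c.relative_abundance is None else f"{c.relative_abundance:.6f}"
                ),
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_candidates(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"repeat_kmer": str}, keep_default_na=False
    )


def write_junction_table(supports: Iterable, path: str) -> str:
    rows = [
        {
            "chrom": s.junction.chrom,
            "start": s.junction.start,
            "end": s.junction.end,
            "strand": s.junction.strand,
            "split": s.split_read_count,
            "overlapping": s.overlapping_read_count,
            "dataset": s.dataset or "",
        }
        for s in supports
    ]
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_junction_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def read_bed(path: str) -> List[GenomeInterval]:
    """Read a BED-style interval list (chrom, start, end[, name, score,
    strand]); 0-based half-open as BED prescribes."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(
                GenomeInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return intervals
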
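"""The falsitron filter cascade.

A falsitron is an apparent excision event (a splice-like junction)
supported by split reads only in reverse-transcription-based protocols
(cDNA/dcDNA) while the same locus is well covered — but never spliced —
in direct RNA sequencing. The cascade nominates candidates from paired
cDNA-type and dRNA-type evidence:

(i)   split-read support in the cDNA-type data >= ``min_coverage``;
(ii)  the junction is absent from the dRNA junction set;
(iii) dRNA read coverage over the junction interval >= ``min_coverage``
      (so absence is informative, not a dropout);
(iv)  the junction lies fully inside one dRNA exon (filter path ``1a``)
      or its ends fall in two adjacent dRNA exons (``1b``);
(v)   the junction's terminal dinucleotides are not a canonical
      donor–acceptor pair (default GT–AG), since a real unannotated
      intron would carry splice-site signals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .intervals import AlignedRead, SpliceJunction, TranscriptModel, revcomp
from .junctions import JunctionSupport, extract_junctions, region_coverage
from .repeats import RepeatAnnotation

logger = logging.getLogger(__name__)

CANONICAL_GT_AG: FrozenSet[Tuple[str, str]] = frozenset({("GT", "AG")})
CANONICAL_GT_GC_AG: FrozenSet[Tuple[str, str]] = frozenset(
    {("GT", "AG"), ("GC", "AG")}
)


@dataclass(frozen=True)
class DetectorParams:
    """Thresholds of the filter cascade.

    ``canonical_pairs`` holds the donor–acceptor dinucleotide pairs
    excluded as canonical; the minor GC donor can be added with
    :data:`CANONICAL_GT_GC_AG`. ``drna_absence_slack`` > 0 enables a
    fuzzy absence test (the junction counts as present in dRNA if a dRNA
    junction lies within that many nt on both ends); off by default.
    """

    min_coverage: int = 5
    canonical_pairs: FrozenSet[Tuple[str, str]] = CANONICAL_GT_AG
    require_absent_in_drna: bool = True
    drna_absence_slack: int = 0

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not self.canonical_pairs:
            raise ValueError("canonical_pairs must be non-empty")
        if self.drna_absence_slack < 0:
            raise ValueError("drna_absence_slack must be >= 0")


@dataclass
class FalsitronCandidate:
    """A junction that survived the cascade, with all its evidence."""

    junction: SpliceJunction
    filter_path: str
    host_transcript_id: str
    cdna_split_support: int
    drna_coverage: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    repeat: Optional[RepeatAnnotation] = None
    relative_abundance: Optional[float] = None


def contained_in_exon(
    j: SpliceJunction, models: Sequence[TranscriptModel]
) -> Optional[str]:
    """Filter 1a: transcript id of the first model with an exon fully
    containing ``j`` (boundary-inclusive), else None."""
    for m in models:
        if m.chrom != j.chrom or not j.strand_compatible(m.strand):
            continue
        for exon in m.exons:
            if exon.start <= j.start and j.end <= exon.end:
                return m.transcript_id
    return None


def spans_adjacent_exons(
    j: SpliceJunction, models: Sequence[TranscriptModel]
) -> Optional[str]:
    """Filter 1b: transcript id of the first model with consecutive exons
    E_i, E_{i+1} such that j.start lies in E_i and j.end in E_{i+1}."""
    for m in models:
        if m.chrom != j.chrom or not j.strand_compatible(m.strand):
            continue
        for a, b in zip(m.exons, m.exons[1:]):
            if a.start <= j.start < a.end and b.start < j.end <= b.end:
                return m.transcript_id
    return None


def splice_site_dinucleotides(
    j: SpliceJunction, genome: Dict[str, str]
) -> Tuple[str, str]:
    """First and last intronic dinucleotides of ``j`` in transcript
    orientation (GT/AG for a canonical intron)."""
    if j.strand not in ("+", "-"):
        raise ValueError(
            f"junction {j.chrom}:{j.start}-{j.end} is unstranded; resolve the "
            "strand from the host transcript before extracting splice sites"
        )
    if j.chrom not in genome:
        raise KeyError(f"chromosome {j.chrom!r} absent from genome")
    seq = genome[j.chrom]
    if j.start < 0 or j.end > len(seq) or j.start + 2 > len(seq) or j.end - 2 < 0:
        raise ValueError(
            f"junction {j.chrom}:{j.start}-{j.end} too close to sequence edge"
        )
    if j.strand == "+":
        return seq[j.start : j.start + 2], seq[j.end - 2 : j.end]
    return revcomp(seq[j.end - 2 : j.end]), revcomp(seq[j.start : j.start + 2])


def _present_in_drna(
    j: SpliceJunction, drna_junctions: Sequence[SpliceJunction], slack: int
) -> bool:
    if slack == 0:
        return any(j.matches(d) for d in drna_junctions)
    return any(
        d.chrom == j.chrom
        and abs(d.start - j.start) <= slack
        and abs(d.end - j.end) <= slack
        and j.strand_compatible(d.strand)
        for d in drna_junctions
    )


def detect_falsitrons(
    cdna_junctions: Sequence[JunctionSupport],
    cdna_reads: Optional[Sequence[AlignedRead]],
    drna_reads: Sequence[AlignedRead],
    drna_models: Sequence[TranscriptModel],
    genome: Dict[str, str],
    params: Optional[DetectorParams] = None,
) -> List[FalsitronCandidate]:
    """Run the filter cascade and return candidates sorted by coordinate.

    ``cdna_junctions`` should come from :func:`~falsitron.junctions.
    extract_junctions` on the cDNA-type alignments (``cdna_reads`` is
    accepted for recomputing overlap denominators but is not otherwise
    required). Relative abundance (split / overlapping) is filled from
    the junction table. Raises ``KeyError`` naming the chromosome if a
    surviving junction's chromosome is missing from the genome.
    """
    params = params or DetectorParams()
    drna_junction_list = [s.junction for s in extract_junctions(drna_reads)]
    model_by_id = {m.transcript_id: m for m in drna_models}

    n_support = n_absent = n_cov = n_host = 0
    candidates: List[FalsitronCandidate] = []
    for sup in sorted(cdna_junctions, key=lambda s: s.junction):
        j = sup.junction
        if sup.split_read_count < params.min_coverage:
            continue
        n_support += 1
        if params.require_absent_in_drna and _present_in_drna(
            j, drna_junction_list, params.drna_absence_slack
        ):
            continue
        n_absent += 1
        drna_cov = region_coverage(drna_reads, j.interval())
        if drna_cov < params.min_coverage:
            continue
        n_cov += 1
        host = contained_in_exon(j, drna_models)
        path = "1a"
        if host is None:
            host = spans_adjacent_exons(j, drna_models)
            path = "1b"
        if host is None:
            continue
        n_host += 1
        strand = j.strand if j.strand in ("+", "-") else model_by_id[host].strand
        stranded_j = SpliceJunction(j.chrom, j.start, j.end, strand)
        if j.chrom not in genome:
            raise KeyError(f"chromosome {j.chrom!r} absent from genome")
        donor, acceptor = splice_site_dinucleotides(stranded_j, genome)
        if (donor, acceptor) in params.canonical_pairs:
            continue
        abundance = (
            sup.split_read_count / sup.overlapping_read_count
            if sup.overlapping_read_count > 0
            else None
        )
        candidates.append(
            FalsitronCandidate(
                junction=stranded_j,
                filter_path=path,
                host_transcript_id=host,
                cdna_split_support=sup.split_read_count,
                drna_coverage=drna_cov,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                relative_abundance=abundance,
            )
        )
    logger.info(
        "falsitron cascade: %d junctions in, %d with split support >= %d, "
        "%d absent from dRNA, %d with dRNA coverage >= %d, %d in host exons, "
        "%d non-canonical candidates out",
        len(cdna_junctions),
        n_support,
        params.min_coverage,
        n_absent,
        n_cov,
        params.min_coverage,
        n_host,
        len(candidates),
    )
    return candidates
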
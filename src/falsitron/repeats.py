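"""Direct-repeat search at splice-site windows.

RT slippage is mediated by two identical sequence copies (direct
repeats) flanking the spuriously "excised" region. For each junction we
take a window around each splice-site boundary (default 40 nt, 20 nt on
each side) and look for the longest k-mer (default k in 4..20) that
occurs in both windows, requiring each occurrence to overlap at least
1 nt of its window's splice-site dinucleotide motif — the first two and
last two intronic bases. Windows on minus-strand junctions are
reverse-complemented so the search always runs in transcript
orientation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from statistics import median_low
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .intervals import GenomeInterval, SpliceJunction, revcomp


@dataclass(frozen=True)
class RepeatSearchParams:
    """k-mer range and window width. ``k_min=3`` is a supported variant
    for cataloguing shorter repeats."""

    k_min: int = 4
    k_max: int = 20
    window: int = 40

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max <= self.window):
            raise ValueError("require 1 <= k_min <= k_max <= window")
        if self.window % 2 != 0 or self.window < 4:
            raise ValueError("window must be an even number >= 4")


@dataclass(frozen=True)
class RepeatAnnotation:
    """Longest motif-overlapping k-mer shared by the two windows.

    ``repeat_length`` is 0 when no qualifying k-mer exists; ``pos5`` and
    ``pos3`` are offsets of the chosen occurrences within their windows.
    """

    repeat_length: int
    kmer: str
    pos5: int
    pos3: int
    overlaps_motifs: bool


NO_REPEAT = RepeatAnnotation(0, "", -1, -1, False)


@dataclass(frozen=True)
class SpliceWindows:
    """Window sequences (transcript orientation) with the offsets of the
    splice-site dinucleotide motifs inside each."""

    w5: str
    w3: str
    motif5: Tuple[int, int]
    motif3: Tuple[int, int]


def splice_windows(
    j: SpliceJunction, genome: Dict[str, str], window: int = 40
) -> SpliceWindows:
    """Windows of ``window`` nt centred on the two splice-site boundaries
    of ``j`` (half exonic, half intronic), read 5'→3' in transcript
    orientation. Windows hitting a contig edge are truncated with a
    warning and the motif offsets adjusted."""
    if j.strand not in ("+", "-"):
        raise ValueError("splice_windows requires a resolved strand")
    if j.chrom not in genome:
        raise KeyError(f"chromosome {j.chrom!r} absent from genome")
    seq = genome[j.chrom]
    half = window // 2
    if j.strand == "+":
        five_b, three_b = j.start, j.end
    else:
        five_b, three_b = j.end, j.start

    def cut(boundary: int) -> Tuple[str, int, int]:
        a, b = max(0, boundary - half), min(len(seq), boundary + half)
        if b - a < window:
            warnings.warn(
                f"window at {j.chrom}:{boundary} truncated to {b - a} nt "
                "(contig edge)",
                stacklevel=3,
            )
        return seq[a:b], a, b

    s5, a5, b5 = cut(five_b)
    s3, a3, b3 = cut(three_b)
    if j.strand == "+":
        w5, m5 = s5, (j.start - a5, j.start - a5 + 2)
        w3, m3 = s3, (j.end - 2 - a3, j.end - a3)
    else:
        w5, m5 = revcomp(s5), (b5 - j.end, b5 - j.end + 2)
        w3, m3 = revcomp(s3), (b3 - j.start - 2, b3 - j.start)
    for (ms, me), w, name in ((m5, w5, "5'"), (m3, w3, "3'")):
        if ms < 0 or me > len(w):
            raise ValueError(
                f"{name} splice-site motif of {j.chrom}:{j.start}-{j.end} "
                "falls outside the sequence"
            )
    return SpliceWindows(w5=w5, w3=w3, motif5=m5, motif3=m3)


def max_direct_repeat(
    w5: str,
    w3: str,
    motif5: Tuple[int, int],
    motif3: Tuple[int, int],
    params: Optional[RepeatSearchParams] = None,
) -> RepeatAnnotation:
    """Largest k in ``[k_min, k_max]`` with a k-mer occurring in ``w5``
    overlapping >= 1 nt of ``motif5`` and in ``w3`` overlapping >= 1 nt of
    ``motif3``. Ties among equal-k occurrences break by smallest combined
    offset distance to the motif starts, then lexicographic k-mer, then
    positions."""
    params = params or RepeatSearchParams()
    m5s, m5e = motif5
    m3s, m3e = motif3
    for k in range(min(params.k_max, len(w5), len(w3)), params.k_min - 1, -1):
        occ3: Dict[str, List[int]] = {}
        for i in range(len(w3) - k + 1):
            if i < m3e and i + k > m3s:
                occ3.setdefault(w3[i : i + k], []).append(i)
        best = None
        for i in range(len(w5) - k + 1):
            if not (i < m5e and i + k > m5s):
                continue
            kmer = w5[i : i + k]
            for i3 in occ3.get(kmer, ()):
                cand = (abs(i - m5s) + abs(i3 - m3s), kmer, i, i3)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            _, kmer, i5, i3 = best
            return RepeatAnnotation(k, kmer, i5, i3, True)
    return NO_REPEAT


def repeat_for_junction(
    j: SpliceJunction,
    genome: Dict[str, str],
    params: Optional[RepeatSearchParams] = None,
) -> RepeatAnnotation:
    params = params or RepeatSearchParams()
    sw = splice_windows(j, genome, params.window)
    return max_direct_repeat(sw.w5, sw.w3, sw.motif5, sw.motif3, params)


def _as_junction(item) -> SpliceJunction:
    if isinstance(item, SpliceJunction):
        return item
    if isinstance(item, GenomeInterval):
        return SpliceJunction(item.chrom, item.start, item.end, item.strand)
    return item.junction  # FalsitronCandidate-like


def annotate_repeats(
    items: Sequence,
    genome: Dict[str, str],
    params: Optional[RepeatSearchParams] = None,
) -> Tuple[List[RepeatAnnotation], dict]:
    """Annotate every item (candidate, junction or stranded interval) and
    summarise: fraction of items with repeat_length >= 4 and the
    lower-median repeat length among those. Candidates get their
    ``repeat`` field filled in place."""
    params = params or RepeatSearchParams()
    annotations: List[RepeatAnnotation] = []
    for item in items:
        ann = repeat_for_junction(_as_junction(item), genome, params)
        if hasattr(item, "repeat"):
            item.repeat = ann
        annotations.append(ann)
    with_repeat = [a.repeat_length for a in annotations if a.repeat_length >= 4]
    summary = {
        "n_total": len(annotations),
        "n_repeat_ge4": len(with_repeat),
        "fraction_repeat_ge4": (
            len(with_repeat) / len(annotations) if annotations else None
        ),
        "median_repeat_length": median_low(with_repeat) if with_repeat else None,
    }
    return annotations, summary
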
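"""Position-wise nucleotide composition at 5' and 3' splice sites.

Real introns carry strong positional signals at their boundaries (the
GT donor, the AG acceptor, the polypyrimidine tract); RT-slippage
artifacts do not. For each intron-like interval we take a 15-nt window
at each site — 3 exonic + 12 intronic nt — in transcript orientation,
and tabulate per-position nucleotide counts and frequencies.

Position labels: 5' site -3..-1 (exon), +1..+12 (intron); 3' site
-12..-1 (intron), +1..+3 (exon). There is no position 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, revcomp

EXONIC_NT = 3
INTRONIC_NT = 12
WINDOW_NT = EXONIC_NT + INTRONIC_NT
BASES = ("A", "C", "G", "T")


def position_labels(site: str) -> List[int]:
    if site == "5prime":
        return list(range(-EXONIC_NT, 0)) + list(range(1, INTRONIC_NT + 1))
    if site == "3prime":
        return list(range(-INTRONIC_NT, 0)) + list(range(1, EXONIC_NT + 1))
    raise ValueError(f"unknown site {site!r}")


@dataclass(frozen=True)
class SpliceProfile:
    """Per-position nucleotide counts over a set of site windows.

    ``counts`` and ``frequencies`` are DataFrames indexed by position
    label with columns A/C/G/T; ambiguous bases (N) are excluded from
    each position's denominator rather than dropping whole sequences.
    """

    site: str
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    n_sequences: int


def site_windows(
    intervals: Sequence[GenomeInterval], genome: Dict[str, str]
) -> Tuple[List[str], List[str]]:
    """15-nt windows at the 5' and 3' splice sites of each stranded
    intron-like interval. Intervals shorter than the intronic window or
    running off the contig are dropped with a warning."""
    fives: List[str] = []
    threes: List[str] = []
    for iv in intervals:
        if iv.strand not in ("+", "-"):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} is unstranded"
            )
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        seq = genome[iv.chrom]
        if iv.length < INTRONIC_NT:
            warnings.warn(
                f"dropping interval {iv.chrom}:{iv.start}-{iv.end}: shorter "
                f"than the {INTRONIC_NT}-nt intronic window",
                stacklevel=2,
            )
            continue
        if iv.start - EXONIC_NT < 0 or iv.end + EXONIC_NT > len(seq):
            warnings.warn(
                f"dropping interval {iv.chrom}:{iv.start}-{iv.end}: window "
                "outside sequence bounds",
                stacklevel=2,
            )
            continue
        if iv.strand == "+":
            fives.append(seq[iv.start - EXONIC_NT : iv.start + INTRONIC_NT])
            threes.append(seq[iv.end - INTRONIC_NT : iv.end + EXONIC_NT])
        else:
            fives.append(revcomp(seq[iv.end - INTRONIC_NT : iv.end + EXONIC_NT]))
            threes.append(revcomp(seq[iv.start - EXONIC_NT : iv.start + INTRONIC_NT]))
    return fives, threes


def frequency_matrix(seqs: Sequence[str], site: str = "5prime") -> SpliceProfile:
    """Counts and relative frequencies per position over equal-length
    sequences (alphabet A/C/G/T/N; N excluded position-wise)."""
    if not seqs:
        labels = position_labels(site) if len(position_labels(site)) else []
        empty = pd.DataFrame(0, index=labels, columns=list(BASES))
        return SpliceProfile(site, empty, empty.astype(float), 0)
    length = len(seqs[0])
    for idx, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"sequence {idx} has length {len(s)}, expected {length}"
            )
        bad = set(s.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {idx} has invalid characters {bad}")
    arr = np.array([list(s.upper()) for s in seqs])
    counts = np.zeros((length, 4), dtype=int)
    for bi, base in enumerate(BASES):
        counts[:, bi] = (arr == base).sum(axis=0)
    denom = counts.sum(axis=1, keepdims=True)  # excludes N position-wise
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
    labels = position_labels(site) if length == WINDOW_NT else list(range(length))
    return SpliceProfile(
        site=site,
        counts=pd.DataFrame(counts, index=labels, columns=list(BASES)),
        frequencies=pd.DataFrame(freqs, index=labels, columns=list(BASES)),
        n_sequences=len(seqs),
    )


def splice_profiles(
    intervals: Sequence[GenomeInterval], genome: Dict[str, str]
) -> Dict[str, SpliceProfile]:
    """Profiles for both sites of an interval set."""
    fives, threes = site_windows(intervals, genome)
    return {
        "5prime": frequency_matrix(fives, "5prime"),
        "3prime": frequency_matrix(threes, "3prime"),
    }


def profiles_to_long(profiles: Dict[str, SpliceProfile]) -> pd.DataFrame:
    """Long-format table: site, position, base, count, frequency."""
    rows = []
    for site, prof in profiles.items():
        for pos in prof.counts.index:
            for base in BASES:
                rows.append(
                    {
                        "site": site,
                        "position": pos,
                        "base": base,
                        "count": int(prof.counts.loc[pos, base]),
                        "frequency": float(prof.frequencies.loc[pos, base]),
                    }
                )
    return pd.DataFrame(rows, columns=["site", "position", "base", "count", "frequency"])
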
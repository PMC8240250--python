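"""Synthetic genomes, transcript models and pre-aligned long reads with
planted RT-slippage artifacts.

The generative model mirrors the proposed artifact mechanism: an exonic
segment flanked by two identical direct repeats (optionally enclosing a
hairpin-forming inverted repeat) lets the reverse transcriptase slip
from one repeat copy to the other, deleting one copy plus the
intervening sequence from the cDNA. Per molecule this happens with
probability ``p_slip`` in cDNA-type protocols only; direct RNA reads
are always faithful. Reads are emitted pre-aligned (SAM), so aligner
behaviour is out of the loop and read skips can be compared to the
planted truth exactly.

Junction register: a slippage deletion across direct repeats is
coordinate-ambiguous. Truth intervals and read skips are both emitted at
the register shifted one base into the repeat, so each repeat copy
overlaps its splice-site dinucleotide motif — the placement actually
observed for these artifacts, whose junctions end inside the repeats.
The generator pins this register (and the planted repeat length) by
rejection sampling the locus context.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import AlignedRead, GenomeInterval, SpliceJunction, TranscriptModel, revcomp
from .repeats import RepeatSearchParams, repeat_for_junction
from .detector import splice_site_dinucleotides

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_MODES = ("dRNA", "cDNA", "dcDNA")
_MODE_INDEX = {m: i for i, m in enumerate(_MODES)}

TRUTH_COLUMNS = [
    "locus_id",
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
    "repeat_length",
    "repeat_seq",
    "p_slip",
    "canonical_boundaries",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 10 multi-exon genes, 5 planted artifact loci with repeat
    lengths 4/6/8/12/16 nt, per-molecule slippage probability 0.3 in
    cDNA-type reads, depth 100 per transcript, 2% substitution error.
    ``repeat_lengths`` entries are 0 (no repeat planted) or 3..16.
    """

    n_genes: int = 10
    exons_per_gene: Tuple[int, int] = (4, 6)
    exon_length: Tuple[int, int] = (150, 350)
    intron_length: Tuple[int, int] = (100, 250)
    n_falsitron_loci: int = 5
    repeat_lengths: Tuple[int, ...] = (4, 6, 8, 12, 16)
    falsitron_length: Tuple[int, int] = (150, 600)
    hairpin_stem: Optional[int] = 8
    canonical_boundaries: Optional[Tuple[bool, ...]] = None
    p_slip: float = 0.3
    depth: int = 100
    substitution_error_rate: float = 0.02
    pcr_duplicate_factor: int = 1
    intergenic_gap: int = 300
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_slip <= 1.0):
            raise ValueError("p_slip must be in [0, 1]")
        if self.n_falsitron_loci > self.n_genes:
            raise ValueError("cannot plant more loci than genes")
        if len(self.repeat_lengths) != self.n_falsitron_loci:
            raise ValueError("repeat_lengths must list one value per locus")
        for r in self.repeat_lengths:
            if r != 0 and not (3 <= r <= 16):
                raise ValueError(f"repeat length {r} outside 0 or 3..16")
        if self.canonical_boundaries is not None and len(
            self.canonical_boundaries
        ) != self.n_falsitron_loci:
            raise ValueError("canonical_boundaries must list one flag per locus")
        if self.falsitron_length[0] <= max(self.repeat_lengths, default=0) + 30:
            raise ValueError("falsitron_length minimum too small for the repeats")
        if self.depth < 0 or self.intergenic_gap < 1:
            raise ValueError("depth must be >= 0 and intergenic_gap >= 1")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_length,
            self.intron_length,
            self.falsitron_length,
        ):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < lo <= hi")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """A planted artifact locus: the apparent 'intron' after slippage."""

    locus_id: str
    gene_id: str
    transcript_id: str
    junction: SpliceJunction
    repeat_length: int
    repeat_seq: str
    p_slip: float
    canonical_boundaries: bool


@dataclass
class Simulation:
    config: SimConfig
    genome: Dict[str, str]
    models: List[TranscriptModel]
    truths: List[SimTruth]


# ---------------------------------------------------------------------------
# sequence helpers

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, n)])


def _polypyrimidine(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["C", "T"])[rng.integers(0, 2, n)])


def _intron_seq(rng: np.random.Generator, n: int) -> str:
    """Canonical intron in transcript orientation: GT donor, pyrimidine-
    rich 3' end, AG acceptor."""
    if n < 30:
        raise ValueError("introns shorter than 30 nt are not generated")
    ppt = _polypyrimidine(rng, 14)
    return "GT" + _rand_seq(rng, n - 18) + ppt + "AG"


def _with_char(seq: str, idx: int, char: str) -> str:
    return seq[:idx] + char + seq[idx + 1 :]


def _different_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _segment_seq(
    rng: np.random.Generator, s_len: int, stem: Optional[int]
) -> str:
    """Intervening segment, optionally with a hairpin-forming inverted
    repeat (structural decoration only)."""
    if stem and s_len >= 2 * stem + 9:
        stem_seq = _rand_seq(rng, stem)
        tail = s_len - 3 - 2 * stem - 4
        return (
            _rand_seq(rng, 3)
            + stem_seq
            + _rand_seq(rng, 4)
            + revcomp(stem_seq)
            + _rand_seq(rng, tail)
        )
    return _rand_seq(rng, s_len)


def _build_host_exon(
    rng: np.random.Generator,
    r: int,
    falsitron_len: int,
    stem: Optional[int],
    canonical: bool,
) -> Tuple[str, int, int, str]:
    """Exon sequence hosting one planted locus (transcript orientation).

    Returns (exon_seq, junction_start, junction_end, repeat_seq) with
    junction coordinates local to the exon. The construction is
    rejection-sampled until the planted repeat is exactly what the
    repeat search recovers and the boundary dinucleotides match the
    requested canonical flag.
    """
    s_len = falsitron_len - r
    for _ in range(500):
        lf = _rand_seq(rng, int(rng.integers(25, 60)))
        rf = _rand_seq(rng, int(rng.integers(25, 60)))
        seg = _segment_seq(rng, s_len, stem)
        if r > 0:
            rep = _rand_seq(rng, r)
            if canonical:
                # register-1 donor = repeat[1:3], acceptor = segment[-1] + repeat[0]
                rep = _with_char(rep, 0, "G")
                rep = _with_char(rep, 1, "G")
                rep = _with_char(rep, 2, "T")
                seg = _with_char(seg, len(seg) - 1, "A")
            locus = rep + seg + rep
            j_local = (1, 1 + falsitron_len)
        else:
            rep = ""
            if canonical:
                seg = "GT" + seg[2:-2] + "AG"
            locus = seg
            j_local = (0, falsitron_len)
        # pin the register and the repeat length against the flanks
        lf = _with_char(lf, len(lf) - 1, _different_base(rng, seg[-1]))
        rf = _with_char(rf, 0, _different_base(rng, seg[0]))
        exon = lf + locus + rf
        j0, j1 = len(lf) + j_local[0], len(lf) + j_local[1]
        mini = {"x": exon}
        junction = SpliceJunction("x", j0, j1, "+")
        donor, acceptor = splice_site_dinucleotides(junction, mini)
        if ((donor, acceptor) == ("GT", "AG")) != canonical:
            continue
        found = repeat_for_junction(
            junction, mini, RepeatSearchParams(k_min=4, k_max=20, window=40)
        )
        if r >= 4:
            if found.repeat_length != r or found.kmer != rep:
                continue
        elif r == 3:
            if found.repeat_length != 0:
                continue
            found3 = repeat_for_junction(
                junction, mini, RepeatSearchParams(k_min=3, k_max=20, window=40)
            )
            if found3.repeat_length != 3 or found3.kmer != rep:
                continue
        else:
            if found.repeat_length != 0:
                continue
        return exon, j0, j1, rep
    raise RuntimeError(
        f"could not construct a planted locus with repeat length {r}"
    )


# ---------------------------------------------------------------------------
# genome construction

@dataclass
class _Gene:
    gene_id: str
    transcript_id: str
    strand: str
    local_exons: List[Tuple[int, int]]  # transcript orientation
    sequence: str  # transcript orientation
    locus_local: Optional[Tuple[int, int]] = None  # junction, gene-local
    locus_repeat: str = ""
    locus_index: Optional[int] = None
    canonical: bool = False


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, gene_idx: int
) -> _Gene:
    locus_index = gene_idx if gene_idx < cfg.n_falsitron_loci else None
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    host = n_exons // 2 if locus_index is not None else -1
    strand = "+" if gene_idx % 2 == 0 else "-"

    exon_seqs: List[str] = []
    locus_in_exon = None
    repeat_seq = ""
    canonical = False
    for i in range(n_exons):
        if i == host:
            r = cfg.repeat_lengths[locus_index]
            canonical = bool(
                cfg.canonical_boundaries[locus_index]
                if cfg.canonical_boundaries is not None
                else False
            )
            length = int(
                rng.integers(cfg.falsitron_length[0], cfg.falsitron_length[1] + 1)
            )
            exon, j0, j1, repeat_seq = _build_host_exon(
                rng, r, length, cfg.hairpin_stem, canonical
            )
            exon_seqs.append(exon)
            locus_in_exon = (j0, j1)
        else:
            exon_seqs.append(
                _rand_seq(rng, int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)))
            )
    intron_seqs = [
        _intron_seq(rng, int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)))
        for _ in range(n_exons - 1)
    ]

    parts: List[str] = []
    local_exons: List[Tuple[int, int]] = []
    pos = 0
    locus_local = None
    for i, exon in enumerate(exon_seqs):
        local_exons.append((pos, pos + len(exon)))
        if i == host and locus_in_exon is not None:
            locus_local = (pos + locus_in_exon[0], pos + locus_in_exon[1])
        parts.append(exon)
        pos += len(exon)
        if i < n_exons - 1:
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    gid = f"G{gene_idx + 1}"
    return _Gene(
        gene_id=gid,
        transcript_id=f"{gid}.t1",
        strand=strand,
        local_exons=local_exons,
        sequence="".join(parts),
        locus_local=locus_local,
        locus_repeat=repeat_seq,
        locus_index=locus_index,
        canonical=canonical,
    )


def simulate_genome(config: SimConfig) -> Simulation:
    """Deterministically build the synthetic genome, transcript models
    and planted-locus truth records from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = [_build_gene(rng, config, i) for i in range(config.n_genes)]

    chrom_parts: List[str] = []
    models: List[TranscriptModel] = []
    truths: List[SimTruth] = []
    offset = 0
    for gene in genes:
        gap = _rand_seq(rng, config.intergenic_gap)
        chrom_parts.append(gap)
        offset += len(gap)
        gene_start = offset
        glen = len(gene.sequence)
        genomic_seq = (
            gene.sequence if gene.strand == "+" else revcomp(gene.sequence)
        )
        chrom_parts.append(genomic_seq)
        offset += glen

        def to_genomic(local: Tuple[int, int]) -> Tuple[int, int]:
            a, b = local
            if gene.strand == "+":
                return gene_start + a, gene_start + b
            return gene_start + glen - b, gene_start + glen - a

        exons = sorted(to_genomic(e) for e in gene.local_exons)
        models.append(
            TranscriptModel(
                transcript_id=gene.transcript_id,
                gene_id=gene.gene_id,
                chrom=config.chrom,
                strand=gene.strand,
                exons=tuple(
                    GenomeInterval(config.chrom, a, b, gene.strand) for a, b in exons
                ),
            )
        )
        if gene.locus_local is not None:
            gs, ge = to_genomic(gene.locus_local)
            truths.append(
                SimTruth(
                    locus_id=f"locus{gene.locus_index + 1}",
                    gene_id=gene.gene_id,
                    transcript_id=gene.transcript_id,
                    junction=SpliceJunction(config.chrom, gs, ge, gene.strand),
                    repeat_length=len(gene.locus_repeat),
                    repeat_seq=gene.locus_repeat,
                    p_slip=config.p_slip,
                    canonical_boundaries=gene.canonical,
                )
            )
    chrom_parts.append(_rand_seq(rng, config.intergenic_gap))
    genome = {config.chrom: "".join(chrom_parts)}
    return Simulation(config=config, genome=genome, models=models, truths=truths)


# ---------------------------------------------------------------------------
# read simulation

def _apply_slip(blocks: Sequence[Tuple[int, int]], truth: SimTruth):
    """Split the block containing the truth interval into two, creating
    the artifact N skip."""
    out = []
    for s, e in blocks:
        if s < truth.junction.start and truth.junction.end < e:
            out.append((s, truth.junction.start))
            out.append((truth.junction.end, e))
        else:
            out.append((s, e))
    return tuple(out)


def _read_sequence(
    rng: np.random.Generator,
    genome_seq: str,
    blocks: Sequence[Tuple[int, int]],
    error_rate: float,
) -> str:
    seq = "".join(genome_seq[s:e] for s, e in blocks)
    if error_rate > 0:
        n_err = rng.binomial(len(seq), error_rate)
        if n_err:
            positions = rng.choice(len(seq), size=n_err, replace=False)
            chars = list(seq)
            for p in positions:
                chars[p] = _different_base(rng, chars[p])
            seq = "".join(chars)
    return seq


def simulate_reads(
    sim: Simulation,
    mode: str,
    depth: Optional[int] = None,
    p_slip: Optional[float] = None,
    seed: Optional[int] = None,
) -> Tuple[List[AlignedRead], pd.DataFrame]:
    """Emit pre-aligned spliced reads for one protocol.

    dRNA reads are always faithful copies of the mature transcript (true
    introns as N skips). cDNA/dcDNA reads additionally acquire, per
    molecule and planted locus, the artifact skip with probability
    ``p_slip``. Substitution errors never touch the alignment geometry.
    Returns the reads and a read-level truth table (read_id,
    transcript_id, mode, slipped, locus_id). Deterministic given the
    configuration seed (or ``seed``).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    cfg = sim.config
    depth = cfg.depth if depth is None else depth
    p = cfg.p_slip if p_slip is None else p_slip
    if mode == "dRNA" and p > 0:
        logger.warning(
            "dRNA mode ignores p_slip=%.3g: no artifact junctions are emitted", p
        )
    base_seed = cfg.seed if seed is None else seed
    # separate streams so alignment geometry is independent of the error model
    rng_slip = np.random.default_rng([base_seed, _MODE_INDEX[mode], 11])
    rng_err = np.random.default_rng([base_seed, _MODE_INDEX[mode], 13])
    genome_seq = sim.genome[cfg.chrom]
    truth_by_tid = {t.transcript_id: t for t in sim.truths}

    reads: List[AlignedRead] = []
    rows = []
    for model in sim.models:
        base_blocks = tuple((e.start, e.end) for e in model.exons)
        truth = truth_by_tid.get(model.transcript_id)
        for i in range(depth):
            blocks = base_blocks
            slipped = False
            if mode != "dRNA" and truth is not None and rng_slip.random() < p:
                blocks = _apply_slip(base_blocks, truth)
                slipped = True
            copies = (
                cfg.pcr_duplicate_factor
                if (mode == "cDNA" and slipped and cfg.pcr_duplicate_factor > 1)
                else 1
            )
            for c in range(copies):
                name = f"{model.transcript_id}_{mode}_{i:05d}"
                if c:
                    name += f"_dup{c}"
                reads.append(
                    AlignedRead(
                        name=name,
                        chrom=cfg.chrom,
                        strand=model.strand,
                        blocks=blocks,
                        sequence=_read_sequence(
                            rng_err, genome_seq, blocks, cfg.substitution_error_rate
                        ),
                    )
                )
                rows.append(
                    {
                        "read_id": name,
                        "transcript_id": model.transcript_id,
                        "mode": mode,
                        "slipped": slipped,
                        "locus_id": truth.locus_id if (truth and slipped) else "",
                    }
                )
    return reads, pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "mode", "slipped", "locus_id"]
    )


# ---------------------------------------------------------------------------
# file emission

def truth_table(truths: Sequence[SimTruth]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": t.locus_id,
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
            "chrom": t.junction.chrom,
            "start": t.junction.start,
            "end": t.junction.end,
            "strand": t.junction.strand,
            "repeat_length": t.repeat_length,
            "repeat_seq": t.repeat_seq,
            "p_slip": t.p_slip,
            "canonical_boundaries": t.canonical_boundaries,
        }
        for t in truths
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def build_genome(config: SimConfig, outdir: str) -> Dict[str, str]:
    """Write genome.fa, annotation.gff3 and truth.tsv; returns the paths."""
    import os

    from . import genome_io

    os.makedirs(outdir, exist_ok=True)
    sim = simulate_genome(config)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    genome_io.write_genome(sim.genome, paths["genome"])
    genome_io.write_annotation(sim.models, paths["annotation"])
    truth_table(sim.truths).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_all(config: SimConfig, outdir: str) -> Dict[str, str]:
    """Full fixture set: genome, annotation, truth and SAM files for all
    three protocols, plus read-level truth tables."""
    import os

    from . import genome_io

    paths = build_genome(config, outdir)
    sim = simulate_genome(config)
    lengths = {name: len(seq) for name, seq in sim.genome.items()}
    frames = []
    for mode in _MODES:
        reads, read_truth = simulate_reads(sim, mode)
        key = f"reads_{mode.lower()}"
        paths[key] = os.path.join(outdir, f"{key}.sam")
        genome_io.write_alignments(reads, lengths, paths[key])
        frames.append(read_truth)
    paths["read_truth"] = os.path.join(outdir, "read_truth.tsv")
    pd.concat(frames, ignore_index=True).to_csv(
        paths["read_truth"], sep="\t", index=False
    )
    return paths
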
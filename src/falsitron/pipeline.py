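"""End-to-end orchestration: detect -> annotate repeats -> abundance ->
splice profiles, with per-stage row counts logged."""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

from . import genome_io
from .detector import DetectorParams, detect_falsitrons
from .junctions import extract_junctions
from .profiles import profiles_to_long, splice_profiles
from .repeats import RepeatSearchParams, annotate_repeats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    cdna_alignments: str
    drna_alignments: str
    drna_annotation: str
    outdir: str
    detector: DetectorParams = field(default_factory=DetectorParams)
    repeats: RepeatSearchParams = field(default_factory=RepeatSearchParams)
    annotation_format: str = "auto"
    cdna_label: str = "cDNA"

    def validate(self) -> None:
        for path in (
            self.genome,
            self.cdna_alignments,
            self.drna_alignments,
            self.drna_annotation,
        ):
            if not os.path.exists(path):
                raise FileNotFoundError(path)


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Run the full analysis; returns the paths of candidates.tsv,
    candidates_annotated.tsv and profile.tsv under ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)

    genome = genome_io.read_genome(config.genome)
    drna_models = genome_io.read_annotation(
        config.drna_annotation, source_label="dRNA",
        annotation_format=config.annotation_format,
    )
    cdna_reads = genome_io.read_alignments(config.cdna_alignments)
    drna_reads = genome_io.read_alignments(config.drna_alignments)
    logger.info(
        "inputs: %d dRNA models, %d cDNA reads, %d dRNA reads",
        len(drna_models), len(cdna_reads), len(drna_reads),
    )

    cdna_junctions = extract_junctions(cdna_reads, dataset=config.cdna_label)
    logger.info("stage junctions: %d distinct cDNA junctions", len(cdna_junctions))

    candidates = detect_falsitrons(
        cdna_junctions, cdna_reads, drna_reads, drna_models, genome, config.detector
    )
    logger.info("stage detect: %d candidates", len(candidates))
    out: Dict[str, str] = {}
    out["candidates"] = os.path.join(config.outdir, "candidates.tsv")
    genome_io.write_candidates(candidates, out["candidates"])

    _, summary = annotate_repeats(candidates, genome, config.repeats)
    logger.info(
        "stage repeats: %s of %s candidates with >=4-nt direct repeat",
        summary["n_repeat_ge4"], summary["n_total"],
    )
    out["candidates_annotated"] = os.path.join(
        config.outdir, "candidates_annotated.tsv"
    )
    genome_io.write_candidates(candidates, out["candidates_annotated"])

    profiles = splice_profiles([c.junction for c in candidates], genome)
    logger.info(
        "stage profile: %d candidate junctions profiled",
        profiles["5prime"].n_sequences,
    )
    out["profile"] = os.path.join(config.outdir, "profile.tsv")
    profiles_to_long(profiles).to_csv(out["profile"], sep="\t", index=False)
    return out
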
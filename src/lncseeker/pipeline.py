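"""End-to-end identification cascade and function-prediction entry points.

The cascade applies, in order: the length/exon filter, the strand-specific
known-annotation filter, the coding-potential classification (coding-like
transcripts are dropped; lncRNA and TUCP candidates continue), and the
BLASTX/Pfam domain filter.  Survivors classified as lncRNA are clustered
into gene loci and given A-B-C names.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import (
    coding_potential,
    domain_filter,
    expression_function,
    locus_naming,
    structure_filter,
    transcript_io,
)
from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable cutoffs of the cascade, at their standard defaults."""

    thresholds: structure_filter.FilterThresholds = field(
        default_factory=structure_filter.FilterThresholds)
    max_lnc_aa: int = 100
    max_lnc_coverage: float = 0.30
    max_tucp_coverage: float = 0.90
    coding_score: float = 800.0
    blastx_evalue: float = domain_filter.BLASTX_EVALUE_CUTOFF
    pfam_evalue: float = domain_filter.PFAM_EVALUE_CUTOFF
    q_threshold: float = expression_function.DEFAULT_Q_THRESHOLD
    r_threshold: float = expression_function.DEFAULT_R_THRESHOLD
    positive_only: bool = False
    species_code: str = "hsa"
    # optional external-tool command templates (adapters, unused in tests)
    blastx_cmd: Optional[str] = None
    hmmer_cmd: Optional[str] = None
    uniref90_path: Optional[str] = None
    pfam_path: Optional[str] = None


@dataclass
class IdentifyResult:
    report: pd.DataFrame
    lncrnas: list[TranscriptModel]
    tucps: list[TranscriptModel]
    names: dict[str, locus_naming.LncRnaName]


def run_identify(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    annotations: AnnotationSet,
    blastx_hits: Sequence[domain_filter.HitRecord] = (),
    pfam_hits: Sequence[domain_filter.DomainHit] = (),
    config: PipelineConfig = PipelineConfig(),
    cds_scores: Optional[Mapping[str, float]] = None,
) -> IdentifyResult:
    """Run the four-stage cascade and name the resulting lncRNAs.

    ``cds_scores`` optionally supplies externally computed CDS scores per
    transcript; transcripts absent from it use the built-in surrogate.
    """
    fate: dict[str, str] = {}
    assess_info: dict[str, coding_potential.CodingAssessment] = {}

    verdicts = structure_filter.run_structure_filters(
        models, annotations, config.thresholds)
    survivors = []
    for model, verdict in zip(models, verdicts):
        if verdict.passed:
            survivors.append(model)
        else:
            fate[model.transcript_id] = verdict.status.value

    candidates = []
    for model in survivors:
        seq = transcript_io.extract_sequence(model, genome)
        external = (cds_scores or {}).get(model.transcript_id)
        assessment = coding_potential.assess(seq, external)
        assess_info[model.transcript_id] = assessment
        cls = coding_potential.classify_transcript(
            assessment, config.max_lnc_aa, config.max_lnc_coverage,
            config.max_tucp_coverage, config.coding_score)
        if cls is coding_potential.TranscriptClass.CODING_LIKE:
            fate[model.transcript_id] = "REMOVED_CODING_LIKE"
        else:
            candidates.append((model, cls))

    remaining = [m for m, _ in candidates]
    all_ids = {m.transcript_id for m in models}
    for qid in sorted({h.query_id for h in [*blastx_hits, *pfam_hits]}
                      - all_ids):
        logger.warning("hit names unknown transcript %r; ignored", qid)
    remaining_ids = {m.transcript_id for m in remaining}
    blastx_hits = [h for h in blastx_hits if h.query_id in remaining_ids]
    pfam_hits = [h for h in pfam_hits if h.query_id in remaining_ids]
    removed, kept = domain_filter.filter_by_blastx(
        remaining, blastx_hits, config.blastx_evalue)
    for m in removed:
        fate[m.transcript_id] = "REMOVED_BLASTX"
    removed, kept = domain_filter.filter_by_pfam(
        kept, pfam_hits, config.pfam_evalue)
    for m in removed:
        fate[m.transcript_id] = "REMOVED_PFAM"

    kept_ids = {m.transcript_id for m in kept}
    cls_of = {m.transcript_id: cls for m, cls in candidates}
    lncrnas = [m for m in kept
               if cls_of[m.transcript_id] is
               coding_potential.TranscriptClass.LNCRNA]
    tucps = [m for m in kept
             if cls_of[m.transcript_id] is
             coding_potential.TranscriptClass.TUCP]
    for m in kept:
        fate[m.transcript_id] = cls_of[m.transcript_id].value

    names = locus_naming.name_transcripts(lncrnas, config.species_code) \
        if lncrnas else {}

    rows = []
    for m in models:
        a = assess_info.get(m.transcript_id)
        name = names.get(m.transcript_id)
        rows.append({
            "transcript_id": m.transcript_id,
            "fate": fate[m.transcript_id],
            "aa_length": a.aa_length if a else None,
            "orf_coverage": round(a.orf_coverage, 6) if a else None,
            "cds_score": a.cds_score if a else None,
            "name": name.render() if name else "",
        })
    report = pd.DataFrame(
        rows, columns=["transcript_id", "fate", "aa_length",
                       "orf_coverage", "cds_score", "name"])
    return IdentifyResult(report, lncrnas, tucps, names)


def run_identify_files(
    transcripts_path: str | Path,
    genome_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    blastx_path: Optional[str | Path] = None,
    pfam_path: Optional[str | Path] = None,
    cds_scores_path: Optional[str | Path] = None,
    config: PipelineConfig = PipelineConfig(),
    in_format: str = "gtf",
) -> IdentifyResult:
    """File-level wrapper: read inputs, run the cascade, write reports."""
    reader = (transcript_io.read_gtf if in_format == "gtf"
              else transcript_io.read_bed12)
    models = reader(transcripts_path)
    genome = transcript_io.read_genome(genome_path)
    annotations = transcript_io.read_annotation_bed(annotation_path)
    blastx = (domain_filter.parse_blast_tabular(blastx_path)
              if blastx_path else [])
    pfam = (domain_filter.parse_domtblout(pfam_path) if pfam_path else [])
    cds_scores = (coding_potential.load_cds_scores(cds_scores_path)
                  if cds_scores_path else None)
    if not models:
        logger.warning("no transcripts in input; writing empty report")
    result = run_identify(models, genome, annotations, blastx, pfam,
                          config, cds_scores)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    renamed = [
        TranscriptModel(result.names[m.transcript_id].render(), m.exons)
        for m in result.lncrnas
    ]
    transcript_io.write_bed12(renamed, out / "lncrnas.bed12")
    transcript_io.write_bed12(result.tucps, out / "tucps.bed12")
    locus_naming.write_name_table(result.names, out / "names.tsv")
    return result


def run_function(
    matrix: pd.DataFrame,
    go_annotation: Mapping[str, set[str]],
    target_lnc: str,
    coding_rows: Optional[Sequence[str]] = None,
    config: PipelineConfig = PipelineConfig(),
):
    """Function prediction for one target lncRNA.

    ``coding_rows`` defaults to every GO-annotated row of the matrix
    other than the target.
    """
    if target_lnc not in matrix.index:
        near = [r for r in matrix.index
                if target_lnc.lower() in str(r).lower()][:5]
        raise KeyError(
            f"target {target_lnc!r} not in expression matrix"
            + (f"; similar ids: {near}" if near else ""))
    if coding_rows is None:
        coding_rows = [r for r in matrix.index
                       if r != target_lnc and go_annotation.get(r)]
    return expression_function.predict_function(
        target_lnc, matrix, list(coding_rows), go_annotation,
        config.q_threshold, config.r_threshold, config.positive_only)
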
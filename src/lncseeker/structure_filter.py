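"""Structural filters of the lncRNA identification cascade.

Filter 1 keeps multi-exonic transcripts whose spliced length exceeds
200 nt.  Filter 2 removes transcripts that overlap, or lie within 50 nt
of, a same-strand coding or pseudogene exon, and transcripts whose
exonic overlap covers at least 80 % of a same-strand small-RNA gene
(miRNA precursor, miRNA, tRNA, rRNA, snRNA, snoRNA).  Both rules are
strand-specific, so antisense transcripts of coding genes survive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

from .models import AnnotationSet, GenomeInterval, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the structural filters.

    min_length_nt: spliced length must strictly exceed this (nt).
    min_exons: minimum exon count (multi-exonic = 2).
    flank_nt: a transcript within this many nt of a same-strand coding or
        pseudogene exon is removed (inclusive distance).
    precursor_cover_frac: fraction of a small-RNA gene that must be
        covered by transcript exons to trigger removal.
    """

    min_length_nt: int = 200
    min_exons: int = 2
    flank_nt: int = 50
    precursor_cover_frac: float = 0.80

    def __post_init__(self) -> None:
        if min(self.min_length_nt, self.min_exons, self.flank_nt) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 < self.precursor_cover_frac <= 1):
            raise ValueError("precursor_cover_frac must be in (0, 1]")


class FilterStatus(str, Enum):
    PASS = "PASS"
    FAIL_LENGTH = "FAIL_LENGTH"
    FAIL_EXONS = "FAIL_EXONS"
    FAIL_CODING_OVERLAP = "FAIL_CODING_OVERLAP"
    FAIL_PSEUDOGENE_OVERLAP = "FAIL_PSEUDOGENE_OVERLAP"
    FAIL_SMALLRNA_OVERLAP = "FAIL_SMALLRNA_OVERLAP"


@dataclass(frozen=True)
class FilterVerdict:
    transcript_id: str
    status: FilterStatus
    evidence: str = ""

    def __post_init__(self) -> None:
        if (self.status is FilterStatus.PASS) != (self.evidence == ""):
            raise ValueError("PASS verdicts carry no evidence; failures must")

    @property
    def passed(self) -> bool:
        return self.status is FilterStatus.PASS


def filter_length_exons(
    model: TranscriptModel,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterVerdict:
    """Keep multi-exonic transcripts strictly longer than the cutoff."""
    if model.length <= thresholds.min_length_nt:
        return FilterVerdict(model.transcript_id, FilterStatus.FAIL_LENGTH,
                             f"length={model.length}")
    if model.n_exons < thresholds.min_exons:
        return FilterVerdict(model.transcript_id, FilterStatus.FAIL_EXONS,
                             f"exons={model.n_exons}")
    return FilterVerdict(model.transcript_id, FilterStatus.PASS)


def _within_flank(exon: GenomeInterval, feature: GenomeInterval,
                  flank: int) -> bool:
    """True if exon overlaps feature or lies within ``flank`` nt of it.

    Distance is genomic and strand-agnostic; an inter-interval gap of
    exactly ``flank`` nt still triggers.  Strand eligibility is checked
    by the caller.
    """
    if exon.chrom != feature.chrom:
        return False
    return feature.start <= exon.end + flank and exon.start <= feature.end + flank


class AnnotationIndex:
    """Interval-tree index over an AnnotationSet, keyed by (chrom, strand)."""

    def __init__(self, annotations: AnnotationSet) -> None:
        self._coding = self._build(
            (iv, name) for iv, name in annotations.coding_exons)
        self._pseudo = self._build(
            (iv, name) for iv, name in annotations.pseudogene_exons)
        self._small = self._build(
            (iv, (name, cls)) for iv, name, cls in annotations.small_rna_genes)

    @staticmethod
    def _build(entries) -> dict[tuple[str, str], IntervalTree]:
        trees: dict[tuple[str, str], IntervalTree] = {}
        for iv, payload in entries:
            trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
                iv.start, iv.end, (iv, payload))
        return trees

    def query(self, kind: str, chrom: str, strand: str,
              start: int, end: int):
        trees = {"coding": self._coding, "pseudogene": self._pseudo,
                 "small_rna": self._small}[kind]
        tree = trees.get((chrom, strand))
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def _smallrna_coverage(model: TranscriptModel, gene: GenomeInterval) -> float:
    """Fraction of the small-RNA gene covered by the transcript's exons.

    Intronic span does not count: coverage is summed over exon/gene
    intersections (exons are disjoint so the sum is exact).
    """
    covered = sum(e.overlap_nt(gene) for e in model.exons)
    return covered / len(gene)


def filter_known_annotation(
    model: TranscriptModel,
    annotations: AnnotationSet | AnnotationIndex,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterVerdict:
    """Strand-specific known-annotation overlap filter.

    Coding and pseudogene exons trigger failure on overlap or proximity
    within ``flank_nt``; small-RNA genes trigger only when the exonic
    overlap covers at least ``precursor_cover_frac`` of the gene.
    Opposite-strand features never trigger, allowing antisense lncRNAs.
    """
    index = (annotations if isinstance(annotations, AnnotationIndex)
             else AnnotationIndex(annotations))
    flank = thresholds.flank_nt

    for kind, status in (
        ("coding", FilterStatus.FAIL_CODING_OVERLAP),
        ("pseudogene", FilterStatus.FAIL_PSEUDOGENE_OVERLAP),
    ):
        hits: list[tuple[GenomeInterval, str]] = []
        for exon in model.exons:
            # +1 on each side so a gap of exactly flank nt is retrieved
            hits.extend(index.query(kind, exon.chrom, exon.strand,
                                    exon.start - flank - 1,
                                    exon.end + flank + 1))
        offenders = sorted(
            {name for iv, name in hits
             if any(_within_flank(e, iv, flank) for e in model.exons)}
        )
        if offenders:
            return FilterVerdict(model.transcript_id, status, offenders[0])

    small_hits = []
    for exon in model.exons:
        small_hits.extend(index.query("small_rna", exon.chrom, exon.strand,
                                      exon.start, exon.end))
    offenders = sorted(
        {name for iv, (name, _cls) in small_hits
         if _smallrna_coverage(model, iv) >= thresholds.precursor_cover_frac}
    )
    if offenders:
        return FilterVerdict(model.transcript_id,
                             FilterStatus.FAIL_SMALLRNA_OVERLAP, offenders[0])
    return FilterVerdict(model.transcript_id, FilterStatus.PASS)


def run_structure_filters(
    models: Iterable[TranscriptModel],
    annotations: AnnotationSet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[FilterVerdict]:
    """Apply filter 1 then filter 2 to every model; one verdict each."""
    index = AnnotationIndex(annotations)
    verdicts = []
    for model in models:
        verdict = filter_length_exons(model, thresholds)
        if verdict.passed:
            verdict = filter_known_annotation(model, index, thresholds)
        verdicts.append(verdict)
    return verdicts


def write_verdicts(verdicts: Iterable[FilterVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstatus\tevidence\n")
        for v in verdicts:
            fh.write(f"{v.transcript_id}\t{v.status.value}\t{v.evidence}\n")
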
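"""Core genomic domain types shared across the pipeline.

All coordinates are 0-based half-open (BED convention) on the internal
surface; format readers convert at the boundary.  Exons are stored in
genomic order regardless of strand; transcript orientation is applied
only when sequence is extracted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")

SMALL_RNA_CLASSES = frozenset(
    {"miRNA_precursor", "miRNA", "tRNA", "rRNA", "snRNA", "snoRNA"}
)


class ValidationError(ValueError):
    """An object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomeInterval") -> int:
        """Overlap length in nt, ignoring strand; 0 if different chrom."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """A multi-exon, stranded transcript model.

    Exons are non-overlapping, sorted by start, and share one
    chromosome and strand.
    """

    transcript_id: str
    exons: tuple[GenomeInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons on conflicting strands"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced length in nt (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class AnnotationSet:
    """Categorised reference features used by the annotation-overlap filter.

    Each entry is ``(interval, feature_id)``; small-RNA genes additionally
    carry a class label from :data:`SMALL_RNA_CLASSES`.
    """

    coding_exons: list[tuple[GenomeInterval, str]] = field(default_factory=list)
    pseudogene_exons: list[tuple[GenomeInterval, str]] = field(default_factory=list)
    small_rna_genes: list[tuple[GenomeInterval, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, _, cls in self.small_rna_genes:
            if cls not in SMALL_RNA_CLASSES:
                raise ValidationError(f"unknown small-RNA class {cls!r}")


def sort_models(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Deterministic ordering by (chrom, start, transcript_id)."""
    return sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id))


def flip_strand(interval: GenomeInterval) -> GenomeInterval:
    return GenomeInterval(
        interval.chrom, interval.start, interval.end,
        "-" if interval.strand == "+" else "+",
    )


def flip_model_strand(model: TranscriptModel) -> TranscriptModel:
    return TranscriptModel(model.transcript_id,
                           tuple(flip_strand(e) for e in model.exons))


def make_transcript(
    transcript_id: str,
    chrom: str,
    strand: str,
    exon_coords: Sequence[tuple[int, int]],
) -> TranscriptModel:
    """Convenience constructor from (start, end) pairs."""
    exons = tuple(
        GenomeInterval(chrom, s, e, strand)
        for s, e in sorted(exon_coords)
    )
    return TranscriptModel(transcript_id, exons)
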
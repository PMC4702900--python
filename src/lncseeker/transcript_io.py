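"""Reading and writing transcript models and extracting spliced sequences.

Supported formats: GTF 2.2 (``exon`` features with ``transcript_id``
attributes, 1-based inclusive coordinates) and BED12.  Annotation sets
for the overlap filter are read from BED6+1 files carrying a feature
class in the seventh column.  Genomes are plain (optionally line-wrapped,
multi-record) FASTA.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .models import (
    SMALL_RNA_CLASSES,
    AnnotationSet,
    GenomeInterval,
    TranscriptModel,
    ValidationError,
    sort_models,
)


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Only ``exon`` features are used.  GTF's 1-based inclusive coordinates
    are converted to the internal 0-based half-open convention.  Output is
    sorted by (chrom, start, transcript_id).
    """
    exons_by_tx: dict[str, list[GenomeInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            attributes = _parse_gtf_attributes(attrs)
            tx_id = attributes.get("transcript_id")
            if tx_id is None:
                raise ParseError(
                    f"{path}: line {lineno}: exon lacks transcript_id attribute"
                )
            try:
                interval = GenomeInterval(chrom, start1 - 1, end1, strand)
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            exons_by_tx.setdefault(tx_id, []).append(interval)

    models = []
    for tx_id, exons in exons_by_tx.items():
        try:
            models.append(TranscriptModel(tx_id, tuple(sorted(exons))))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None
    return sort_models(models)


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a BED12 file.

    Duplicate names are an error, never silently merged.
    """
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}: line {lineno}: blockCount={block_count} but "
                    f"{len(sizes)} blockSizes / {len(starts)} blockStarts"
                )
            chrom_start, chrom_end = int(start_s), int(end_s)
            exons = []
            for size, rel in zip(sizes, starts):
                exons.append(
                    GenomeInterval(chrom, chrom_start + rel,
                                   chrom_start + rel + size, strand)
                )
            if exons[-1].end != chrom_end:
                raise ParseError(
                    f"{path}: line {lineno}: blocks inconsistent with chromEnd"
                )
            if name in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate transcript id {name!r}"
                )
            seen.add(name)
            models.append(TranscriptModel(name, tuple(exons)))
    return models


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write models as canonical BED12.

    Canonical form: score 0, thickStart = thickEnd = chromStart,
    itemRgb 0, no trailing commas in block lists.  ``read_bed12`` after
    ``write_bed12`` is the identity on canonical models.
    """
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(len(e)) for e in m.exons)
            rel_starts = ",".join(str(e.start - m.start) for e in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.start),
                        str(m.end),
                        m.transcript_id,
                        "0",
                        m.strand,
                        str(m.start),
                        str(m.start),
                        "0",
                        str(m.n_exons),
                        sizes,
                        rel_starts,
                    ]
                )
                + "\n"
            )


def read_annotation_bed(path: str | Path) -> AnnotationSet:
    """Read an annotation set from a BED6+1 file.

    Column 7 carries the feature class: ``coding``, ``pseudogene``, or a
    small-RNA class (miRNA_precursor, miRNA, tRNA, rRNA, snRNA, snoRNA).
    """
    anns = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 7 fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand, cls = fields[:7]
            iv = GenomeInterval(chrom, int(start_s), int(end_s), strand)
            if cls == "coding":
                anns.coding_exons.append((iv, name))
            elif cls == "pseudogene":
                anns.pseudogene_exons.append((iv, name))
            elif cls in SMALL_RNA_CLASSES:
                anns.small_rna_genes.append((iv, name, cls))
            else:
                raise ParseError(
                    f"{path}: line {lineno}: unknown feature class {cls!r}"
                )
    return anns


def write_annotation_bed(anns: AnnotationSet, path: str | Path) -> None:
    rows = []
    for iv, name in anns.coding_exons:
        rows.append((iv, name, "coding"))
    for iv, name in anns.pseudogene_exons:
        rows.append((iv, name, "pseudogene"))
    for iv, name, cls in anns.small_rna_genes:
        rows.append((iv, name, cls))
    rows.sort(key=lambda r: (r[0].chrom, r[0].start, r[1]))
    with open(path, "w") as fh:
        for iv, name, cls in rows:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t{cls}\n"
            )


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a (small) multi-record FASTA into a chrom -> sequence map."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation.

    Exon sequences are concatenated in genomic order; for minus-strand
    transcripts the concatenation is reverse-complemented.
    """
    if model.chrom not in genome:
        raise KeyError(f"{model.transcript_id}: chromosome {model.chrom!r} "
                       "not in genome")
    chrom_seq = genome[model.chrom]
    if model.end > len(chrom_seq):
        raise IndexError(
            f"{model.transcript_id}: exon end {model.end} beyond "
            f"{model.chrom} length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_gtf(models: Iterable[TranscriptModel], path: str | Path,
              source: str = "lncseeker") -> None:
    """Write models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in sort_models(models):
            for e in m.exons:
                attrs = (
                    f'gene_id "{m.transcript_id}"; '
                    f'transcript_id "{m.transcript_id}";'
                )
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )
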
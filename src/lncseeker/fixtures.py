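"""Seeded synthetic fixture generator for the whole pipeline.

Builds a toy genome, reference annotations, transcript models with
planted fates, similarity/domain hit tables, an expression matrix with a
planted co-expression block, and a GO annotation with a planted enriched
term — everything the identification cascade and the function predictor
consume, with a truth table recording the intended fate of every
transcript.

ORFs are planted by explicit codon construction: transcript background
sequence is drawn from the {C,G,T} alphabet, which contains no ATG and
no stop codon in any frame (all of ATG/TAA/TAG/TGA require an A), so the
single planted ATG...stop span is provably the longest ORF.  Every
component draws from its own RNG stream derived from the master seed, so
adding a component never perturbs the others.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .domain_filter import DomainHit, HitRecord
from .models import AnnotationSet, GenomeInterval, TranscriptModel
from . import transcript_io

_NO_A = "CGT"
_REVCOMP = str.maketrans("ACGT", "TGCA")

CONSERVATION_SPECIES = ("ptr", "mml", "dre")
DEFAULT_CLADES = {
    "primates": frozenset({"hsa", "ptr", "mml"}),
    "vertebrates": frozenset({"hsa", "ptr", "mml", "dre"}),
}


class GenerationError(RuntimeError):
    """Fixture could not be laid out under the requested spec."""


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic bundle.

    Counts are planted transcripts per class; genome_length must leave
    room to place all features without forced overlap; n_samples sizes
    the expression matrix.
    """

    seed: int = 0
    n_coding: int = 8
    n_lnc: int = 8
    n_tucp: int = 4
    n_antisense: int = 3
    genome_length: int = 200_000
    n_samples: int = 12
    planted_go_term: str = "GO:0007283"
    n_partners: int = 8
    n_background_coding: int = 30
    include_failures: bool = True
    species_code: str = "hsa"

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_lnc", "n_tucp", "n_antisense",
                     "n_partners", "n_background_coding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    annotations: AnnotationSet
    truth: pd.DataFrame
    blastx_hits: list[HitRecord]
    pfam_hits: list[DomainHit]
    blastn_hits: dict[str, list[HitRecord]]
    expression: pd.DataFrame
    go_annotation: dict[str, set[str]]
    target_lnc: str
    partner_ids: list[str]
    coding_expression_ids: list[str]
    clades: dict[str, frozenset] = field(default_factory=lambda: dict(DEFAULT_CLADES))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _background(rng: np.random.Generator, n: int) -> str:
    """A-free background: no ATG or stop codon can occur in any frame."""
    return "".join(rng.choice(list(_NO_A), size=n))


def _orf_block(rng: np.random.Generator, aa_length: int, with_stop: bool = True) -> str:
    """ATG + (aa_length-1) A-free codons + TAA; nothing else starts an ORF."""
    body = _background(rng, 3 * (aa_length - 1))
    return "ATG" + body + ("TAA" if with_stop else "")


def _plant_sequence(rng: np.random.Generator, length: int,
                    aa_length: Optional[int]) -> str:
    """Transcript sequence of exact length with one controlled ORF.

    The character right after a planted stop is forced to 'C' so the
    stop's trailing As cannot seed a spurious ATG.
    """
    if aa_length is None:
        return _background(rng, length)
    orf = _orf_block(rng, aa_length)
    slack = length - len(orf)
    if slack < 1:
        raise GenerationError(
            f"transcript length {length} too short for a {aa_length}-aa ORF")
    offset = int(rng.integers(3, max(4, slack - 1))) if slack > 4 else 1
    offset = min(offset, slack - 1)
    prefix = _background(rng, offset)
    suffix = "C" + _background(rng, slack - offset - 1)
    return prefix + orf + suffix


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


class _Layout:
    """Sequential feature placement along one chromosome."""

    def __init__(self, rng: np.random.Generator, genome_length: int,
                 gap: tuple[int, int] = (300, 500)) -> None:
        self.rng = rng
        self.cursor = 1000
        self.genome_length = genome_length
        self.gap = gap

    def take(self, span: int) -> int:
        start = self.cursor
        if start + span > self.genome_length - 1000:
            raise GenerationError(
                f"genome_length {self.genome_length} too small: placement "
                f"cursor reached {start + span}")
        self.cursor = start + span + int(self.rng.integers(*self.gap))
        return start


def _make_exons(rng: np.random.Generator, chrom: str, strand: str,
                start: int, spliced_length: int,
                n_exons: int) -> tuple[TranscriptModel, int]:
    """Split a spliced length into exons with random introns."""
    cuts = sorted(rng.choice(
        np.arange(80, spliced_length - 80),
        size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0, *[int(c) for c in cuts], spliced_length]
    exon_lengths = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(60, 150)) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, elen in enumerate(exon_lengths):
        exons.append(GenomeInterval(chrom, pos, pos + elen, strand))
        pos = pos + elen + (introns[i] if i < len(introns) else 0)
    return TranscriptModel("tmp", tuple(exons)), pos - start


def _write_into_genome(genome: list[str], model: TranscriptModel,
                       tx_seq: str) -> None:
    """Write a spliced sequence into the genome at the model's exons."""
    genomic = tx_seq if model.strand == "+" else _revcomp(tx_seq)
    offset = 0
    for e in model.exons:
        genome[e.start : e.end] = genomic[offset : offset + len(e)]
        offset += len(e)


_CLASS_PARAMS = {
    # planted_class: (spliced_length, orf_aa, n_exons)
    "lncRNA": (520, 40, 3),
    "antisense_lncRNA": (480, 35, 2),
    "TUCP": (600, 90, 2),
    "coding": (900, 280, 3),
}


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Deterministic synthetic bundle for one FixtureSpec."""
    chrom = "chr1"
    rng_genome = _rng(spec.seed, 0)
    rng_layout = _rng(spec.seed, 1)
    rng_tx = _rng(spec.seed, 2)
    rng_ann = _rng(spec.seed, 3)
    rng_hits = _rng(spec.seed, 4)
    rng_expr = _rng(spec.seed, 5)
    rng_go = _rng(spec.seed, 6)

    genome = list("".join(rng_genome.choice(list("ACGT"),
                                            size=spec.genome_length)))
    layout = _Layout(rng_layout, spec.genome_length)
    annotations = AnnotationSet()
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []

    def plant(tx_id: str, planted_class: str, expected_fate: str,
              strand: str) -> TranscriptModel:
        length, aa, n_exons = _CLASS_PARAMS[
            planted_class if planted_class in _CLASS_PARAMS else "lncRNA"]
        seq = _plant_sequence(rng_tx, length, aa)
        start = layout.take(length + 400)
        model, _span = _make_exons(rng_tx, chrom, strand, start, length, n_exons)
        model = TranscriptModel(tx_id, model.exons)
        _write_into_genome(genome, model, seq)
        transcripts.append(model)
        truth_rows.append({"transcript_id": tx_id,
                           "planted_class": planted_class,
                           "expected_fate": expected_fate})
        return model

    strands = ["+", "-"]
    lnc_ids = []
    for i in range(spec.n_lnc):
        tx_id = f"LNC{i + 1:03d}"
        plant(tx_id, "lncRNA", "LNCRNA", strands[i % 2])
        lnc_ids.append(tx_id)
    for i in range(spec.n_tucp):
        plant(f"TUCP{i + 1:03d}", "TUCP", "TUCP", strands[i % 2])
    for i in range(spec.n_coding):
        plant(f"COD{i + 1:03d}", "coding", "REMOVED_CODING_LIKE",
              strands[i % 2])
    antisense_ids = []
    for i in range(spec.n_antisense):
        tx_id = f"AS{i + 1:03d}"
        strand = strands[i % 2]
        model = plant(tx_id, "antisense_lncRNA", "LNCRNA", strand)
        # a coding exon exactly under the first exon, opposite strand
        opp = "-" if strand == "+" else "+"
        e = model.exons[0]
        annotations.coding_exons.append(
            (GenomeInterval(chrom, e.start, e.end, opp), f"ANTGENE{i + 1}"))
        antisense_ids.append(tx_id)

    blastx_rows: list[HitRecord] = []
    pfam_rows: list[DomainHit] = []

    if spec.include_failures:
        # filter-1 failures
        short_seq = _plant_sequence(rng_tx, 180, None)
        start = layout.take(400)
        m = _make_exons(rng_tx, chrom, "+", start, 180, 2)[0]
        m = TranscriptModel("SHORT001", m.exons)
        _write_into_genome(genome, m, short_seq)
        transcripts.append(m)
        truth_rows.append({"transcript_id": "SHORT001",
                           "planted_class": "fail_length",
                           "expected_fate": "FAIL_LENGTH"})

        mono_seq = _plant_sequence(rng_tx, 500, None)
        start = layout.take(700)
        m = TranscriptModel("MONO001", (GenomeInterval(chrom, start,
                                                       start + 500, "+"),))
        _write_into_genome(genome, m, mono_seq)
        transcripts.append(m)
        truth_rows.append({"transcript_id": "MONO001",
                           "planted_class": "fail_exons",
                           "expected_fate": "FAIL_EXONS"})

        # filter-2 failures: sense overlap with a coding exon
        m = plant("SENSE001", "fail_coding_overlap", "FAIL_CODING_OVERLAP", "+")
        e = m.exons[0]
        annotations.coding_exons.append(
            (GenomeInterval(chrom, e.start, e.end, "+"), "SENSEGENE1"))

        # transcript exon fully covering a miRNA precursor, same strand
        m = plant("MIR001", "fail_smallrna_overlap", "FAIL_SMALLRNA_OVERLAP", "+")
        e = m.exons[0]
        annotations.small_rna_genes.append(
            (GenomeInterval(chrom, e.start + 5, e.start + 85, "+"),
             "mir-fix-1", "miRNA_precursor"))

        # filter-4 failures
        plant("BLX001", "fail_blastx", "REMOVED_BLASTX", "-")
        blastx_rows.append(HitRecord("BLX001", "UniRef90_FIX1", 92.0, 120,
                                     8, 1, 1, 360, 1, 120, 1e-45, 210.0))
        plant("PFX001", "fail_pfam", "REMOVED_PFAM", "+")
        pfam_rows.append(DomainHit("PFX001", "PF00001.21", 1e-8, 1e-8))

    # plausible (unused-by-the-cascade) hits for coding plants
    for i in range(spec.n_coding):
        e_val = float(10.0 ** -rng_hits.integers(40, 80))
        blastx_rows.append(HitRecord(f"COD{i + 1:03d}", f"UniRef90_C{i + 1}",
                                     95.0, 250, 10, 0, 1, 750, 1, 250,
                                     e_val, 400.0))

    # decoy annotation features in their own slots (must not hit plants)
    for i in range(6):
        start = layout.take(300)
        strand = strands[i % 2]
        annotations.coding_exons.append(
            (GenomeInterval(chrom, start, start + 200, strand),
             f"DECOYCOD{i + 1}"))
    for i in range(3):
        start = layout.take(250)
        annotations.pseudogene_exons.append(
            (GenomeInterval(chrom, start, start + 150, strands[i % 2]),
             f"DECOYPSE{i + 1}"))
    for i, cls in enumerate(("miRNA_precursor", "tRNA", "snoRNA")):
        start = layout.take(200)
        annotations.small_rna_genes.append(
            (GenomeInterval(chrom, start, start + 80, strands[i % 2]),
             f"DECOYSRNA{i + 1}", cls))

    # conservation hit tables: lnc 1 primate-conserved, lnc 2
    # vertebrate-conserved, lnc 3 species-specific, remainder alternate
    blastn_hits: dict[str, list[HitRecord]] = {sp: [] for sp in
                                               CONSERVATION_SPECIES}
    for i, lnc in enumerate(lnc_ids):
        if i % 3 == 2:
            continue  # species-specific
        species = CONSERVATION_SPECIES[:2] if i % 3 == 0 else CONSERVATION_SPECIES
        for sp in species:
            n_hits = int(rng_hits.integers(1, 4))
            for j in range(n_hits):
                e_val = float(10.0 ** -rng_hits.integers(6, 40))
                blastn_hits[sp].append(
                    HitRecord(lnc, f"{sp}-lnc{i + 1}-{j + 1}", 88.0, 150,
                              12, 2, 1, 150, 1, 150, e_val,
                              float(rng_hits.integers(50, 200))))

    # expression matrix with a planted co-expression block
    target_lnc = lnc_ids[0] if lnc_ids else ""
    partner_ids = [f"PC{i + 1:03d}" for i in range(spec.n_partners)]
    background_ids = [f"BG{i + 1:03d}"
                      for i in range(spec.n_background_coding)]
    coding_expr_ids = partner_ids + background_ids
    rows = {}
    target_profile = rng_expr.lognormal(mean=2.0, sigma=1.0,
                                        size=spec.n_samples)
    for lnc in lnc_ids:
        if lnc == target_lnc:
            rows[lnc] = target_profile
        else:
            rows[lnc] = rng_expr.lognormal(2.0, 1.0, spec.n_samples)
    for pid in partner_ids:
        scale = float(rng_expr.uniform(0.5, 2.0))
        noise = rng_expr.normal(0.0, 0.02 * target_profile.std(),
                                spec.n_samples)
        rows[pid] = np.maximum(0.0, scale * target_profile + noise)
    for bid in background_ids:
        rows[bid] = rng_expr.lognormal(2.0, 1.0, spec.n_samples)
    expression = pd.DataFrame(
        rows, index=[f"S{i + 1:02d}" for i in range(spec.n_samples)]
    ).T
    expression.index.name = "feature_id"

    # GO annotation: planted term enriched among partners, present at
    # background frequency elsewhere
    go_pool = [f"GO:{7000000 + i}" for i in range(10)]
    go_annotation: dict[str, set[str]] = {}
    for i, pid in enumerate(partner_ids):
        terms = {spec.planted_go_term} if i < max(1, spec.n_partners - 1) \
            else set()
        terms.add(str(rng_go.choice(go_pool)))
        go_annotation[pid] = terms
    for bid in background_ids:
        terms = {str(t) for t in rng_go.choice(go_pool, size=2,
                                               replace=False)}
        if rng_go.random() < 0.10:
            terms.add(spec.planted_go_term)
        go_annotation[bid] = terms

    truth = pd.DataFrame(truth_rows,
                         columns=["transcript_id", "planted_class",
                                  "expected_fate"])
    return FixtureBundle(
        spec=spec,
        genome={chrom: "".join(genome)},
        transcripts=transcripts,
        annotations=annotations,
        truth=truth,
        blastx_hits=blastx_rows,
        pfam_hits=pfam_rows,
        blastn_hits=blastn_hits,
        expression=expression,
        go_annotation=go_annotation,
        target_lnc=target_lnc,
        partner_ids=partner_ids,
        coding_expression_ids=coding_expr_ids,
    )


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle component in its standard on-disk format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.gtf",
        "annotation": out / "annotation.bed",
        "blastx": out / "blastx.tsv",
        "pfam": out / "pfam.domtblout",
        "expression": out / "expression.tsv",
        "go": out / "go.tsv",
        "truth": out / "truth.tsv",
        "clades": out / "clades.txt",
    }
    transcript_io.write_genome(bundle.genome, paths["genome"])
    transcript_io.write_gtf(bundle.transcripts, paths["transcripts"])
    transcript_io.write_annotation_bed(bundle.annotations, paths["annotation"])
    _write_outfmt6(bundle.blastx_hits, paths["blastx"])
    _write_domtblout(bundle.pfam_hits, paths["pfam"])
    for sp, hits in sorted(bundle.blastn_hits.items()):
        p = out / f"blastn_{sp}.tsv"
        _write_outfmt6(hits, p)
        paths[f"blastn_{sp}"] = p
    bundle.expression.to_csv(paths["expression"], sep="\t")
    with open(paths["go"], "w") as fh:
        fh.write("gene_id\tgo_term\tnamespace\n")
        for gene in sorted(bundle.go_annotation):
            for term in sorted(bundle.go_annotation[gene]):
                fh.write(f"{gene}\t{term}\tbiological_process\n")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["clades"], "w") as fh:
        for name, members in sorted(bundle.clades.items()):
            fh.write(f"{name} = {','.join(sorted(members))}\n")
    return paths


def _write_outfmt6(hits: list[HitRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end,
                h.s_start, h.s_end, h.e_value, h.bit_score)) + "\n")


def _write_domtblout(hits: list[DomainHit], path: Path) -> None:
    header = ("#target_name accession tlen query_name accession qlen "
              "full_E full_score full_bias dom_n dom_of c_Evalue i_Evalue "
              "dom_score\n")
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            fh.write(f"{h.domain_id} - 120 {h.query_id} - 200 "
                     f"{h.full_seq_evalue} 80.0 0.1 1 1 "
                     f"{h.best_domain_evalue} {h.best_domain_evalue} 78.0\n")
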
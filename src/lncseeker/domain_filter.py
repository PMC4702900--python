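"""Protein-similarity and Pfam-domain filter (cascade filter 4).

Transcripts with a UniRef90 BLASTX hit at E < 1e-30 are removed; the
remainder are translated in all three forward frames and removed when a
Pfam hit shows both full-sequence E < 1e-5 and best-domain E < 1e-5.
The library contract is over parsed tabular hit files (BLAST outfmt 6
and HMMER3 domtblout), so no external tool or database is needed at
test time; command templates for running the tools live in the pipeline
configuration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .coding_potential import VALID_ALPHABET
from .models import TranscriptModel

logger = logging.getLogger(__name__)

BLASTX_EVALUE_CUTOFF = 1e-30
PFAM_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class HitRecord:
    """One row of BLAST tabular (outfmt 6) output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")


@dataclass(frozen=True)
class DomainHit:
    """Aggregated Pfam evidence for one query/domain pair."""

    query_id: str
    domain_id: str
    full_seq_evalue: float
    best_domain_evalue: float

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0 or self.best_domain_evalue < 0:
            raise ValueError("negative E-value in domain hit")


def translate_three_frames(sequence: str) -> tuple[str, str, str]:
    """Translate the three forward frames with the standard code.

    Trailing partial codons are dropped; stop codons render as '*'.
    """
    sequence = sequence.upper()
    bad = set(sequence) - VALID_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = []
    for frame in range(3):
        sub = sequence[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames.append(str(Seq(sub).translate()) if sub else "")
    return tuple(frames)  # type: ignore[return-value]


def parse_blast_tabular(path: str | Path) -> list[HitRecord]:
    """Parse BLAST outfmt-6 (12 fixed columns)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(f)}"
                )
            hits.append(
                HitRecord(
                    query_id=f[0], subject_id=f[1],
                    pct_identity=float(f[2]), aln_length=int(f[3]),
                    mismatches=int(f[4]), gap_opens=int(f[5]),
                    q_start=int(f[6]), q_end=int(f[7]),
                    s_start=int(f[8]), s_end=int(f[9]),
                    e_value=float(f[10]), bit_score=float(f[11]),
                )
            )
    return hits


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 --domtblout and aggregate per (query, domain).

    Column layout per hmmscan: target name, target accession, tlen,
    query name, query accession, qlen, full-sequence E-value (col 7),
    ... , per-domain i-Evalue (col 13).  The best-domain E-value of a
    pair is the minimum i-Evalue over its domain rows.
    """
    full: dict[tuple[str, str], float] = {}
    best: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 14:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 14 columns, got {len(f)}"
                )
            domain_id, query_id = f[0], f[3]
            full_e, dom_e = float(f[6]), float(f[12])
            key = (query_id, domain_id)
            full[key] = min(full.get(key, full_e), full_e)
            best[key] = min(best.get(key, dom_e), dom_e)
    return [
        DomainHit(q, d, full[(q, d)], best[(q, d)])
        for q, d in sorted(full)
    ]


def _partition(
    transcripts: Sequence[TranscriptModel],
    flagged_ids: set[str],
    hit_ids: Iterable[str],
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    known = {t.transcript_id for t in transcripts}
    for qid in set(hit_ids) - known:
        logger.warning("hit names unknown transcript %r; ignored", qid)
    removed = [t for t in transcripts if t.transcript_id in flagged_ids]
    kept = [t for t in transcripts if t.transcript_id not in flagged_ids]
    return removed, kept


def filter_by_blastx(
    transcripts: Sequence[TranscriptModel],
    hits: Iterable[HitRecord],
    threshold: float = BLASTX_EVALUE_CUTOFF,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition into (removed, kept): removed iff any hit E < threshold."""
    hits = list(hits)
    flagged = {h.query_id for h in hits if h.e_value < threshold}
    return _partition(transcripts, flagged, (h.query_id for h in hits))


def filter_by_pfam(
    transcripts: Sequence[TranscriptModel],
    hits: Iterable[DomainHit],
    threshold: float = PFAM_EVALUE_CUTOFF,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition on the Pfam rule: both E-values below threshold in one hit.

    The conjunction is per hit: a transcript with one hit failing the
    full-sequence test and another failing the best-domain test is kept.
    PfamA and PfamB hits are treated identically.
    """
    hits = list(hits)
    flagged = {
        h.query_id
        for h in hits
        if h.full_seq_evalue < threshold and h.best_domain_evalue < threshold
    }
    return _partition(transcripts, flagged, (h.query_id for h in hits))
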
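"""ORF discovery, coding-potential scoring, and the lncRNA/TUCP decision.

A transcript is called a lncRNA when its longest ORF is shorter than
100 aa, ORF coverage is below 30 % and the CDS score is below 800; it is
a TUCP (transcript of uncertain coding potential) when the CDS score is
below 800 and ORF coverage lies in [30 %, 90 %]; anything else is
treated as coding-like and removed from the lncRNA set.

The CDS score is on the 0-1000 txCdsPredict scale.  Scores can be
imported from a user-supplied table, or computed by a built-in surrogate
scorer on the same scale (monotone in ORF length, with fixed bonuses for
a stop codon and a Kozak-consistent context).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# surrogate scorer calibration (0-1000 txCdsPredict-like scale)
_SCORE_PER_AA = 6.0
_STOP_BONUS = 50.0
_KOZAK_BONUS = 50.0
_SCORE_CAP = 1000.0


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame on the forward strand of a transcript.

    nt_length includes the stop codon when present, so a stop-terminated
    full-length ORF reaches coverage 1.0; aa_length excludes the stop.
    """

    frame: int
    start_offset: int
    aa_length: int
    nt_length: int
    has_stop: bool

    def __post_init__(self) -> None:
        expected = 3 * self.aa_length + (3 if self.has_stop else 0)
        if self.nt_length != expected:
            raise ValueError(
                f"nt_length {self.nt_length} inconsistent with "
                f"aa_length {self.aa_length}, has_stop {self.has_stop}"
            )
        if self.frame not in (0, 1, 2):
            raise ValueError(f"invalid frame {self.frame}")


@dataclass(frozen=True)
class CodingAssessment:
    longest_orf: Optional[OrfCall]
    orf_coverage: float
    cds_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orf_coverage <= 1.0):
            raise ValueError(f"orf_coverage {self.orf_coverage} outside [0,1]")
        if not (0.0 <= self.cds_score <= 1000.0):
            raise ValueError(f"cds_score {self.cds_score} outside [0,1000]")

    @property
    def aa_length(self) -> int:
        return self.longest_orf.aa_length if self.longest_orf else 0


class TranscriptClass(str, Enum):
    LNCRNA = "LNCRNA"
    TUCP = "TUCP"
    CODING_LIKE = "CODING_LIKE"


def _check_alphabet(sequence: str) -> None:
    bad = set(sequence) - VALID_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")


def find_longest_orf(sequence: str) -> Optional[OrfCall]:
    """Longest ATG-to-stop ORF over the three forward frames.

    An ORF starts at ATG and ends at the first in-frame stop codon
    (included in nt_length) or runs off the 3' end (has_stop False).
    Ties on aa_length are broken by smaller start_offset, then smaller
    frame.  Returns None when no ATG-initiated ORF exists.
    """
    sequence = sequence.upper()
    _check_alphabet(sequence)
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")

    best: Optional[OrfCall] = None
    for frame in range(3):
        orf_start: Optional[int] = None
        n_codons = 0
        for pos in range(frame, len(sequence) - 2, 3):
            codon = sequence[pos : pos + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = pos
                    n_codons = 1
                continue
            if codon in STOP_CODONS:
                call = OrfCall(frame, orf_start, n_codons,
                               3 * n_codons + 3, True)
                best = _better(best, call)
                orf_start = None
            else:
                n_codons += 1
        if orf_start is not None:  # open ORF running off the 3' end
            call = OrfCall(frame, orf_start, n_codons, 3 * n_codons, False)
            best = _better(best, call)
    return best


def _better(a: Optional[OrfCall], b: OrfCall) -> OrfCall:
    if a is None:
        return b
    key_a = (-a.aa_length, a.start_offset, a.frame)
    key_b = (-b.aa_length, b.start_offset, b.frame)
    return a if key_a <= key_b else b


def score_cds(sequence: str, orf: Optional[OrfCall]) -> float:
    """Surrogate coding-potential score on the 0-1000 scale.

    Deterministic and monotone non-decreasing in ORF aa_length; awards a
    fixed bonus for a stop codon and for an A/G at position -3 of the
    start (Kozak-consistent context).  A missing ORF scores 0, and
    scores saturate at 1000.
    """
    if orf is None:
        return 0.0
    score = _SCORE_PER_AA * orf.aa_length
    if orf.has_stop:
        score += _STOP_BONUS
    if orf.start_offset >= 3 and sequence[orf.start_offset - 3].upper() in "AG":
        score += _KOZAK_BONUS
    return min(_SCORE_CAP, score)


def assess(sequence: str, cds_score: Optional[float] = None) -> CodingAssessment:
    """Full coding assessment of one transcript sequence.

    ``cds_score`` overrides the surrogate with an externally computed
    value (e.g. parsed txCdsPredict output).
    """
    orf = find_longest_orf(sequence)
    coverage = (orf.nt_length / len(sequence)) if orf else 0.0
    score = score_cds(sequence, orf) if cds_score is None else float(cds_score)
    return CodingAssessment(orf, coverage, score)


def classify_transcript(
    assessment: CodingAssessment,
    max_lnc_aa: int = 100,
    max_lnc_coverage: float = 0.30,
    max_tucp_coverage: float = 0.90,
    coding_score: float = 800.0,
) -> TranscriptClass:
    """Apply the 5-way decision thresholds.

    lncRNA: aa < 100 and coverage < 0.30 and score < 800.
    TUCP: score < 800 and coverage <= 0.90 otherwise (the printed rule
    covers 0.30 <= coverage <= 0.90; the unassigned corner aa >= 100
    with coverage < 0.30 is also routed here).
    Coding-like: score >= 800 or coverage > 0.90.
    """
    if assessment.cds_score >= coding_score or \
            assessment.orf_coverage > max_tucp_coverage:
        return TranscriptClass.CODING_LIKE
    if assessment.aa_length < max_lnc_aa and \
            assessment.orf_coverage < max_lnc_coverage:
        return TranscriptClass.LNCRNA
    return TranscriptClass.TUCP


@dataclass(frozen=True)
class ClassifierMetrics:
    """Binary-classification metrics; a None field marks an undefined ratio."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    tn: int
    fp: int
    fn: int


def classifier_metrics(
    truth_labels: Sequence[bool], predicted_labels: Sequence[bool]
) -> ClassifierMetrics:
    """Accuracy, sensitivity and specificity from paired label vectors.

    Labels are booleans (True = positive).  Undefined ratios (empty
    denominator) are reported as None, never NaN.
    """
    if len(truth_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if len(truth_labels) == 0:
        raise ValueError("empty label vectors")
    tp = sum(1 for t, p in zip(truth_labels, predicted_labels) if t and p)
    tn = sum(1 for t, p in zip(truth_labels, predicted_labels) if not t and not p)
    fp = sum(1 for t, p in zip(truth_labels, predicted_labels) if not t and p)
    fn = sum(1 for t, p in zip(truth_labels, predicted_labels) if t and not p)
    n = tp + tn + fp + fn
    return ClassifierMetrics(
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def load_cds_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of externally computed CDS scores."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or \
                    line.lower().startswith("transcript_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            scores[parts[0]] = float(parts[1])
    return scores


def write_classification_report(
    rows: Iterable[tuple[str, CodingAssessment, TranscriptClass]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\taa_length\torf_coverage\tcds_score\tclass\n")
        for tx_id, a, cls in rows:
            fh.write(f"{tx_id}\t{a.aa_length}\t{a.orf_coverage:.4f}\t"
                     f"{a.cds_score:.1f}\t{cls.value}\n")
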
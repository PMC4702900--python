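"""Co-expression function prediction for lncRNAs (guilt by association).

Pearson correlation is computed between every lncRNA and every
protein-coding gene over an FPKM expression matrix; two-sided p-values
come from the t statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom and are adjusted with the Benjamini-Hochberg FDR over the full
family of pairs.  Significant partners (default q < 0.05, |r| >= 0.7)
feed a hypergeometric GO enrichment with Bonferroni and BH corrections,
where the population is the set of GO-annotated genes present in the
matrix.  Also here: the FPKM definition and the containment rule that
counts a small-RNA read for a gene only when the read lies entirely
inside the annotated gene region on the same strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GenomeInterval

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_R_THRESHOLD = 0.7


def compute_fpkm(
    fragment_count: float, transcript_length_nt: int,
    total_mapped_fragments: int,
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length_nt <= 0 or total_mapped_fragments <= 0:
        raise ValueError("transcript length and library size must be positive")
    if fragment_count < 0:
        raise ValueError("fragment count must be non-negative")
    return fragment_count * 1e9 / (transcript_length_nt * total_mapped_fragments)


class PearsonResult(NamedTuple):
    r: Optional[float]
    p: Optional[float]
    undefined: bool


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson r with a two-sided t-distribution p-value.

    Returns an explicit undefined flag (rather than NaN) when either
    vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(None, None, True)
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p), False)


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment min(1, p*m)."""
    p = _check_pvalues(p_values)
    return np.minimum(1.0, p * p.size)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the population, K carrying the annotation, n drawn
    (the co-expressed set), k of the drawn carrying it.
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"inconsistent parameters k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class CorrelationEdge:
    lnc_id: str
    coding_id: str
    r: float
    p: float
    q: float


@dataclass(frozen=True)
class EnrichmentRow:
    go_term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_bonferroni: float
    q: float


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: rows = features, header = sample names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample names")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite expression values")
    return df


def build_coexpression(
    lnc_rows: Sequence[str],
    coding_rows: Sequence[str],
    matrix: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    positive_only: bool = False,
) -> list[CorrelationEdge]:
    """Score all lncRNA x coding pairs and keep significant edges.

    BH is applied over the full family of testable pairs; edges are kept
    where q < q_threshold and |r| >= r_threshold (r >= r_threshold with
    ``positive_only``).  Constant rows are skipped with a warning.
    """
    missing = (set(lnc_rows) | set(coding_rows)) - set(matrix.index)
    if missing:
        raise KeyError(f"rows not in matrix: {sorted(missing)[:5]}")

    def usable(ids: Sequence[str]) -> list[str]:
        out = []
        for rid in ids:
            if np.ptp(matrix.loc[rid].to_numpy(dtype=float)) == 0:
                logger.warning("constant expression row %r skipped", rid)
            else:
                out.append(rid)
        return out

    lnc_use, coding_use = usable(lnc_rows), usable(coding_rows)
    if not lnc_use or not coding_use:
        return []

    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    lnc_m = matrix.loc[lnc_use].to_numpy(dtype=float)
    cod_m = matrix.loc[coding_use].to_numpy(dtype=float)

    # vectorised product-moment correlations between the two blocks
    lnc_z = (lnc_m - lnc_m.mean(axis=1, keepdims=True))
    cod_z = (cod_m - cod_m.mean(axis=1, keepdims=True))
    lnc_z /= np.linalg.norm(lnc_z, axis=1, keepdims=True)
    cod_z /= np.linalg.norm(cod_z, axis=1, keepdims=True)
    r_mat = np.clip(lnc_z @ cod_z.T, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = r_mat * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r_mat**2))
    p_mat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_mat = np.minimum(1.0, p_mat)

    q_flat = bh_fdr(p_mat.ravel())
    q_mat = q_flat.reshape(p_mat.shape)

    edges = []
    for i, lnc in enumerate(lnc_use):
        for j, cod in enumerate(coding_use):
            r = float(r_mat[i, j])
            keep_r = r >= r_threshold if positive_only else abs(r) >= r_threshold
            if keep_r and q_mat[i, j] < q_threshold:
                edges.append(CorrelationEdge(lnc, cod, r,
                                             float(p_mat[i, j]),
                                             float(q_mat[i, j])))
    edges.sort(key=lambda e: (e.q, e.p, e.lnc_id, e.coding_id))
    return edges


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Gene -> GO-term sets from a TSV (gene_id, go_term[, namespace])."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or \
                    line.lower().startswith("gene_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def go_enrichment(
    partner_ids: Sequence[str],
    go_annotation: Mapping[str, set[str]],
    population_ids: Sequence[str],
) -> list[EnrichmentRow]:
    """Hypergeometric GO enrichment of a co-expressed partner set.

    Population N = GO-annotated genes among ``population_ids``.  One row
    per term present in the population; Bonferroni and BH corrections
    are computed over the per-term family; rows sorted by p (term id on
    ties).
    """
    if not set(partner_ids) <= set(population_ids):
        raise ValueError("partner_ids must be a subset of population_ids")
    population = [g for g in dict.fromkeys(population_ids) if go_annotation.get(g)]
    partners = [g for g in dict.fromkeys(partner_ids) if go_annotation.get(g)]
    if not partners:
        logger.warning("no GO-annotated partners; empty enrichment result")
        return []
    N, n = len(population), len(partners)

    term_pop: dict[str, int] = {}
    for g in population:
        for term in go_annotation[g]:
            term_pop[term] = term_pop.get(term, 0) + 1
    term_hit: dict[str, int] = {}
    for g in partners:
        for term in go_annotation[g]:
            term_hit[term] = term_hit.get(term, 0) + 1

    terms = sorted(term_pop)
    pvals = [
        hypergeom_upper_tail(term_hit.get(t, 0), term_pop[t], n, N)
        for t in terms
    ]
    p_bonf = bonferroni(pvals)
    q = bh_fdr(pvals)
    rows = [
        EnrichmentRow(t, term_hit.get(t, 0), term_pop[t], n, N,
                      float(p), float(pb), float(qq))
        for t, p, pb, qq in zip(terms, pvals, p_bonf, q)
    ]
    rows.sort(key=lambda r: (r.p, r.go_term))
    return rows


def assign_reads_to_genes(
    read_intervals: Sequence[GenomeInterval],
    gene_intervals: Sequence[tuple[GenomeInterval, str]],
) -> dict[str, int]:
    """Count reads perfectly located inside annotated gene regions.

    A read counts for a gene only when the read interval is fully
    contained in the gene interval on the same strand; a read contained
    in several genes counts once per containing gene.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    counts = {gid: 0 for _, gid in gene_intervals}
    for iv, gid in gene_intervals:
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
            iv.start, iv.end, (iv, gid))
    for read in read_intervals:
        tree = trees.get((read.chrom, read.strand))
        if tree is None:
            continue
        for hit in tree.overlap(read.start, read.end):
            gene_iv, gid = hit.data
            if gene_iv.start <= read.start and read.end <= gene_iv.end:
                counts[gid] += 1
    return counts


def predict_function(
    target_lnc: str,
    matrix: pd.DataFrame,
    coding_rows: Sequence[str],
    go_annotation: Mapping[str, set[str]],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    positive_only: bool = False,
) -> tuple[list[CorrelationEdge], list[EnrichmentRow]]:
    """lncFunction: edges for one target lncRNA, then GO enrichment."""
    if target_lnc not in matrix.index:
        raise KeyError(f"target {target_lnc!r} not in expression matrix")
    edges = build_coexpression([target_lnc], coding_rows, matrix,
                               q_threshold, r_threshold, positive_only)
    partners = [e.coding_id for e in edges]
    population = [g for g in coding_rows if g in matrix.index]
    enrichment = go_enrichment(partners, go_annotation, population)
    return edges, enrichment


def write_edge_table(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tcoding_id\tr\tp\tq\n")
        for e in edges:
            fh.write(f"{e.lnc_id}\t{e.coding_id}\t{e.r:.6f}\t"
                     f"{e.p:.6g}\t{e.q:.6g}\n")


def write_enrichment_table(rows: Iterable[EnrichmentRow],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("go_term\tk\tK\tn\tN\tp\tp_bonferroni\tq\n")
        for r in rows:
            fh.write(f"{r.go_term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.p_bonferroni:.6g}\t{r.q:.6g}\n")
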
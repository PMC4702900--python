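"""Clustering of transcripts into gene loci and A-B-C name assignment.

Two transcripts belong to the same gene locus when they are connected,
transitively, by same-strand exonic overlap of at least 1 nt (the
standard Cufflinks-style locus notion).  Names follow the three-part
scheme ``<species>-lncRNA<gene>-<transcript>``: e.g. hsa-lncRNA10932-8
is the 8th transcript of gene lncRNA10932 in human.  Gene numbers are
assigned genome-wide by leftmost position; transcript numbers are
1-based within a gene by (start, end, transcript_id).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .models import TranscriptModel

_NAME_RE = re.compile(r"^([a-z]{3})-lncRNA(\d+)-(\d+)$")
_SPECIES_RE = re.compile(r"^[a-z]{3}$")


@dataclass(frozen=True)
class LncRnaName:
    species_code: str
    gene_number: int
    transcript_number: int

    def __post_init__(self) -> None:
        if not _SPECIES_RE.match(self.species_code):
            raise ValueError(f"invalid species code {self.species_code!r}")
        if self.gene_number < 1 or self.transcript_number < 1:
            raise ValueError("gene and transcript numbers are 1-based")

    def render(self) -> str:
        return (f"{self.species_code}-lncRNA{self.gene_number}"
                f"-{self.transcript_number}")

    @property
    def gene_name(self) -> str:
        return f"{self.species_code}-lncRNA{self.gene_number}"

    @classmethod
    def parse(cls, text: str) -> "LncRnaName":
        m = _NAME_RE.match(text)
        if not m:
            raise ValueError(f"not a valid lncRNA name: {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


def cluster_into_genes(models: Sequence[TranscriptModel]) -> dict[str, int]:
    """Map transcript_id -> 1-based gene index.

    Connected components of the same-strand exonic-overlap graph, found
    by a sweep over exons within each (chrom, strand); gene indices are
    assigned by the leftmost genomic position of each component
    (ties broken by chrom, then smallest member id).
    """
    uf = _UnionFind(m.transcript_id for m in models)
    exons = sorted(
        ((e.chrom, e.strand, e.start, e.end, m.transcript_id)
         for m in models for e in m.exons),
    )
    cur_key = None
    cur_end = -1
    cur_rep = ""
    for chrom, strand, start, end, tx_id in exons:
        key = (chrom, strand)
        if key != cur_key or start >= cur_end:
            cur_key, cur_rep, cur_end = key, tx_id, end
        else:
            uf.union(cur_rep, tx_id)
            cur_end = max(cur_end, end)

    by_tx = {m.transcript_id: m for m in models}
    components: dict[str, list[str]] = {}
    for m in models:
        components.setdefault(uf.find(m.transcript_id), []).append(
            m.transcript_id)

    def component_key(member_ids: list[str]) -> tuple:
        starts = [(by_tx[t].chrom, by_tx[t].start) for t in member_ids]
        chrom, start = min(starts)
        return (chrom, start, min(member_ids))

    ordered = sorted(components.values(), key=component_key)
    gene_of: dict[str, int] = {}
    for gene_idx, member_ids in enumerate(ordered, start=1):
        for tx_id in member_ids:
            gene_of[tx_id] = gene_idx
    return gene_of


def assign_names(
    clusters: Mapping[str, int],
    models: Sequence[TranscriptModel],
    species_code: str,
) -> dict[str, LncRnaName]:
    """Map transcript_id -> LncRnaName given a gene clustering."""
    if not _SPECIES_RE.match(species_code):
        raise ValueError(f"invalid species code {species_code!r}: "
                         "expected three lowercase letters")
    by_tx = {m.transcript_id: m for m in models}
    missing = set(clusters) - set(by_tx)
    if missing:
        raise ValueError(f"clusters reference unknown transcripts {sorted(missing)}")

    by_gene: dict[int, list[TranscriptModel]] = {}
    for tx_id, gene in clusters.items():
        by_gene.setdefault(gene, []).append(by_tx[tx_id])

    names: dict[str, LncRnaName] = {}
    for gene, members in by_gene.items():
        members.sort(key=lambda m: (m.start, m.end, m.transcript_id))
        for tx_num, m in enumerate(members, start=1):
            names[m.transcript_id] = LncRnaName(species_code, gene, tx_num)
    return names


def name_transcripts(
    models: Sequence[TranscriptModel], species_code: str
) -> dict[str, LncRnaName]:
    """Cluster and name in one step."""
    return assign_names(cluster_into_genes(models), models, species_code)


def write_name_table(
    names: Mapping[str, LncRnaName], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tname\tgene_name\n")
        for tx_id in sorted(names):
            n = names[tx_id]
            fh.write(f"{tx_id}\t{n.render()}\t{n.gene_name}\n")
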
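"""Cross-species best-hit conservation of lncRNAs.

Each lncRNA sequence is searched against the lncRNA sets of the other
species (BLASTN, ``-task blastn -word_size 6 -evalue 1e-5 -strand
plus``); for every query and target species, the hit with the lowest
E-value is kept as the most conserved counterpart.  The library works
over parsed tabular hits; the BLASTN invocation itself is an external
adapter configured in the pipeline.  Lineage labelling reduces the
per-species presence pattern to the most specific named clade that
contains every species carrying an ortholog.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domain_filter import HitRecord

BLASTN_PARAMETERS = "-task blastn -word_size 6 -evalue 1e-5 -strand plus"
BLASTN_EVALUE_CUTOFF = 1e-5

SPECIES_SPECIFIC = "species-specific"


@dataclass(frozen=True)
class OrthologCall:
    query_id: str
    target_species: str
    best_subject_id: str
    best_e_value: float


def best_hit_per_query(
    hits: Iterable[HitRecord], target_species: str
) -> list[OrthologCall]:
    """One call per query: the hit with minimal E-value.

    Ties are broken by higher bit score, then lexicographic subject id.
    Queries without hits are simply absent.  Hits are assumed already
    E-value-filtered by the search itself.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    return [
        OrthologCall(q, target_species, best[q].subject_id, best[q].e_value)
        for q in sorted(best)
    ]


def _hit_key(h: HitRecord) -> tuple:
    return (h.e_value, -h.bit_score, h.subject_id)


def best_hits_by_species(
    hits_by_species: Mapping[str, Sequence[HitRecord]]
) -> list[OrthologCall]:
    """Best-hit calls across several target species' hit tables."""
    calls: list[OrthologCall] = []
    for species in sorted(hits_by_species):
        calls.extend(best_hit_per_query(hits_by_species[species], species))
    return calls


def lineage_label(
    query_species: str,
    presence: Mapping[str, bool],
    clades: Mapping[str, frozenset | set],
) -> str:
    """Most specific clade covering the query and all ortholog species.

    ``presence`` maps target species to whether an ortholog was found.
    With no orthologs at all the label is ``species-specific``.  Clades
    are named species sets; specificity = smallest containing set, ties
    broken by name.  A relevant species not covered by any clade is a
    configuration error.
    """
    with_ortholog = {sp for sp, has in presence.items() if has}
    if not with_ortholog:
        return SPECIES_SPECIFIC
    needed = with_ortholog | {query_species}
    covered_by_any = set().union(*clades.values()) if clades else set()
    missing = needed - covered_by_any
    if missing:
        raise ValueError(
            f"species {sorted(missing)} not present in any clade definition"
        )
    candidates = [
        (len(members), name)
        for name, members in clades.items()
        if needed <= set(members)
    ]
    if not candidates:
        raise ValueError(
            f"no single clade contains all of {sorted(needed)}; "
            "clade definitions must cover the species set"
        )
    return min(candidates)[1]


def read_clades(path: str | Path) -> dict[str, frozenset]:
    """Read clade definitions from a key-value file.

    Format: ``name = sp1,sp2,...`` per line; '#' comments allowed.
    """
    clades: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'name = sp,sp'")
            name, members = line.split("=", 1)
            clades[name.strip()] = frozenset(
                s.strip() for s in members.split(",") if s.strip()
            )
    return clades


def write_ortholog_table(
    calls: Iterable[OrthologCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\ttarget_species\tbest_subject_id\tbest_e_value\n")
        for c in calls:
            fh.write(f"{c.query_id}\t{c.target_species}\t"
                     f"{c.best_subject_id}\t{c.best_e_value:.3g}\n")
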
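"""Gene-name universe construction and protein-identifier resolution.

DIA quantification reports an ordered list of candidate identifiers (UniProt
accessions and gene names, ranked by statistical confidence) per quantified
protein. To place proteins into gene-set space, a universe of unique gene
names is compiled from the gene-set collections, and each protein resolves to
the earliest candidate found in that universe — falling back to its top-ranked
candidate when none intersects.

Also provides the Venn partition of proteins across tissues (tissue-specific
vs tissue-shared identifications), which feeds over-representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .containers import GeneSetCollection, IntensityMatrix

__all__ = [
    "IdentifierRecord",
    "Universe",
    "build_universe",
    "resolve_identifier",
    "resolve_all",
    "compute_tissue_overlap",
]


@dataclass(frozen=True)
class IdentifierRecord:
    """Candidate identifiers for one quantified protein, best first."""

    ordered_ids: tuple[str, ...]
    #: generative truth (synthetic data only); None for real records
    true_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.ordered_ids:
            raise ValueError("ordered_ids must be non-empty")


@dataclass(frozen=True)
class Universe:
    """Deduplicated gene-name universe with provenance."""

    names: frozenset[str]
    source: tuple[str, ...] = ()

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


def build_universe(collections: Sequence[GeneSetCollection]) -> Universe:
    """Union of all member gene names across the given collections."""
    if not collections:
        raise ValueError("need at least one gene-set collection")
    names: set[str] = set()
    for coll in collections:
        names |= coll.all_genes()
    if not names:
        raise ValueError("all collections are empty; universe would be empty")
    return Universe(frozenset(names), tuple(c.name for c in collections))


def resolve_identifier(
    rec: IdentifierRecord, universe: Universe, casefold: bool = False
) -> str:
    """Earliest in-universe candidate, else the top-ranked candidate.

    Matching is exact and case-sensitive by default (GMT symbols are
    canonical upper-case); ``casefold=True`` enables case-insensitive
    matching against the universe.
    """
    if casefold:
        lookup = {n.casefold(): n for n in universe.names}
        for cand in rec.ordered_ids:
            hit = lookup.get(cand.casefold())
            if hit is not None:
                return hit
    else:
        for cand in rec.ordered_ids:
            if cand in universe:
                return cand
    return rec.ordered_ids[0]


def resolve_all(
    records: Iterable[IdentifierRecord], universe: Universe, casefold: bool = False
) -> list[str]:
    return [resolve_identifier(r, universe, casefold=casefold) for r in records]


def compute_tissue_overlap(
    matrices: Mapping[str, IntensityMatrix]
) -> dict[tuple[str, ...], list[str]]:
    """Full Venn partition of protein identifications across tissues.

    Every protein appearing in at least one tissue is assigned to exactly one
    cell, keyed by the sorted tuple of tissues it was identified in; cells are
    disjoint and their sizes sum to the distinct-protein count.
    """
    if len(matrices) < 2:
        raise ValueError("tissue overlap needs at least two tissues")
    membership: dict[str, list[str]] = {}
    for tissue in sorted(matrices):
        for protein in matrices[tissue].protein_ids:
            membership.setdefault(str(protein), []).append(tissue)
    cells: dict[tuple[str, ...], list[str]] = {}
    for protein, tissues in membership.items():
        cells.setdefault(tuple(tissues), []).append(protein)
    for members in cells.values():
        members.sort()
    return cells


def overlap_cell_sizes(
    cells: Mapping[tuple[str, ...], Sequence[str]]
) -> dict[tuple[str, ...], int]:
    return {cell: len(members) for cell, members in cells.items()}
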
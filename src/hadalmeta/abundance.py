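"""Relative sequence-abundance aggregation from per-read taxonomic assignments.

A read classifier (run upstream) assigns each read a taxonomic lineage, or
leaves it unassigned.  The relative abundance of a taxon at a given rank is

    100 * (assigned reads resolving to that taxon at the rank)
        / (total assigned reads)

The denominator is *all* assigned reads, regardless of whether their lineage
resolves down to the queried rank; reads unresolved at the rank therefore
contribute to the denominator but to no row, so row percentages at a rank may
sum to less than 100 %.  Per-rank renormalization and within-clade
restriction (e.g. percentages within total eukaryotes) are available as
explicit options, never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognized ranks, outermost first, with their lineage-string prefixes.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_PREFIXES: dict[str, str] = {
    "sk": "superkingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

#: Sentinel lineage used for reads the classifier could not assign.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TaxonAssignment:
    """One read's taxonomic assignment.

    ``lineage`` maps rank name to taxon name and may be truncated (e.g. a
    read resolved only to superkingdom).  ``assigned`` is False for
    unclassified reads, whose lineage is empty.
    """

    read_id: str
    lineage: dict[str, str] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return bool(self.lineage)

    def name_at(self, rank: str) -> str | None:
        return self.lineage.get(rank)


@dataclass
class AbundanceTable:
    """Per-taxon read counts and relative abundances at one rank."""

    rank: str
    table: pd.DataFrame  # columns: taxon, count, rel_abundance (percent)
    denominator: int  # total assigned reads

    def __len__(self) -> int:
        return len(self.table)


def parse_lineage(text: str) -> dict[str, str]:
    """Parse a semicolon-delimited, rank-prefixed lineage string.

    ``"sk__Bacteria;p__Proteobacteria"`` -> ``{"superkingdom": "Bacteria",
    "phylum": "Proteobacteria"}``.  The ``unclassified`` sentinel (or an
    empty string) yields an empty lineage.  Fields with unknown rank
    prefixes are tolerated and ignored.
    """
    text = text.strip()
    if not text or text == UNCLASSIFIED:
        return {}
    lineage: dict[str, str] = {}
    for fieldtxt in text.split(";"):
        fieldtxt = fieldtxt.strip()
        if not fieldtxt:
            continue
        if "__" not in fieldtxt:
            continue
        prefix, name = fieldtxt.split("__", 1)
        rank = RANK_PREFIXES.get(prefix)
        if rank and name:
            lineage[rank] = name
    return lineage


def format_lineage(lineage: dict[str, str]) -> str:
    """Inverse of :func:`parse_lineage`; empty lineage -> sentinel."""
    if not lineage:
        return UNCLASSIFIED
    inv = {v: k for k, v in RANK_PREFIXES.items()}
    return ";".join(f"{inv[r]}__{lineage[r]}" for r in RANKS if r in lineage)


def read_assignments_tsv(path) -> list[TaxonAssignment]:
    """Load a read-assignment table (columns: read_id, lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"read_id", "lineage"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns read_id, lineage")
    return [
        TaxonAssignment(read_id=row.read_id, lineage=parse_lineage(row.lineage))
        for row in df.itertuples()
    ]


def summarize_abundance(
    assignments,
    rank: str,
    *,
    within: str | None = None,
    renormalize: bool = False,
) -> AbundanceTable:
    """Aggregate read assignments into an abundance table at ``rank``.

    Parameters
    ----------
    assignments
        Iterable of :class:`TaxonAssignment`.
    rank
        One of :data:`RANKS`.
    within
        Optional clade name; restricts both numerator and denominator to
        assigned reads whose lineage contains this name at any rank
        (e.g. ``within="Eukaryota"`` gives percentages within total
        eukaryotes).
    renormalize
        If True, divide by reads *resolved at the rank* instead of all
        assigned reads (off by default).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    pool = [a for a in assignments if a.assigned]
    if within is not None:
        pool = [a for a in pool if within in a.lineage.values()]
    denominator = len(pool)
    counts: dict[str, int] = {}
    for a in pool:
        name = a.name_at(rank)
        if name is not None:
            counts[name] = counts.get(name, 0) + 1
    if renormalize:
        denominator_eff = sum(counts.values())
    else:
        denominator_eff = denominator
    rows = [
        {
            "taxon": taxon,
            "count": n,
            "rel_abundance": (100.0 * n / denominator_eff) if denominator_eff else 0.0,
        }
        for taxon, n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["taxon", "count", "rel_abundance"])
    return AbundanceTable(rank=rank, table=table, denominator=denominator)


def rank_abundance_report(table: AbundanceTable, top_n: int) -> pd.DataFrame:
    """Rows of ``table`` sorted by descending abundance, truncated to top_n.

    Ties are broken alphabetically by taxon name, so the report is
    deterministic.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = table.table.sort_values(
        ["rel_abundance", "taxon"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(top_n)
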
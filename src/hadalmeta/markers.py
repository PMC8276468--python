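"""Marker-gene hit filtering and alignment trimming/concatenation contracts.

Supports the phylogenetic workflows around conserved marker genes (e.g.
the Caudovirales terminase large subunit, TerL, and universal single-copy
protein sets): filtering homology-search hits at fixed thresholds,
gap-trimming alignment columns, and concatenating per-marker alignments
into a partitioned supermatrix.  Alignment and tree inference themselves
are external.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from Bio import SeqIO

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class MarkerHit:
    """One homology-search hit of a marker against a query ORF."""

    query_id: str
    marker_name: str
    evalue: float
    percent_identity: float
    query_coverage: float  # percent of the query aligned
    aligned_region: tuple[int, int] = (0, 0)  # 0-based half-open
    subject_coverage: float | None = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative E-value")
        for label, v in (("identity", self.percent_identity), ("coverage", self.query_coverage)):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.query_id}: {label} {v} outside [0, 100]")


@dataclass
class AlignmentMatrix:
    """A multiple alignment: equal-length rows of residues/gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def occupancy(self) -> np.ndarray:
        """Fraction of non-gap residues per column."""
        if not self.rows:
            return np.empty(0)
        arr = np.array([list(r) for r in self.rows])
        return np.mean(~np.isin(arr, list(GAP_CHARS)), axis=0)

    @classmethod
    def from_fasta(cls, path) -> "AlignmentMatrix":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)

    def select_columns(self, cols) -> "AlignmentMatrix":
        cols = list(cols)
        return AlignmentMatrix(
            list(self.ids), ["".join(r[c] for c in cols) for r in self.rows]
        )


def load_marker_roster(name: str = "universal_single_copy_markers") -> list[str]:
    """Load a shipped marker roster ('universal_single_copy_markers' or
    'ribosomal_proteins_15')."""
    text = (resources.files("hadalmeta.data") / f"{name}.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def filter_marker_hits(
    hits,
    max_evalue: float = 1e-5,
    min_identity: float = 50.0,
    min_coverage: float = 30.0,
    *,
    coverage_mode: str = "query",
) -> list[MarkerHit]:
    """Filter marker hits and keep the best hit per query.

    Keep iff E-value <= max_evalue AND identity >= min_identity AND
    coverage >= min_coverage (all inclusive).  Coverage is query coverage
    by default; ``coverage_mode="subject"`` uses subject coverage where
    recorded.  Best hit per query: lowest E-value, then highest identity.
    """
    if coverage_mode not in ("query", "subject"):
        raise ValueError("coverage_mode must be 'query' or 'subject'")
    kept: dict[str, MarkerHit] = {}
    for hit in hits:
        cov = hit.query_coverage
        if coverage_mode == "subject":
            if hit.subject_coverage is None:
                raise ValueError(f"{hit.query_id}: no subject coverage recorded")
            cov = hit.subject_coverage
        if hit.evalue > max_evalue or hit.percent_identity < min_identity or cov < min_coverage:
            continue
        prev = kept.get(hit.query_id)
        if prev is None or (hit.evalue, -hit.percent_identity) < (
            prev.evalue, -prev.percent_identity
        ):
            kept[hit.query_id] = hit
    return [kept[q] for q in sorted(kept)]


def read_marker_hits_tsv(path) -> list[MarkerHit]:
    """Load marker hits from a tabular file (query_id, marker_name,
    evalue, percent_identity, query_coverage[, qstart, qend])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"query_id", "marker_name", "evalue", "percent_identity", "query_coverage"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    hits = []
    for i, row in enumerate(df.itertuples()):
        try:
            region = (
                (int(row.qstart), int(row.qend))
                if {"qstart", "qend"}.issubset(df.columns)
                else (0, 0)
            )
            hits.append(
                MarkerHit(
                    query_id=str(row.query_id),
                    marker_name=str(row.marker_name),
                    evalue=float(row.evalue),
                    percent_identity=float(row.percent_identity),
                    query_coverage=float(row.query_coverage),
                    aligned_region=region,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed hit at row {i}: {exc}") from exc
    return hits


def trim_alignment(
    matrix: AlignmentMatrix, gap_threshold: float = 0.95, conserve: float = 50.0
) -> AlignmentMatrix:
    """Gap-trim alignment columns (TrimAL-style -gt/-cons contract).

    Columns with occupancy (fraction non-gap) >= ``gap_threshold`` are
    kept.  If fewer than ``conserve`` percent of the columns survive, the
    ``conserve`` percent highest-occupancy columns are kept instead (ties
    broken toward the left-most column).  Relative column order is always
    preserved.  The fallback branch, by construction, is not idempotent;
    the threshold branch is.
    """
    if not matrix.rows:
        raise ValueError("empty alignment matrix")
    occ = matrix.occupancy()
    keep = [i for i, o in enumerate(occ) if o >= gap_threshold]
    n_conserve = math.ceil(matrix.width * conserve / 100.0)
    if len(keep) < n_conserve:
        order = sorted(range(matrix.width), key=lambda i: (-occ[i], i))
        keep = sorted(order[:n_conserve])
    return matrix.select_columns(keep)


def concatenate_alignments(
    matrices, roster: list[str]
) -> tuple[AlignmentMatrix, list[tuple[str, int, int]]]:
    """Concatenate per-marker alignments over a genome roster.

    ``matrices`` is an ordered mapping/sequence of (marker name,
    AlignmentMatrix).  Genomes in the roster missing from a marker
    receive an all-gap block; a genome duplicated within one marker is an
    error.  Returns the supermatrix and a partition table of 0-based
    half-open column ranges.
    """
    if hasattr(matrices, "items"):
        matrices = list(matrices.items())
    parts: list[tuple[str, int, int]] = []
    blocks: dict[str, list[str]] = {g: [] for g in roster}
    offset = 0
    for name, matrix in matrices:
        if len(set(matrix.ids)) != len(matrix.ids):
            dupes = sorted({i for i in matrix.ids if matrix.ids.count(i) > 1})
            raise ValueError(f"marker {name!r}: duplicate genome id(s) {dupes}")
        row_of = dict(zip(matrix.ids, matrix.rows))
        width = matrix.width
        for genome in roster:
            blocks[genome].append(row_of.get(genome, "-" * width))
        parts.append((name, offset, offset + width))
        offset += width
    supermatrix = AlignmentMatrix(list(roster), ["".join(blocks[g]) for g in roster])
    return supermatrix, parts


def partition_table_str(partitions, model: str = "LG") -> str:
    """RAxML-style plain-text partition table (1-based inclusive ranges)."""
    return "".join(
        f"{model}, {name} = {start + 1}-{end}\n" for name, start, end in partitions
    )
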
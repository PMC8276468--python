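"""MAG quality filtering and completeness tiering.

Metagenome-assembled genomes (MAGs) are retained when they meet the
medium-quality draft standard used throughout the workflow: completeness of
at least 50 % and contamination of at most 10 %.  Boundaries are inclusive
by default, mirroring tool-level cutoff semantics (``-c 50 -x 10``); a
strict mode (> / <) is available since the draft-standard prose is worded
strictly.  Quality tiers above the filter use strict thresholds
(> 70 %, > 90 % completeness).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class QCRecord:
    """Per-genome quality estimates (from an upstream tool such as CheckM)."""

    genome_id: str
    completeness: float
    contamination: float
    taxonomy: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"{self.genome_id}: contamination {self.contamination} negative"
            )


@dataclass(frozen=True)
class Rejection:
    record: QCRecord
    reason: str  # "completeness" or "contamination"


def read_qc_tsv(path) -> list[QCRecord]:
    """Load a QC table (genome_id, completeness, contamination[, lineage])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"genome_id", "completeness", "contamination"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    records = []
    for i, row in enumerate(df.itertuples()):
        try:
            records.append(
                QCRecord(
                    genome_id=str(row.genome_id),
                    completeness=float(row.completeness),
                    contamination=float(row.contamination),
                    taxonomy=str(row.lineage) if "lineage" in df.columns else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed record at row {i}: {exc}") from exc
    return records


def filter_mags(
    records,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    *,
    strict: bool = False,
) -> tuple[list[QCRecord], list[Rejection]]:
    """Partition records into (kept, rejected-with-reason).

    Default (inclusive): kept iff completeness >= min_completeness and
    contamination <= max_contamination.  ``strict=True`` uses > and <.
    Rejections carry the first failed criterion (completeness checked
    first).
    """
    if not (0.0 <= min_completeness <= 100.0):
        raise ValueError("min_completeness must be in [0, 100]")
    if max_contamination < 0.0:
        raise ValueError("max_contamination must be >= 0")
    kept: list[QCRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        if strict:
            ok_comp = rec.completeness > min_completeness
            ok_cont = rec.contamination < max_contamination
        else:
            ok_comp = rec.completeness >= min_completeness
            ok_cont = rec.contamination <= max_contamination
        if not ok_comp:
            rejected.append(Rejection(rec, "completeness"))
        elif not ok_cont:
            rejected.append(Rejection(rec, "contamination"))
        else:
            kept.append(rec)
    return kept, rejected


def quality_tiers(records) -> dict[str, int]:
    """Count genomes in completeness tiers (strict > 70 / > 90 thresholds).

    Returns ``{"total": ..., "gt70": ..., "gt90": ...}``; counts are
    monotone (gt90 <= gt70 <= total).
    """
    records = list(records)
    return {
        "total": len(records),
        "gt70": sum(1 for r in records if r.completeness > 70.0),
        "gt90": sum(1 for r in records if r.completeness > 90.0),
    }
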
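"""Auxiliary metabolic gene (AMG) flagging and viral functional summaries.

Viral ORFs annotated upstream (eggNOG-style export: COG category, CAZyme
family, orthology id) are screened for host-derived metabolic genes:

* any ORF carrying a CAZyme family assignment is a **carbohydrate** AMG;
* ORFs whose orthology id/symbol appears in the nitrogen/sulfur catalog
  are **nitrogen** or **sulfur** AMGs (defaults: nitrite reductase nirK,
  ATP sulphurylase cysN/nodQ).

An ORF with both kinds of evidence yields one record per kind.  The
module also tallies CAZy classes (GH/PL/CE/GT/AA/CBM) and COG functional
categories across all viral ORFs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CAZY_CLASSES = ("GH", "PL", "CE", "GT", "AA", "CBM")
#: Longest-prefix-first so CBM13 parses as CBM, not CB+M13.
_CAZY_RE = re.compile(r"^(CBM|GH|PL|CE|GT|AA)\d")

UNKNOWN_FUNCTION = "unknown function"


@dataclass(frozen=True)
class AMGRecord:
    orf_id: str
    amg_class: str  # "carbohydrate" | "nitrogen" | "sulfur"
    evidence: str  # the triggering CAZy family or orthology id


def load_ns_catalog(path=None) -> dict[str, str]:
    """Map orthology id/symbol -> "nitrogen"/"sulfur" (shipped default)."""
    if path is None:
        text = (resources.files("hadalmeta.catalogs") / "amg_ns_ko.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    catalog: dict[str, str] = {}
    for cls in ("nitrogen", "sulfur"):
        for ident in doc.get(cls, []) or []:
            catalog[str(ident).lower()] = cls
    if not catalog:
        raise ValueError("empty nitrogen/sulfur AMG catalog")
    return catalog


def read_viral_annotations(path) -> pd.DataFrame:
    """Load a viral ORF annotation table.

    Expected columns: orf_id, cog_category, cazy_family, ko_id,
    description (contig_id optional); missing values read as "".
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "orf_id" not in df.columns:
        raise ValueError(f"{path}: expected an orf_id column")
    for col in ("cog_category", "cazy_family", "ko_id", "description"):
        if col not in df.columns:
            df[col] = ""
    return df


def flag_amgs(
    annotations: pd.DataFrame, ns_ko_catalog: dict[str, str] | None = None
) -> list[AMGRecord]:
    """Flag AMGs among viral ORF annotations.

    One record per (ORF, AMG class); evidence is always a value taken
    verbatim from the input row.
    """
    catalog = ns_ko_catalog if ns_ko_catalog is not None else load_ns_catalog()
    catalog = {k.lower(): v for k, v in catalog.items()}
    records: list[AMGRecord] = []
    for row in annotations.itertuples():
        orf_id = str(row.orf_id)
        cazy = str(getattr(row, "cazy_family", "") or "")
        ko = str(getattr(row, "ko_id", "") or "")
        if cazy:
            records.append(AMGRecord(orf_id, "carbohydrate", cazy))
        if ko and ko.lower() in catalog:
            records.append(AMGRecord(orf_id, catalog[ko.lower()], ko))
    return records


def cazy_class_breakdown(amg_records) -> dict[str, int]:
    """Count carbohydrate AMGs per CAZy class (GH/PL/CE/GT/AA/CBM).

    Families whose prefix is not a recognized class are tallied under
    "other" and logged.
    """
    counts = {cls: 0 for cls in CAZY_CLASSES}
    counts["other"] = 0
    for rec in amg_records:
        if rec.amg_class != "carbohydrate":
            continue
        m = _CAZY_RE.match(rec.evidence)
        if m:
            counts[m.group(1)] += 1
        else:
            counts["other"] += 1
            logger.warning("unrecognized CAZy family %r on %s", rec.evidence, rec.orf_id)
    return counts


def cog_category_summary(annotations: pd.DataFrame) -> dict[str, int]:
    """Count viral ORFs per single-letter COG functional category.

    Multi-letter assignments ("KL") count once per letter; ORFs with no
    COG assignment are tallied under "unknown function".
    """
    counts: dict[str, int] = {}
    unknown = 0
    for row in annotations.itertuples():
        cats = str(getattr(row, "cog_category", "") or "").strip()
        letters = [c for c in cats if c.isalpha()]
        if not letters:
            unknown += 1
            continue
        for letter in letters:
            counts[letter] = counts.get(letter, 0) + 1
    out = dict(sorted(counts.items()))
    out[UNKNOWN_FUNCTION] = unknown
    return out


def amg_table(records) -> pd.DataFrame:
    """AMG records as a table (one row per record)."""
    return pd.DataFrame(
        [
            {"orf_id": r.orf_id, "amg_class": r.amg_class, "evidence": r.evidence}
            for r in records
        ],
        columns=["orf_id", "amg_class", "evidence"],
    )
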
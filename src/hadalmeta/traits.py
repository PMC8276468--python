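"""Pathway module-completeness scoring and metabolic lifestyle classification.

Each genome's annotation is compared against a catalog of pathways, each
defined by a set of key marker genes.  Two quantities are derived:

* **module completeness** — the percentage of a pathway's key genes encoded
  by the genome (e.g. 1 of 4 key genes present scores 25.0);
* **lifestyle flags** — a pathway counts as *present* when at least
  ``min_markers_present`` of its key genes are found (default 1; the CBB
  entry ships with 2 so both rbcS and prkB are required).  Flags then
  follow from pathway categories:

  - heterotroph: any degradation-category pathway present
  - autotroph:   any CO2-fixation pathway present
  - mixotroph:   heterotroph and autotroph
  - aerobic:     aerobic respiration present
  - anaerobic:   any anaerobic-respiration pathway present
  - facultative: aerobic and anaerobic
  - chemolithotroph: per subtype (nitrification, CO oxidation, ...)

The shipped YAML catalogs are the single source of truth for marker
symbols; annotation rows naming unknown markers are ignored (with a logged
count), never guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_DEGRADATION_SUFFIX = "_degradation"
_CO2_PREFIX = "co2_fixation:"
_AEROBIC = "aerobic_respiration"
_ANAEROBIC_PREFIX = "anaerobic:"
_CHEMO_PREFIX = "chemolithotrophy:"


@dataclass(frozen=True)
class PathwayDef:
    """A named pathway/trait: category, key marker genes, presence rule."""

    name: str
    category: str
    key_genes: frozenset[str]
    min_markers_present: int = 1

    def __post_init__(self):
        if not self.key_genes:
            raise ValueError(f"pathway {self.name!r}: key_genes empty")
        if not (1 <= self.min_markers_present <= len(self.key_genes)):
            raise ValueError(
                f"pathway {self.name!r}: min_markers_present "
                f"{self.min_markers_present} outside [1, {len(self.key_genes)}]"
            )

    @property
    def is_degradation(self) -> bool:
        return self.category.endswith(_DEGRADATION_SUFFIX)

    @property
    def is_co2_fixation(self) -> bool:
        return self.category.startswith(_CO2_PREFIX)

    @property
    def is_aerobic(self) -> bool:
        return self.category == _AEROBIC

    @property
    def is_anaerobic(self) -> bool:
        return self.category.startswith(_ANAEROBIC_PREFIX)

    @property
    def chemolithotroph_type(self) -> str | None:
        if self.category.startswith(_CHEMO_PREFIX):
            return self.category[len(_CHEMO_PREFIX):]
        return None


@dataclass
class TraitProfile:
    """Per-genome pathway completeness values and lifestyle calls."""

    genome_id: str
    completeness_by_pathway: dict[str, float]
    present_pathways: frozenset[str]
    heterotroph: bool
    autotroph_any: bool
    mixotroph: bool
    aerobic: bool
    anaerobic: bool
    facultative: bool
    chemolithotroph_by_type: dict[str, bool] = field(default_factory=dict)

    FLAG_NAMES = (
        "heterotroph",
        "autotroph_any",
        "mixotroph",
        "aerobic",
        "anaerobic",
        "facultative",
    )

    def flags(self) -> dict[str, bool]:
        d = {name: getattr(self, name) for name in self.FLAG_NAMES}
        for subtype, val in sorted(self.chemolithotroph_by_type.items()):
            d[f"chemolithotroph:{subtype}"] = val
        return d


def _build_catalog(entries) -> list[PathwayDef]:
    catalog = []
    seen = set()
    for entry in entries:
        if entry["name"] in seen:
            raise ValueError(f"duplicate pathway name {entry['name']!r} in catalog")
        seen.add(entry["name"])
        catalog.append(
            PathwayDef(
                name=str(entry["name"]),
                category=str(entry["category"]),
                key_genes=frozenset(str(g) for g in entry["key_genes"]),
                min_markers_present=int(entry.get("min_markers_present", 1)),
            )
        )
    return catalog


def load_catalog(path) -> list[PathwayDef]:
    """Load a pathway catalog from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "pathways" not in doc or not doc["pathways"]:
        raise ValueError(f"{path}: catalog has no pathways")
    return _build_catalog(doc["pathways"])


def default_catalog(kind: str = "prokaryote") -> list[PathwayDef]:
    """Load a shipped catalog: ``"prokaryote"`` or ``"fungal"``."""
    ref = resources.files("hadalmeta.catalogs") / f"{kind}.yml"
    doc = yaml.safe_load(ref.read_text())
    return _build_catalog(doc["pathways"])


def catalog_markers(catalog) -> dict[str, str]:
    """Map each marker symbol to its (unique) pathway name."""
    out: dict[str, str] = {}
    for pw in catalog:
        for gene in pw.key_genes:
            if gene in out:
                raise ValueError(
                    f"marker {gene!r} appears in both {out[gene]!r} and {pw.name!r}"
                )
            out[gene] = pw.name
    return out


def module_completeness(genes_present, pathway: PathwayDef) -> float:
    """Percentage of the pathway's key genes present, rounded to 2 decimals."""
    present = frozenset(genes_present) & pathway.key_genes
    return round(100.0 * len(present) / len(pathway.key_genes), 2)


def classify_traits(genes_present, catalog, genome_id: str = "") -> TraitProfile:
    """Classify one genome's lifestyle from its marker-gene content.

    ``genes_present`` is an iterable of marker labels found in the genome;
    labels not in the catalog are ignored (count logged at debug level).
    """
    genes = set(str(g) for g in genes_present)
    known = set()
    for pw in catalog:
        known |= pw.key_genes
    unknown = genes - known
    if unknown:
        logger.debug(
            "%s: %d annotation label(s) match no catalog marker", genome_id, len(unknown)
        )

    completeness: dict[str, float] = {}
    present: set[str] = set()
    heterotroph = autotroph = aerobic = anaerobic = False
    chemo: dict[str, bool] = {}
    for pw in catalog:
        completeness[pw.name] = module_completeness(genes, pw)
        n_hit = len(genes & pw.key_genes)
        is_present = n_hit >= pw.min_markers_present
        if is_present:
            present.add(pw.name)
        if pw.is_degradation:
            heterotroph |= is_present
        elif pw.is_co2_fixation:
            autotroph |= is_present
        elif pw.is_aerobic:
            aerobic |= is_present
        elif pw.is_anaerobic:
            anaerobic |= is_present
        subtype = pw.chemolithotroph_type
        if subtype is not None:
            chemo[subtype] = chemo.get(subtype, False) | is_present
    return TraitProfile(
        genome_id=genome_id,
        completeness_by_pathway=completeness,
        present_pathways=frozenset(present),
        heterotroph=heterotroph,
        autotroph_any=autotroph,
        mixotroph=heterotroph and autotroph,
        aerobic=aerobic,
        anaerobic=anaerobic,
        facultative=aerobic and anaerobic,
        chemolithotroph_by_type=chemo,
    )


def classify_annotation_table(
    annotations: pd.DataFrame, catalog, *, genome_col="genome_id", marker_col="marker_label"
) -> list[TraitProfile]:
    """Classify every genome in an annotation table (one row per gene)."""
    profiles = []
    for genome_id, group in annotations.groupby(genome_col, sort=True):
        genes = set(group[marker_col].dropna().astype(str))
        genes.discard("")
        profiles.append(classify_traits(genes, catalog, genome_id=str(genome_id)))
    return profiles


def trait_matrix(
    profiles, taxonomy: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Genome x pathway completeness matrix plus community flag summary.

    Rows are ordered by taxonomy (if given) then genome id.  The summary
    holds, per lifestyle flag, the genome count and the percentage of all
    genomes carrying it.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one trait profile required")
    taxonomy = taxonomy or {}
    profiles.sort(key=lambda p: (taxonomy.get(p.genome_id, ""), p.genome_id))
    matrix = pd.DataFrame(
        [p.completeness_by_pathway for p in profiles],
        index=[p.genome_id for p in profiles],
    )
    matrix.index.name = "genome_id"
    n = len(profiles)
    summary: dict[str, dict] = {"n_genomes": n, "flags": {}}
    flag_names: list[str] = list(profiles[0].flags().keys())
    for p in profiles:
        for name in p.flags():
            if name not in flag_names:
                flag_names.append(name)
    for name in flag_names:
        count = sum(1 for p in profiles if p.flags().get(name, False))
        summary["flags"][name] = {"count": count, "percent": round(100.0 * count / n, 2)}
    return matrix, summary


def flags_table(profiles) -> pd.DataFrame:
    """Boolean flag table, one row per genome (for TSV export)."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.genome_id):
        row = {"genome_id": p.genome_id}
        row.update(p.flags())
        rows.append(row)
    return pd.DataFrame(rows)
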
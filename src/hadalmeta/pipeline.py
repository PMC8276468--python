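"""End-to-end orchestration: abundance -> MAG QC -> traits -> virus-host -> AMG.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) names
the inputs, catalogs and thresholds.  When sequence/table inputs are not
supplied, a seeded synthetic bundle is generated first, so the whole
pipeline is runnable from nothing but a seed.  Every run writes a JSON
manifest (config hash, package version, per-stage row counts); identical
config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

import hadalmeta
from hadalmeta import abundance as ab
from hadalmeta import amg as amg_mod
from hadalmeta import mag_qc, traits, virus_host
from hadalmeta._fasta import read_fasta
from hadalmeta.synthetic_data import SyntheticConfig, generate_bundle, write_bundle

logger = logging.getLogger(__name__)

STAGES = ("abundance", "mag_qc", "traits", "virus_host", "amg")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration with the workflow's documented defaults."""

    seed: int = 42
    output_dir: str = "hadalmeta_run"
    # optional pre-existing inputs; unset ones come from the synthetic bundle
    hosts_fasta: str | None = None
    viruses_fasta: str | None = None
    reads_tsv: str | None = None
    annotations_tsv: str | None = None
    qc_tsv: str | None = None
    blast_tsv: str | None = None
    viral_orfs_tsv: str | None = None
    catalog_yml: str | None = None
    ns_ko_yml: str | None = None
    # thresholds
    rank: str = "phylum"
    top_n: int = 30
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_bitscore: float = 50.0
    max_evalue: float = 0.001
    d_max: float = 0.0015
    min_virus_len: int = 5000
    max_mismatch: int = 2
    marker_max_evalue: float = 1e-5
    marker_min_identity: float = 50.0
    marker_min_coverage: float = 30.0
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        checks = [
            (0 <= self.min_completeness <= 100, "min_completeness"),
            (self.max_contamination >= 0, "max_contamination"),
            (self.max_evalue > 0, "max_evalue"),
            (self.d_max > 0, "d_max"),
            (self.max_mismatch >= 0, "max_mismatch"),
            (self.min_virus_len >= 0, "min_virus_len"),
            (self.top_n >= 1, "top_n"),
            (self.rank in ab.RANKS, "rank"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config field {name!r} outside its documented range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**doc)

    def config_hash(self) -> str:
        # output_dir does not influence results, so two runs of the same
        # analysis into different directories hash (and compare) equal
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _display_path(path, outdir: Path) -> str:
    try:
        return str(Path(path).relative_to(outdir))
    except ValueError:
        return str(path)


def _require(path: str | None, label: str) -> str:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"missing input path for {label}: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    catalog = (
        traits.load_catalog(_require(config.catalog_yml, "catalog_yml"))
        if config.catalog_yml
        else traits.default_catalog()
    )
    ns_catalog = amg_mod.load_ns_catalog(config.ns_ko_yml)

    # Stage 0: materialize inputs (synthetic bundle for anything unset).
    needs_synth = not all(
        (config.hosts_fasta, config.viruses_fasta, config.reads_tsv,
         config.annotations_tsv, config.qc_tsv, config.viral_orfs_tsv)
    )
    paths = {
        "hosts_fasta": config.hosts_fasta,
        "viruses_fasta": config.viruses_fasta,
        "reads_tsv": config.reads_tsv,
        "annotations_tsv": config.annotations_tsv,
        "qc_tsv": config.qc_tsv,
        "viral_orfs_tsv": config.viral_orfs_tsv,
    }
    if needs_synth:
        synth_cfg = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        bundle = generate_bundle(synth_cfg, catalog)
        written = write_bundle(bundle, outdir / "synthetic")
        for key in paths:
            if paths[key] is None:
                paths[key] = written[key]
    for key, value in paths.items():
        _require(value, key)

    manifest = {
        "package": "hadalmeta",
        "version": hadalmeta.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(STAGES),
        "inputs": {k: _display_path(v, outdir) for k, v in sorted(paths.items())},
    }

    # Stage 1: abundance
    try:
        assignments = ab.read_assignments_tsv(paths["reads_tsv"])
        table = ab.summarize_abundance(assignments, config.rank)
        report = ab.rank_abundance_report(table, config.top_n)
        (outdir / "abundance").mkdir(exist_ok=True)
        table.table.to_csv(outdir / "abundance" / f"{config.rank}_abundance.tsv",
                           sep="\t", index=False, float_format="%.6f")
        report.to_csv(outdir / "abundance" / f"{config.rank}_top{config.top_n}.tsv",
                      sep="\t", index=False, float_format="%.6f")
        counts["abundance"] = len(table)
    except Exception as exc:
        raise StageError("abundance", exc) from exc

    # Stage 2: MAG QC
    try:
        qc_records = mag_qc.read_qc_tsv(paths["qc_tsv"])
        kept, rejected = mag_qc.filter_mags(
            qc_records, config.min_completeness, config.max_contamination
        )
        tiers = mag_qc.quality_tiers(kept)
        (outdir / "magqc").mkdir(exist_ok=True)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in kept]
        ).to_csv(outdir / "magqc" / "kept.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"genome_id": r.record.genome_id, "reason": r.reason} for r in rejected]
        ).to_csv(outdir / "magqc" / "rejected.tsv", sep="\t", index=False)
        (outdir / "magqc" / "summary.json").write_text(
            json.dumps({"kept": len(kept), "rejected": len(rejected), "tiers": tiers},
                       indent=1, sort_keys=True)
        )
        counts["mag_qc"] = len(qc_records)
    except Exception as exc:
        raise StageError("mag_qc", exc) from exc

    # Stage 3: traits
    try:
        ann = pd.read_csv(paths["annotations_tsv"], sep="\t", dtype=str).fillna("")
        profiles = traits.classify_annotation_table(ann, catalog)
        matrix, summary = traits.trait_matrix(profiles)
        (outdir / "traits").mkdir(exist_ok=True)
        matrix.to_csv(outdir / "traits" / "completeness_matrix.tsv", sep="\t",
                      float_format="%.2f")
        traits.flags_table(profiles).to_csv(outdir / "traits" / "flags.tsv",
                                            sep="\t", index=False)
        (outdir / "traits" / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        counts["traits"] = len(profiles)
    except Exception as exc:
        raise StageError("traits", exc) from exc

    # Stage 4: virus-host association
    try:
        hosts = read_fasta(paths["hosts_fasta"])
        viruses = read_fasta(paths["viruses_fasta"])
        edges = []
        if config.blast_tsv:
            blast = virus_host.read_blast_tab(_require(config.blast_tsv, "blast_tsv"))
        else:
            blast = virus_host.exact_substring_hits(viruses, hosts)
        edges += virus_host.filter_similarity_links(
            blast, config.min_bitscore, config.max_evalue
        )
        spacers = virus_host.detect_spacers(hosts)
        edges += virus_host.match_spacers(spacers, viruses, config.max_mismatch)
        edges += virus_host.assign_by_composition(
            viruses, hosts, config.d_max, config.min_virus_len
        )
        graph, net_summary = virus_host.build_network(edges)
        (outdir / "virus_host").mkdir(exist_ok=True)
        virus_host.edges_to_frame(edges).to_csv(
            outdir / "virus_host" / "edges.tsv", sep="\t", index=False
        )
        nx.write_graphml(graph, outdir / "virus_host" / "network.graphml")
        nx.to_pandas_edgelist(graph).to_csv(
            outdir / "virus_host" / "network_edges.tsv", sep="\t", index=False
        )
        (outdir / "virus_host" / "summary.json").write_text(
            json.dumps(net_summary, indent=1, sort_keys=True)
        )
        counts["virus_host"] = len(edges)
    except Exception as exc:
        raise StageError("virus_host", exc) from exc

    # Stage 5: AMG flagging
    try:
        orfs = amg_mod.read_viral_annotations(paths["viral_orfs_tsv"])
        records = amg_mod.flag_amgs(orfs, ns_catalog)
        (outdir / "amg").mkdir(exist_ok=True)
        amg_mod.amg_table(records).to_csv(outdir / "amg" / "amg.tsv", sep="\t", index=False)
        (outdir / "amg" / "summary.json").write_text(
            json.dumps(
                {
                    "n_amgs": len(records),
                    "cazy_classes": amg_mod.cazy_class_breakdown(records),
                    "cog_categories": amg_mod.cog_category_summary(orfs),
                },
                indent=1, sort_keys=True,
            )
        )
        counts["amg"] = len(records)
    except Exception as exc:
        raise StageError("amg", exc) from exc

    manifest["row_counts"] = counts
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
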
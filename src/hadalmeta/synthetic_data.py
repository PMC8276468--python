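"""Seeded synthetic metagenomes with a known ground-truth manifest.

Real hadal-sediment raw data are hundreds of gigabases and live in public
archives; every downstream stage here is instead exercised on generated
communities whose truth is known exactly:

* **hosts** — each genome is sampled from its own order-``markov_order``
  nucleotide chain whose transition rows are independent Dirichlet draws,
  giving hosts distinct, separable tetranucleotide signatures;
* **prophages** — viral contigs copied verbatim from a source host
  (guaranteeing a similarity link and a small composition distance), plus
  decoy viruses sampled from a chain fitted to the pooled hosts
  (compositionally near, but linked to nobody);
* **CRISPR arrays** — repeat-spacer-repeat arrays (28 bp repeats, 3
  repeats / 2 spacers) inserted into hosts, each spacer copied from a
  random virus window and optionally mutated;
* **annotations** — per-genome marker-gene tables emitting exactly the
  genes a planted lifestyle requires, plus non-marker noise;
* **read assignments** — multinomial draws from a Dirichlet community
  abundance vector, with a seeded unassigned fraction.

Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hadalmeta.abundance import UNCLASSIFIED
from hadalmeta.traits import PathwayDef

_BASES = "ACGT"

#: Fixed community template the default abundance vector is drawn over
#: (rank-prefixed lineages echoing dominant hadal-sediment groups).
COMMUNITY_LINEAGES: tuple[str, ...] = (
    "sk__Bacteria;p__Proteobacteria;c__Gammaproteobacteria",
    "sk__Bacteria;p__Proteobacteria;c__Alphaproteobacteria",
    "sk__Bacteria;p__Chloroflexi;c__Dehalococcoidia",
    "sk__Bacteria;p__Actinobacteria;c__Actinomycetia",
    "sk__Bacteria;p__Planctomycetes;c__Planctomycetia",
    "sk__Bacteria;p__Firmicutes;c__Bacilli",
    "sk__Bacteria;p__Bacteroidetes;c__Bacteroidia",
    "sk__Archaea;p__Thaumarchaeota;c__Nitrososphaeria",
    "sk__Eukaryota;p__Ascomycota;c__Sordariomycetes",
    "sk__Eukaryota;p__Basidiomycota;c__Agaricomycetes",
    "sk__Viruses;p__Uroviricota;c__Caudoviricetes",
)

CRISPR_REPEAT_LEN = 28
SPACERS_PER_ARRAY = 2  # 3 repeats / 2 spacers


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic community; defaults are the benchmark
    conditions (5 hosts x 50 kb, 2 prophages each, 30 bp exact spacers)."""

    seed: int = 42
    n_hosts: int = 5
    host_length: int = 50_000
    markov_order: int = 3
    n_prophages_per_host: int = 2
    prophage_length_range: tuple[int, int] = (8_000, 12_000)
    n_spacer_arrays: int = 5
    spacer_length: int = 30
    spacer_mismatch_rate: float = 0.0
    n_reads: int = 100_000
    unassigned_fraction: float = 0.1
    abundance_concentration: float = 5.0
    composition_alpha: float = 1.0  # per-row Dirichlet alpha; lower = more distinct
    n_decoys: int = 3

    def __post_init__(self):
        for name in ("n_hosts", "host_length", "markov_order", "n_prophages_per_host",
                     "n_spacer_arrays", "spacer_length", "n_reads", "n_decoys"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = self.prophage_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"prophage_length_range must be ordered positive, got {(lo, hi)}")
        for name in ("spacer_mismatch_rate", "unassigned_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        if self.abundance_concentration <= 0:
            raise ValueError("abundance_concentration must be > 0")
        if self.composition_alpha <= 0:
            raise ValueError("composition_alpha must be > 0")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent, reproducibly derived RNG streams per component."""
        names = ("hosts", "prophages", "crispr", "annotations",
                 "reads", "community", "qc", "viral_orfs")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class GenomeRecord:
    """A host genome/MAG: id plus one or more contig sequences."""

    genome_id: str
    sequences: list[tuple[str, str]]  # (contig name, sequence)
    taxonomy: str | None = None

    def concatenated(self) -> str:
        return "".join(seq for _, seq in self.sequences)


@dataclass
class ViralContig:
    contig_id: str
    sequence: str
    family: str | None = None


@dataclass
class TruthManifest:
    """Ground truth recorded while generating the synthetic community."""

    prophage_links: set[tuple[str, str]] = field(default_factory=set)
    spacer_links: set[tuple[str, str, int]] = field(default_factory=set)
    trait_labels: dict[str, dict[str, bool]] = field(default_factory=dict)
    abundance_vector: dict[str, float] = field(default_factory=dict)
    composition_models: dict[str, list] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "prophage_links": sorted(list(t) for t in self.prophage_links),
                "spacer_links": sorted(list(t) for t in self.spacer_links),
                "trait_labels": {k: self.trait_labels[k] for k in sorted(self.trait_labels)},
                "abundance_vector": {k: self.abundance_vector[k] for k in sorted(self.abundance_vector)},
                "composition_models": {k: self.composition_models[k] for k in sorted(self.composition_models)},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        doc = json.loads(text)
        return cls(
            prophage_links={tuple(t) for t in doc["prophage_links"]},
            spacer_links={(t[0], t[1], int(t[2])) for t in doc["spacer_links"]},
            trait_labels=doc["trait_labels"],
            abundance_vector=doc["abundance_vector"],
            composition_models=doc["composition_models"],
        )


# --- host genomes ---------------------------------------------------------

def _sample_chain(rng: np.random.Generator, transitions: np.ndarray, length: int) -> str:
    """Emit ``length`` bases from an order-k chain (transitions: 4^k x 4)."""
    n_ctx = transitions.shape[0]
    cum = np.cumsum(transitions, axis=1)
    state = int(rng.integers(n_ctx))
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    for i in range(length):
        c = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = min(c, 3)
        state = (state * 4 + out[i]) % n_ctx
    return "".join(_BASES[c] for c in out)


def generate_host_genomes(config: SyntheticConfig):
    """Generate hosts, each from its own Dirichlet-perturbed chain.

    Returns (list of GenomeRecord, composition_models) where the models
    map host id to its 4^order x 4 transition table.
    """
    if config.n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    if config.host_length < 4:
        raise ValueError("host_length must be >= 4")
    rng = config.rngs()["hosts"]
    n_ctx = 4**config.markov_order
    hosts: list[GenomeRecord] = []
    models: dict[str, list] = {}
    for i in range(config.n_hosts):
        hid = f"host_{i + 1:03d}"
        transitions = rng.dirichlet(
            np.full(4, config.composition_alpha), size=n_ctx
        )
        seq = _sample_chain(rng, transitions, config.host_length)
        hosts.append(GenomeRecord(hid, [(hid, seq)]))
        models[hid] = transitions.round(8).tolist()
    return hosts, models


def _fit_chain(sequences, order: int) -> np.ndarray:
    """Max-likelihood order-k transition table (with +1 pseudocounts)."""
    n_ctx = 4**order
    counts = np.ones((n_ctx, 4))
    code = {b: i for i, b in enumerate(_BASES)}
    for seq in sequences:
        state = 0
        for j, ch in enumerate(seq):
            c = code[ch]
            if j >= order:
                counts[state, c] += 1
            state = (state * 4 + c) % n_ctx
    return counts / counts.sum(axis=1, keepdims=True)


# --- prophages and decoys -------------------------------------------------

def plant_prophages(hosts, config: SyntheticConfig):
    """Copy prophage windows out of hosts; emit unlinked decoy viruses.

    Each prophage is a verbatim subsequence of its source host.  Decoys
    are sampled from a chain fitted to the pooled hosts, so they sit
    compositionally near the community without belonging to any host.
    Returns (list of ViralContig, prophage_links).
    """
    rng = config.rngs()["prophages"]
    lo, hi = config.prophage_length_range
    viruses: list[ViralContig] = []
    links: set[tuple[str, str]] = set()
    for host in hosts:
        seq = host.concatenated()
        if config.n_prophages_per_host and len(seq) < hi:
            raise ValueError(
                f"{host.genome_id}: host length {len(seq)} shorter than the "
                f"largest requested prophage ({hi} bp)"
            )
        for p in range(config.n_prophages_per_host):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(seq) - length + 1))
            vid = f"virus_{host.genome_id}_p{p + 1}"
            viruses.append(ViralContig(vid, seq[start : start + length]))
            links.add((vid, host.genome_id))
    pooled = _fit_chain([h.concatenated() for h in hosts], config.markov_order)
    for d in range(config.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        viruses.append(ViralContig(f"decoy_{d + 1:02d}", _sample_chain(rng, pooled, length)))
    return viruses, links


# --- CRISPR arrays --------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[c] for c in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each position independently with probability ``rate``."""
    if rate <= 0:
        return seq, 0
    flags = rng.random(len(seq)) < rate
    chars = list(seq)
    for i in np.flatnonzero(flags):
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars), int(flags.sum())


def plant_crispr_arrays(hosts, viruses, config: SyntheticConfig):
    """Insert repeat-spacer-repeat arrays whose spacers copy virus windows.

    Arrays use a fixed random 28 bp repeat (per array, 3 copies) around
    spacers of ``spacer_length`` copied from random virus windows and
    mutated per ``spacer_mismatch_rate``.  Returns (modified hosts,
    spacer_links) where links record (virus, host, mismatch count).
    Hosts are returned unchanged (same objects) when no arrays are
    requested.
    """
    if config.n_spacer_arrays == 0:
        return hosts, set()
    if not viruses:
        raise ValueError("no viruses available to source CRISPR spacers from")
    shortest = min(len(v.sequence) for v in viruses)
    if config.spacer_length > shortest:
        raise ValueError(
            f"spacer_length {config.spacer_length} exceeds shortest virus ({shortest} bp)"
        )
    rng = config.rngs()["crispr"]
    new_seqs = {h.genome_id: h.concatenated() for h in hosts}
    links: set[tuple[str, str, int]] = set()
    host_ids = [h.genome_id for h in hosts]
    for a in range(config.n_spacer_arrays):
        hid = host_ids[a % len(host_ids)]
        repeat = _random_seq(rng, CRISPR_REPEAT_LEN)
        parts = [repeat]
        for _ in range(SPACERS_PER_ARRAY):
            virus = viruses[int(rng.integers(len(viruses)))]
            start = int(rng.integers(0, len(virus.sequence) - config.spacer_length + 1))
            window = virus.sequence[start : start + config.spacer_length]
            spacer, n_mut = _mutate(rng, window, config.spacer_mismatch_rate)
            parts.extend([spacer, repeat])
            links.add((virus.contig_id, hid, n_mut))
        array = "".join(parts)
        seq = new_seqs[hid]
        at = int(rng.integers(0, len(seq) + 1))
        new_seqs[hid] = seq[:at] + array + seq[at:]
    out = [
        GenomeRecord(h.genome_id, [(h.genome_id, new_seqs[h.genome_id])], h.taxonomy)
        for h in hosts
    ]
    return out, links


# --- annotation tables ----------------------------------------------------

_LIFESTYLE_PROBS = {
    "heterotroph": 0.8,
    "autotroph": 0.4,
    "aerobic": 0.85,
    "anaerobic": 0.8,
    "chemolithotroph": 0.5,
}


def generate_annotation_tables(pathway_catalog, config: SyntheticConfig):
    """Plant a lifestyle per genome and emit exactly its required markers.

    For each genome a lifestyle is drawn (heterotroph / autotroph /
    aerobic / anaerobic / chemolithotroph flags, independently); for each
    chosen trait one pathway of that category is picked and
    ``min_markers_present`` of its key genes are emitted, plus non-marker
    noise genes.  Returns (annotation DataFrame, trait_labels).
    """
    catalog = list(pathway_catalog)
    if not catalog:
        raise ValueError("pathway catalog is empty")
    names = [p.name for p in catalog]
    if len(set(names)) != len(names):
        raise ValueError("catalog contains duplicate pathway names")
    by_kind: dict[str, list[PathwayDef]] = {
        "heterotroph": [p for p in catalog if p.is_degradation],
        "autotroph": [p for p in catalog if p.is_co2_fixation],
        "aerobic": [p for p in catalog if p.is_aerobic],
        "anaerobic": [p for p in catalog if p.is_anaerobic],
        "chemolithotroph": [p for p in catalog if p.chemolithotroph_type],
    }
    chemo_subtypes = sorted({p.chemolithotroph_type for p in by_kind["chemolithotroph"]})
    rng = config.rngs()["annotations"]
    rows = []
    labels: dict[str, dict[str, bool]] = {}
    for i in range(config.n_hosts):
        gid = f"host_{i + 1:03d}"
        chosen: dict[str, PathwayDef | None] = {}
        for kind, prob in _LIFESTYLE_PROBS.items():
            pool = by_kind[kind]
            if pool and rng.random() < prob:
                chosen[kind] = pool[int(rng.integers(len(pool)))]
            else:
                chosen[kind] = None
        genes: list[str] = []
        for pw in chosen.values():
            if pw is None:
                continue
            keys = sorted(pw.key_genes)
            picks = rng.choice(len(keys), size=pw.min_markers_present, replace=False)
            genes.extend(keys[j] for j in sorted(picks))
        n_noise = int(rng.integers(2, 6))
        genes.extend(f"hyp_{int(rng.integers(10_000)):04d}" for _ in range(n_noise))
        for g_i, gene in enumerate(genes):
            rows.append(
                {
                    "genome_id": gid,
                    "gene_id": f"{gid}_g{g_i + 1:03d}",
                    "marker_label": gene,
                    "cazy_family": gene if gene in {"GH", "PL", "CE", "GT", "AA", "CBM"} else "",
                    "peptidase_family": "",
                    "ko_like_id": "",
                }
            )
        flags = {
            "heterotroph": chosen["heterotroph"] is not None,
            "autotroph_any": chosen["autotroph"] is not None,
            "aerobic": chosen["aerobic"] is not None,
            "anaerobic": chosen["anaerobic"] is not None,
        }
        flags["mixotroph"] = flags["heterotroph"] and flags["autotroph_any"]
        flags["facultative"] = flags["aerobic"] and flags["anaerobic"]
        picked_chemo = chosen["chemolithotroph"]
        for subtype in chemo_subtypes:
            flags[f"chemolithotroph:{subtype}"] = (
                picked_chemo is not None and picked_chemo.chemolithotroph_type == subtype
            )
        labels[gid] = flags
    table = pd.DataFrame(
        rows,
        columns=["genome_id", "gene_id", "marker_label",
                 "cazy_family", "peptidase_family", "ko_like_id"],
    )
    return table, labels


# --- read assignments -----------------------------------------------------

def default_community(config: SyntheticConfig) -> dict[str, float]:
    """Dirichlet-drawn relative abundances over the community template."""
    rng = config.rngs()["community"]
    probs = rng.dirichlet(
        np.full(len(COMMUNITY_LINEAGES), config.abundance_concentration)
    )
    return {lin: float(p) for lin, p in zip(COMMUNITY_LINEAGES, probs)}


def generate_read_assignments(
    abundance_vector: dict[str, float], config: SyntheticConfig
) -> pd.DataFrame:
    """Assign ``n_reads`` reads multinomially per the abundance vector.

    A seeded ``unassigned_fraction`` of reads carries the explicit
    ``unclassified`` sentinel.  Returns a DataFrame (read_id, lineage).
    """
    taxa = sorted(abundance_vector)
    probs = np.array([abundance_vector[t] for t in taxa], dtype=float)
    if (probs < 0).any():
        raise ValueError("negative abundance in abundance_vector")
    if taxa and abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundance_vector sums to {probs.sum():.6f}, expected 1")
    rng = config.rngs()["reads"]
    n = config.n_reads
    if n == 0 or not taxa:
        return pd.DataFrame(columns=["read_id", "lineage"])
    unassigned = rng.random(n) < config.unassigned_fraction
    choice = rng.choice(len(taxa), size=n, p=probs / probs.sum())
    lineages = [
        UNCLASSIFIED if unassigned[i] else taxa[choice[i]] for i in range(n)
    ]
    return pd.DataFrame(
        {"read_id": [f"read_{i + 1:07d}" for i in range(n)], "lineage": lineages}
    )


# --- auxiliary tables for the full pipeline -------------------------------

def generate_qc_table(config: SyntheticConfig) -> pd.DataFrame:
    """Seeded completeness/contamination estimates spanning the cutoffs."""
    rng = config.rngs()["qc"]
    rows = []
    for i in range(config.n_hosts):
        rows.append(
            {
                "genome_id": f"host_{i + 1:03d}",
                "completeness": round(float(rng.uniform(40, 100)), 2),
                "contamination": round(float(rng.uniform(0, 15)), 2),
            }
        )
    return pd.DataFrame(rows)


_COG_LETTERS = "JKLMNOPQTUVC"


def generate_viral_orf_annotations(viruses, config: SyntheticConfig) -> pd.DataFrame:
    """Seeded eggNOG-style ORF annotations for the synthetic viruses.

    A few ORFs per contig: mostly COG-only, some CAZy families, an
    occasional nitrogen/sulfur orthology id, and unannotated ORFs.
    """
    rng = config.rngs()["viral_orfs"]
    cazy_pool = ["GH5", "GH13", "PL1", "GT2", "CE1", "AA3", "CBM13"]
    ns_pool = ["nirK", "cysN"]
    rows = []
    for v in viruses:
        n_orfs = int(rng.integers(3, 7))
        for o in range(n_orfs):
            orf_id = f"{v.contig_id}_orf{o + 1}"
            u = rng.random()
            cog, cazy, ko = "", "", ""
            if u < 0.15:
                cazy = cazy_pool[int(rng.integers(len(cazy_pool)))]
                cog = "G"
            elif u < 0.25:
                ko = ns_pool[int(rng.integers(len(ns_pool)))]
                cog = "P"
            elif u < 0.75:
                n_letters = 1 + int(rng.random() < 0.15)
                cog = "".join(
                    _COG_LETTERS[int(rng.integers(len(_COG_LETTERS)))]
                    for _ in range(n_letters)
                )
            rows.append(
                {
                    "orf_id": orf_id,
                    "contig_id": v.contig_id,
                    "cog_category": cog,
                    "cazy_family": cazy,
                    "ko_id": ko,
                    "description": "",
                }
            )
    return pd.DataFrame(
        rows, columns=["orf_id", "contig_id", "cog_category", "cazy_family", "ko_id", "description"]
    )


# --- bundle ---------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything one seeded run generates, plus its truth manifest."""

    config: SyntheticConfig
    hosts: list[GenomeRecord]
    viruses: list[ViralContig]
    annotations: pd.DataFrame
    reads: pd.DataFrame
    qc: pd.DataFrame
    viral_orfs: pd.DataFrame
    truth: TruthManifest

    def host_sequences(self) -> dict[str, str]:
        return {h.genome_id: h.concatenated() for h in self.hosts}

    def virus_sequences(self) -> dict[str, str]:
        return {v.contig_id: v.sequence for v in self.viruses}


def generate_bundle(config: SyntheticConfig, pathway_catalog=None) -> SyntheticBundle:
    """Run every generator in a fixed order and collect the truth."""
    from hadalmeta.traits import default_catalog

    catalog = pathway_catalog if pathway_catalog is not None else default_catalog()
    hosts, models = generate_host_genomes(config)
    viruses, prophage_links = plant_prophages(hosts, config)
    hosts, spacer_links = plant_crispr_arrays(hosts, viruses, config)
    annotations, trait_labels = generate_annotation_tables(catalog, config)
    abundance_vector = default_community(config)
    reads = generate_read_assignments(abundance_vector, config)
    truth = TruthManifest(
        prophage_links=prophage_links,
        spacer_links=spacer_links,
        trait_labels=trait_labels,
        abundance_vector=abundance_vector,
        composition_models=models,
    )
    return SyntheticBundle(
        config=config,
        hosts=hosts,
        viruses=viruses,
        annotations=annotations,
        reads=reads,
        qc=generate_qc_table(config),
        viral_orfs=generate_viral_orf_annotations(viruses, config),
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle's files (FASTA/TSV/JSON); returns path mapping."""
    from pathlib import Path

    from hadalmeta._fasta import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts_fasta": outdir / "hosts.fasta",
        "viruses_fasta": outdir / "viruses.fasta",
        "annotations_tsv": outdir / "annotations.tsv",
        "reads_tsv": outdir / "reads.tsv",
        "qc_tsv": outdir / "qc.tsv",
        "viral_orfs_tsv": outdir / "viral_orfs.tsv",
        "truth_json": outdir / "truth.json",
        "config_json": outdir / "config.json",
    }
    write_fasta(paths["hosts_fasta"], [(h.genome_id, h.concatenated()) for h in bundle.hosts])
    write_fasta(paths["viruses_fasta"], [(v.contig_id, v.sequence) for v in bundle.viruses])
    bundle.annotations.to_csv(paths["annotations_tsv"], sep="\t", index=False)
    bundle.reads.to_csv(paths["reads_tsv"], sep="\t", index=False)
    bundle.qc.to_csv(paths["qc_tsv"], sep="\t", index=False)
    bundle.viral_orfs.to_csv(paths["viral_orfs_tsv"], sep="\t", index=False)
    paths["truth_json"].write_text(bundle.truth.to_json())
    paths["config_json"].write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=1, sort_keys=True)
    )
    return {k: str(v) for k, v in paths.items()}
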
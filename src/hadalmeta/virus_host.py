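"""Three-signal virus-host association and bipartite network summarization.

A viral contig is linked to a candidate microbial host by any of three
independent signals:

1. **Sequence similarity** — nucleotide alignment hits (BLAST outfmt-6
   dialect) filtered at bit score >= 50 and E-value <= 0.001 (inclusive).
2. **CRISPR spacers** — a spacer detected in a host contig matches the
   viral contig full-length within a small Hamming distance (default <= 2
   mismatches), on either strand.
3. **Tetranucleotide composition** — the virus is assigned to the single
   host whose genome-wide k-mer frequency vector has the lowest mean
   absolute error (d) to the virus, accepted only if d < 0.0015 (strict).

k-mer vectors count every window of the sequence *and* its reverse
complement over the full 4^k k-mer space, so they are exactly
strand-invariant; windows containing non-ACGT characters are skipped.
Links from all signals are deduplicated to distinct (virus, host) pairs
and summarized as a bipartite virus-family x host-class network.

Coordinates are 0-based half-open; strands are "+" / "-".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hadalmeta._fasta import reverse_complement

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G on 2-bit codes

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass
class CompositionVector:
    """Normalized k-mer frequencies of a sequence or multi-contig genome."""

    sequence_id: str
    k: int
    frequencies: np.ndarray  # length 4^k, sums to 1
    kmer_total: int


@dataclass(frozen=True)
class Spacer:
    """A CRISPR spacer with its host coordinates (0-based half-open)."""

    host_id: str
    start: int
    end: int
    sequence: str
    array_index: int = 0


@dataclass(frozen=True)
class AssociationEdge:
    """One virus -> host link with its signal type and strength metadata."""

    virus_id: str
    host_id: str
    signal: str  # "similarity" | "crispr" | "composition"
    strength: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.virus_id, self.host_id)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every valid (ACGT-only) k-window; invalid dropped."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : n - k + 1 + j]
        ok &= window >= 0
        vals = vals * 4 + np.maximum(window, 0)
    return vals[ok]


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Both-strand k-mer counts over the full 4^k space."""
    fwd = _window_codes(_encode(seq), k)
    rev = _window_codes(_encode(reverse_complement(seq)), k)
    counts = np.bincount(fwd, minlength=4**k) + np.bincount(rev, minlength=4**k)
    return counts


def kmer_freq_vector(sequences, k: int = 4, sequence_id: str = "") -> CompositionVector:
    """Compute a both-strand k-mer frequency vector.

    ``sequences`` may be a single string or an iterable of strings (the
    contigs of one genome/MAG); counts are aggregated before normalizing.
    Windows containing non-ACGT characters are skipped.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences given")
    if all(len(s) < k for s in sequences):
        raise ValueError(f"all sequences shorter than k={k}")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        if len(seq) >= k:
            counts += _kmer_counts(seq, k)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid (ACGT-only) k-mer windows in input")
    return CompositionVector(
        sequence_id=sequence_id,
        k=k,
        frequencies=counts / total,
        kmer_total=total,
    )


def mae_distance(v1: CompositionVector, v2: CompositionVector) -> float:
    """Mean absolute error between two composition vectors.

    d = (1 / 4^k) * sum_i |v1_i - v2_i|; symmetric, 0 iff equal, at most
    2 / 4^k for frequency vectors.
    """
    if v1.k != v2.k or v1.frequencies.shape != v2.frequencies.shape:
        raise ValueError("composition vectors have mismatched k / dimension")
    return float(np.mean(np.abs(v1.frequencies - v2.frequencies)))


def assign_by_composition(
    viral_contigs: dict[str, str],
    host_genomes: dict,
    d_max: float = 0.0015,
    min_virus_len: int = 5000,
    k: int = 4,
) -> list[AssociationEdge]:
    """Assign each eligible virus to its compositionally closest host.

    ``host_genomes`` maps host id to a sequence or list of contig
    sequences.  A virus shorter than ``min_virus_len`` yields no edge (its
    signature is too unstable); otherwise it is linked to the single host
    with minimal d, only if d < d_max (strict).  An exact tie on minimal d
    is broken toward the lexicographically smallest host id and flagged.
    """
    if not host_genomes:
        raise ValueError("empty host set")
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    host_vectors = {
        hid: kmer_freq_vector(seqs, k=k, sequence_id=hid)
        for hid, seqs in sorted(host_genomes.items())
    }
    edges: list[AssociationEdge] = []
    for vid in sorted(viral_contigs):
        seq = viral_contigs[vid]
        if len(seq) < max(min_virus_len, k):
            continue
        vvec = kmer_freq_vector(seq, k=k, sequence_id=vid)
        dists = {hid: mae_distance(vvec, hvec) for hid, hvec in host_vectors.items()}
        best_host = min(dists, key=lambda h: (dists[h], h))
        best_d = dists[best_host]
        if best_d < d_max:
            tie = sum(1 for d in dists.values() if d == best_d) > 1
            edges.append(
                AssociationEdge(
                    virus_id=vid,
                    host_id=best_host,
                    signal="composition",
                    strength={"d": best_d, "tie": tie},
                )
            )
    return edges


# --- CRISPR spacer detection (minimal stand-in for a dedicated tool) -----

MIN_REPEAT_LEN = 23
MAX_REPEAT_LEN = 50
MIN_SPACER_LEN = 20
MAX_SPACER_LEN = 60


def detect_spacers(host_sequences: dict[str, str]) -> list[Spacer]:
    """Find CRISPR-like repeat-spacer arrays and return their spacers.

    Minimal detector: an array is >= 3 exact copies of a repeat
    (23-50 bp) separated by unique 20-60 bp spacers.  Seeds on exact
    23-mers occurring >= 3 times with plausible periodicity, extends the
    repeat while all copies agree, then emits the inter-repeat segments.
    """
    spacers: list[Spacer] = []
    for host_id in sorted(host_sequences):
        seq = host_sequences[host_id].upper()
        n = len(seq)
        positions: dict[str, list[int]] = {}
        for i in range(n - MIN_REPEAT_LEN + 1):
            positions.setdefault(seq[i : i + MIN_REPEAT_LEN], []).append(i)
        covered = np.zeros(n, dtype=bool)
        array_index = 0
        for kmer, pos in positions.items():  # insertion order = positional
            if len(pos) < 3:
                continue
            chain = None
            for s in range(len(pos) - 2):  # a stray early copy must not mask the array
                if covered[pos[s]]:
                    continue
                cand = _chain_periodic(pos[s:])
                if len(cand) >= 3:
                    chain = cand
                    break
            if chain is None:
                continue
            rep_len = _extend_repeat(seq, chain)
            if rep_len is None:
                continue
            segs = [
                (chain[i] + rep_len, chain[i + 1]) for i in range(len(chain) - 1)
            ]
            texts = [seq[a:b] for a, b in segs]
            if any(not (MIN_SPACER_LEN <= len(t) <= MAX_SPACER_LEN) for t in texts):
                continue
            if len(set(texts)) != len(texts):  # spacers must be unique
                continue
            for (a, b), t in zip(segs, texts):
                spacers.append(Spacer(host_id, a, b, t, array_index))
            covered[chain[0] : chain[-1] + rep_len] = True
            array_index += 1
    return spacers


def _chain_periodic(pos: list[int]) -> list[int]:
    """Greedily chain seed positions with gaps plausible for an array."""
    lo = MIN_REPEAT_LEN + MIN_SPACER_LEN
    hi = MAX_REPEAT_LEN + MAX_SPACER_LEN
    chain = [pos[0]]
    for p in pos[1:]:
        gap = p - chain[-1]
        if lo <= gap <= hi:
            chain.append(p)
        elif gap > hi:
            break
    return chain


def _extend_repeat(seq: str, chain: list[int]) -> int | None:
    """Longest repeat length on which all chained copies agree."""
    min_gap = min(b - a for a, b in zip(chain, chain[1:]))
    limit = min(MAX_REPEAT_LEN, min_gap - MIN_SPACER_LEN, len(seq) - chain[-1])
    if limit < MIN_REPEAT_LEN:
        return None
    length = MIN_REPEAT_LEN
    while length < limit and all(
        seq[p + length] == seq[chain[0] + length] for p in chain[1:]
    ):
        length += 1
    return length


def match_spacers(
    spacers, viral_contigs: dict[str, str], max_mismatch: int = 2
) -> list[AssociationEdge]:
    """Scan both strands of each virus for full-length spacer matches.

    A (virus, host) pair gets one edge carrying its best (fewest
    mismatches) spacer alignment; matches above ``max_mismatch`` Hamming
    distance are discarded.  Spacers shorter than 20 bp are rejected with
    a warning.
    """
    best: dict[tuple[str, str], dict] = {}
    for spacer in spacers:
        if len(spacer.sequence) < MIN_SPACER_LEN:
            logger.warning(
                "spacer at %s:%d-%d shorter than %d bp; skipped",
                spacer.host_id, spacer.start, spacer.end, MIN_SPACER_LEN,
            )
            continue
        sp = _encode(spacer.sequence)
        for vid in sorted(viral_contigs):
            vseq = viral_contigs[vid]
            hit = _best_hamming_hit(sp, vseq)
            if hit is None or hit[0] > max_mismatch:
                continue
            mism, start, strand = hit
            key = (vid, spacer.host_id)
            rec = {
                "mismatches": mism,
                "virus_start": start,
                "virus_end": start + len(spacer.sequence),
                "strand": strand,
                "spacer_start": spacer.start,
                "spacer_end": spacer.end,
            }
            if key not in best or mism < best[key]["mismatches"]:
                best[key] = rec
    return [
        AssociationEdge(virus_id=v, host_id=h, signal="crispr", strength=rec)
        for (v, h), rec in sorted(best.items())
    ]


def _best_hamming_hit(spacer_codes: np.ndarray, virus_seq: str):
    """Minimal-mismatch full-length placement of a spacer on either strand.

    Returns (mismatches, start_on_plus_strand, strand) or None.  Ambiguous
    virus positions count as mismatches.
    """
    m = spacer_codes.size
    result = None
    for strand, seq in (("+", virus_seq), ("-", reverse_complement(virus_seq))):
        codes = _encode(seq)
        n = codes.size
        if n < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, m)
        mism = np.sum((windows != spacer_codes) | (windows < 0), axis=1)
        i = int(np.argmin(mism))
        score = int(mism[i])
        start = i if strand == "+" else n - i - m
        if result is None or score < result[0]:
            result = (score, start, strand)
    return result


# --- similarity signal ----------------------------------------------------

def read_blast_tab(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (BLAST outfmt-6 dialect)."""
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"{path}: unparseable alignment table: {exc}") from exc
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            float(row.bitscore), float(row.evalue)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable row at line {i}") from exc
    return df


def filter_similarity_links(
    alignment_table: pd.DataFrame,
    min_bitscore: float = 50.0,
    max_evalue: float = 0.001,
) -> list[AssociationEdge]:
    """Filter alignment rows and collapse to one edge per (virus, host).

    Keeps rows with bit score >= min_bitscore and E-value <= max_evalue
    (both inclusive); per pair the best-scoring row (max bit score, then
    min E-value) supplies the edge strength.
    """
    df = alignment_table
    missing = [c for c in ("qseqid", "sseqid", "evalue", "bitscore") if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    keep = df[
        (df["bitscore"].astype(float) >= min_bitscore)
        & (df["evalue"].astype(float) <= max_evalue)
    ]
    edges = []
    for (vid, hid), group in keep.groupby(["qseqid", "sseqid"], sort=True):
        top = group.sort_values(
            ["bitscore", "evalue"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        strength = {
            "bitscore": float(top["bitscore"]),
            "evalue": float(top["evalue"]),
        }
        if "length" in group.columns:
            strength["alignment_length"] = int(top["length"])
        edges.append(
            AssociationEdge(
                virus_id=str(vid), host_id=str(hid),
                signal="similarity", strength=strength,
            )
        )
    return edges


def exact_substring_hits(
    viral_contigs: dict[str, str], host_genomes: dict[str, str]
) -> pd.DataFrame:
    """Naive exact-match similarity search, in the outfmt-6 dialect.

    Reports each virus that occurs verbatim (either strand) in a host,
    with a bit score of ~2 bits per matched base and E-value 0.  A small
    built-in stand-in for an external aligner, suitable for synthetic
    benchmarks; real data should use a dedicated alignment tool.
    """
    rows = []
    for vid in sorted(viral_contigs):
        vseq = viral_contigs[vid]
        for hid in sorted(host_genomes):
            hseq = host_genomes[hid]
            for strand, probe in (("+", vseq), ("-", reverse_complement(vseq))):
                at = hseq.find(probe)
                if at >= 0:
                    L = len(vseq)
                    rows.append(
                        {
                            "qseqid": vid, "sseqid": hid, "pident": 100.0,
                            "length": L, "mismatch": 0, "gapopen": 0,
                            "qstart": 0, "qend": L,
                            "sstart": at, "send": at + L,
                            "evalue": 0.0, "bitscore": round(1.9 * L, 1),
                        }
                    )
                    break
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


# --- network summarization ------------------------------------------------

def build_network(
    edges,
    virus_taxonomy: dict[str, str] | None = None,
    host_taxonomy: dict[str, str] | None = None,
) -> tuple[nx.Graph, dict]:
    """Summarize association edges as a virus-family x host-class network.

    The same (virus, host) pair found by several signals is counted once;
    edge weight is the number of distinct underlying pairs.  Ids missing
    from the taxonomies are grouped under "unclassified".
    """
    virus_taxonomy = virus_taxonomy or {}
    host_taxonomy = host_taxonomy or {}
    pairs = sorted({e.pair for e in edges})
    weights: dict[tuple[str, str], int] = {}
    for vid, hid in pairs:
        fam = virus_taxonomy.get(vid, "unclassified")
        cls = host_taxonomy.get(hid, "unclassified")
        weights[(fam, cls)] = weights.get((fam, cls), 0) + 1
    graph = nx.Graph()
    for (fam, cls), w in sorted(weights.items()):
        graph.add_node(f"family:{fam}", kind="virus_family", name=fam, bipartite=0)
        graph.add_node(f"class:{cls}", kind="host_class", name=cls, bipartite=1)
        graph.add_edge(f"family:{fam}", f"class:{cls}", weight=w)
    per_family: dict[str, dict[str, int]] = {}
    for (fam, cls), w in sorted(weights.items()):
        per_family.setdefault(fam, {})[cls] = w
    summary = {
        "n_pairs": len(pairs),
        "n_families": len(per_family),
        "n_classes": len({cls for _, cls in weights}),
        "per_family_class_counts": per_family,
    }
    return graph, summary


def edges_to_frame(edges) -> pd.DataFrame:
    """Flatten association edges to a table (one row per edge)."""
    rows = []
    for e in edges:
        row = {"virus_id": e.virus_id, "host_id": e.host_id, "signal": e.signal}
        row.update(e.strength)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["virus_id", "host_id", "signal"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df
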
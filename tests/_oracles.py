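"""Naive brute-force reference implementations used as test oracles.

These deliberately avoid the package's own vectorized code paths: plain
dict counting, string slicing and per-position comparison.
"""

from itertools import product

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
ALL_TETRAMERS = ["".join(p) for p in product("ACGT", repeat=4)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bf_kmer_freqs(seq: str, k: int = 4) -> tuple[np.ndarray, int]:
    """Both-strand k-mer frequencies by direct window counting."""
    counts: dict[str, int] = {}
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                counts[w] = counts.get(w, 0) + 1
    total = sum(counts.values())
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    return np.array([counts.get(w, 0) / total for w in kmers]), total


def bf_mae(v1: np.ndarray, v2: np.ndarray) -> float:
    return sum(abs(a - b) for a, b in zip(v1, v2)) / len(v1)


def bf_hamming_scan(probe: str, target: str) -> int:
    """Minimal Hamming distance of a full-length probe placement on
    either strand of the target (brute force over every position)."""
    best = len(probe) + 1
    for strand in (target, revcomp(target)):
        for i in range(len(strand) - len(probe) + 1):
            d = sum(a != b for a, b in zip(probe, strand[i : i + len(probe)]))
            best = min(best, d)
    return best


def bf_abundance(assignments, rank: str) -> tuple[dict[str, int], int]:
    """One-pass counter: per-taxon counts at a rank and the denominator
    (all assigned reads)."""
    counts: dict[str, int] = {}
    denominator = 0
    for a in assignments:
        if not a.assigned:
            continue
        denominator += 1
        name = a.lineage.get(rank)
        if name is not None:
            counts[name] = counts.get(name, 0) + 1
    return counts, denominator
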
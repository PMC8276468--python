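"""FASTA reading/writing helpers (Biopython-backed, deterministic output)."""

from __future__ import annotations

import io
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_LINE_WIDTH = 70


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(id, sequence)`` pairs, wrapped at a fixed width.

    Output is byte-deterministic for a given input order.
    """
    with open(path, "w") as fh:
        fh.write(fasta_str(records))


def fasta_str(records: Iterable[tuple[str, str]]) -> str:
    buf = io.StringIO()
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        buf,
        "fasta",
    )
    return buf.getvalue()


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
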
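"""Reference sequence access: FASTA loading and interval slicing."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO

__all__ = ["SequenceStore", "load_sequences"]


class SequenceStore:
    """Named reference sequences addressable by (name, interval).

    Sequences are held in memory, which suits the kilobase-to-megabase
    genomes this tool targets.  Coordinates are 0-based half-open.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)
        self.names: list[str] = list(self._seqs)
        self.lengths: dict[str, int] = {n: len(s) for n, s in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def sequence(self, name: str) -> str:
        """Whole sequence for ``name``."""
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"sequence {name!r} not found in store") from None

    def fetch(self, name: str, start0: int, end0: int) -> str:
        """Substring ``[start0, end0)``; bounds are checked strictly."""
        seq = self.sequence(name)
        if not (0 <= start0 < end0 <= len(seq)):
            raise ValueError(
                f"interval [{start0}, {end0}) out of bounds for "
                f"{name!r} of length {len(seq)}"
            )
        return seq[start0:end0]


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_sequences(path) -> SequenceStore:
    """Load a (optionally gzipped) FASTA file into a SequenceStore.

    Record order is preserved; duplicate identifiers are an error.
    """
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence identifier {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceStore(seqs)
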
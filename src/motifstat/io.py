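"""Sequence containers and FASTA input/output.

The working container is :class:`SequenceSet`: an ordered list of named
sequences validated against an :class:`~motifstat.alphabet.Alphabet` and
pre-encoded to integer index arrays so that downstream matrix code never
touches raw strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, Alphabet

__all__ = ["SequenceSet", "read_fasta", "write_fasta", "residue_counts"]


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of validated sequences over a common alphabet."""

    names: tuple[str, ...]
    encoded: tuple[np.ndarray, ...]  # int index arrays, one per record
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if len(self.names) != len(self.encoded):
            raise ValueError("names and sequences differ in length")
        if len(self.names) == 0:
            raise ValueError("a SequenceSet needs at least one record")
        for name, enc in zip(self.names, self.encoded):
            if enc.size == 0:
                raise ValueError(f"record {name!r} is empty")

    @classmethod
    def from_strings(
        cls,
        sequences: Iterable[str],
        names: Iterable[str] | None = None,
        alphabet: Alphabet = DNA,
    ) -> "SequenceSet":
        seqs = list(sequences)
        if names is None:
            names = [f"Seq{i + 1}" for i in range(len(seqs))]
        names = tuple(names)
        encoded = tuple(
            alphabet.encode(s, label=n) for n, s in zip(names, seqs)
        )
        return cls(names=names, encoded=encoded, alphabet=alphabet)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.names, self.encoded))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e.size for e in self.encoded], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def sequence(self, i: int, *, rna: bool = False) -> str:
        """Record ``i`` as text (T-spelling by default)."""
        return self.alphabet.decode(self.encoded[i], rna=rna)

    def window(self, i: int, start0: int, width: int, *, rna: bool = False) -> str:
        """The ``width``-mer of record ``i`` starting at 0-based ``start0``."""
        return self.alphabet.decode(self.encoded[i][start0 : start0 + width], rna=rna)


def read_fasta(path: str | Path, alphabet: Alphabet = DNA) -> SequenceSet:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Residues are upper-cased and validated; for the nucleotide alphabet U is
    stored on the T index.  Any residue outside the alphabet raises with the
    record name and position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return SequenceSet.from_strings(
        (str(r.seq) for r in records), (r.id for r in records), alphabet
    )


def write_fasta(seqs: SequenceSet, path: str | Path, *, rna: bool = False) -> None:
    """Write a SequenceSet as FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(seqs.sequence(i, rna=rna)), id=seqs.names[i], description="")
        for i in range(len(seqs))
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def residue_counts(seqs: SequenceSet) -> np.ndarray:
    """Total count of each alphabet symbol over all records.

    For nucleotide input this is the vector (F_A, F_C, F_G, F_T) whose sum is
    the total number of residues; it feeds the input-derived background and
    the residue-conservation checks of the Gibbs sampler.
    """
    counts = np.zeros(seqs.alphabet.size, dtype=np.int64)
    for enc in seqs.encoded:
        counts += np.bincount(enc, minlength=seqs.alphabet.size)
    return counts
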
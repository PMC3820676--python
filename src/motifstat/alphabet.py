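"""Residue alphabets for nucleotide and amino-acid motif analysis.

An :class:`Alphabet` is an ordered set of residue symbols together with an
encoding of residue strings into integer index arrays.  Only two alphabets
matter in practice -- the 4-letter nucleotide alphabet (with U and T sharing
one index, so RNA and DNA input are interchangeable) and the 20-letter
amino-acid alphabet -- but any alphabet of two or more unique symbols is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["Alphabet", "DNA", "PROTEIN", "AlphabetError"]


class AlphabetError(ValueError):
    """A residue outside the alphabet, or an ill-formed alphabet."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with optional symbol aliases.

    Parameters
    ----------
    symbols:
        Ordered residue characters; their order fixes row order in every
        count/weight matrix built from this alphabet.
    aliases:
        Extra characters mapped onto an existing symbol's index.  The
        nucleotide alphabet maps ``U`` to the ``T`` index so that RNA and
        DNA spellings of the same motif are one internal object.
    name:
        Display name.
    """

    symbols: tuple[str, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise AlphabetError("an alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError("alphabet symbols must be unique")
        for alias, target in self.aliases.items():
            if target not in self.symbols:
                raise AlphabetError(f"alias {alias!r} maps to unknown symbol {target!r}")

    @property
    def size(self) -> int:
        """Number of distinct symbols (4 for nucleotide, 20 for amino acid)."""
        return len(self.symbols)

    def index_of(self, residue: str) -> int:
        r = residue.upper()
        table = self._index_table()
        if r not in table:
            raise AlphabetError(f"residue {residue!r} is not in the {self.name} alphabet")
        return table[r]

    def _index_table(self) -> dict[str, int]:
        table = {s: i for i, s in enumerate(self.symbols)}
        for alias, target in self.aliases.items():
            table[alias] = table[target]
        return table

    def encode(self, sequence: str, *, label: str = "<sequence>") -> np.ndarray:
        """Encode a residue string to an int array of symbol indices.

        Case-insensitive; any character outside the alphabet (including
        whitespace and ambiguity codes) is a hard error naming the record
        and the 1-based offending position.
        """
        table = self._index_table()
        out = np.empty(len(sequence), dtype=np.int64)
        for pos, ch in enumerate(sequence.upper()):
            idx = table.get(ch)
            if idx is None:
                raise AlphabetError(
                    f"record {label!r}: residue {ch!r} at position {pos + 1} "
                    f"is not in the {self.name} alphabet"
                )
            out[pos] = idx
        return out

    def decode(self, indices: Sequence[int] | np.ndarray, *, rna: bool = False) -> str:
        """Render index arrays back to text; ``rna=True`` prints U for the T index."""
        symbols = list(self.symbols)
        if rna and "T" in symbols:
            symbols[symbols.index("T")] = "U"
        return "".join(symbols[int(i)] for i in indices)


#: Nucleotide alphabet; U is an alias for T, so "ACGU" and "ACGT" encode alike.
DNA = Alphabet(symbols=("A", "C", "G", "T"), aliases={"U": "T"}, name="nucleotide")

#: The 20 standard amino acids in alphabetical one-letter order.
PROTEIN = Alphabet(symbols=tuple("ACDEFGHIKLMNPQRSTVWY"), name="amino-acid")
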
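"""Background (prior) residue frequency models.

The background vector ``p_i`` is the null hypothesis every log-odds weight is
taken against.  Three modes are supported: uniform, computed from the input
sequences, or user-specified for the problem at hand (e.g. genome-wide or
intron-wide frequencies).  The user-specified mode is the recommended default:
an input-derived background makes a perfectly conserved motif look
uninformative (a poly-U alignment yields p_U = 1 and a flat weight matrix),
and a uniform background manufactures spurious A/T signal in AT-rich genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import DNA, Alphabet
from .io import SequenceSet, residue_counts

__all__ = ["BackgroundModel", "make_background", "parse_background_string", "read_background_tsv", "write_background_tsv"]

_MODES = ("uniform", "from-input", "user-specified")


@dataclass(frozen=True)
class BackgroundModel:
    """Prior symbol frequencies ``p_i`` plus (optionally) the raw totals F_i."""

    p: np.ndarray
    alphabet: Alphabet = DNA
    mode: str = "user-specified"
    totals: np.ndarray | None = None  # raw symbol counts when known

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if self.mode not in _MODES:
            raise ValueError(f"unknown background mode {self.mode!r}")
        if p.shape != (self.alphabet.size,):
            raise ValueError(
                f"background has {p.size} entries for a {self.alphabet.size}-symbol alphabet"
            )
        if np.any(p < 0):
            raise ValueError("background frequencies must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1 (within 1e-12)")

    @property
    def strictly_positive(self) -> bool:
        return bool(np.all(self.p > 0))

    def require_positive(self, context: str = "this operation") -> None:
        """Zero frequencies are storable but cannot be divided by."""
        if not self.strictly_positive:
            zero = [self.alphabet.symbols[i] for i in np.flatnonzero(self.p == 0)]
            raise ValueError(
                f"{context} requires a strictly positive background; "
                f"zero frequency for symbol(s) {', '.join(zero)}"
            )


def make_background(
    mode: str,
    source: SequenceSet | np.ndarray | list[float] | None = None,
    alphabet: Alphabet = DNA,
) -> BackgroundModel:
    """Build a BackgroundModel.

    mode="uniform"
        ``p_i = 1/size``; no source needed.
    mode="from-input"
        ``p_i = F_i / sum(F)`` with F the residue counts of the source
        SequenceSet.
    mode="user-specified"
        source is a non-negative vector (one entry per symbol, sum > 0),
        normalized to sum exactly 1.
    """
    if mode == "uniform":
        p = np.full(alphabet.size, 1.0 / alphabet.size)
        return BackgroundModel(p=p, alphabet=alphabet, mode=mode)
    if mode == "from-input":
        if not isinstance(source, SequenceSet):
            raise TypeError("from-input background needs a SequenceSet source")
        totals = residue_counts(source)
        return BackgroundModel(
            p=totals / totals.sum(), alphabet=source.alphabet, mode=mode, totals=totals
        )
    if mode == "user-specified":
        v = np.asarray(source, dtype=float)
        if v.shape != (alphabet.size,):
            raise ValueError(
                f"expected {alphabet.size} frequencies, got {v.size}"
            )
        if np.any(v < 0):
            raise ValueError("background entries must be non-negative")
        total = v.sum()
        if total <= 0:
            raise ValueError("background entries sum to zero")
        return BackgroundModel(p=v / total, alphabet=alphabet, mode=mode)
    raise ValueError(f"unknown background mode {mode!r}")


def parse_background_string(text: str, alphabet: Alphabet = DNA) -> BackgroundModel:
    """Parse an inline spec like ``"A=0.3279,C=0.1915,G=0.2043,T=0.2763"``."""
    v = np.zeros(alphabet.size)
    seen: set[int] = set()
    for item in text.split(","):
        sym, _, val = item.partition("=")
        if not _:
            raise ValueError(f"malformed background item {item!r} (expected SYMBOL=VALUE)")
        idx = alphabet.index_of(sym.strip())
        if idx in seen:
            raise ValueError(f"duplicate background entry for symbol {sym.strip()!r}")
        seen.add(idx)
        v[idx] = float(val)
    if len(seen) != alphabet.size:
        raise ValueError(f"background string covers {len(seen)} of {alphabet.size} symbols")
    return make_background("user-specified", v, alphabet)


def read_background_tsv(path: str | Path, alphabet: Alphabet = DNA) -> BackgroundModel:
    """Read a 2-column TSV of (symbol, frequency)."""
    v = np.zeros(alphabet.size)
    seen: set[int] = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
        idx = alphabet.index_of(fields[0].strip())
        if idx in seen:
            raise ValueError(f"{path}:{line_no}: duplicate symbol {fields[0]!r}")
        seen.add(idx)
        v[idx] = float(fields[1])
    if len(seen) != alphabet.size:
        raise ValueError(f"{path}: covers {len(seen)} of {alphabet.size} symbols")
    return make_background("user-specified", v, alphabet)


def write_background_tsv(bg: BackgroundModel, path: str | Path) -> None:
    lines = [
        f"{sym}\t{freq:.10g}" for sym, freq in zip(bg.alphabet.symbols, bg.p)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
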
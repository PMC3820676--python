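"""Position weight matrices: counts, pseudocounted frequencies, log-odds
weights, window scoring, and the information-content statistic F.

The pipeline is

    aligned motifs -> CountMatrix f_ij -> FrequencyMatrix p_ij -> PWMatrix

with ``PWM_ij = log2(p_ij / p_i)`` in bits.  A window's score (PWMS) is the
sum of the weights its residues select, i.e. the log2 likelihood ratio of the
"this window is a motif occurrence" hypothesis against the background
hypothesis; ``2**PWMS`` is the corresponding odds ratio.

Pseudocount schemes
-------------------
``add-background``
    p_ij = (f_ij + p_i) / (N + 1): one extra pseudo-observation distributed
    as the background.  Poor at small N.
``scaled-counts`` (default)
    explicit pseudocounts proportional to the background and to the data
    mass: f_i.pseudo = alpha * p_i * N, hence
    p_ij = (f_ij + alpha*p_i*N) / (N*(1+alpha)).  With the recommended small
    alpha (0.0001) this keeps the expected weight of random sequences at ~0.
``scaled-totals``
    the literal variant where the pseudocount scales with the background's
    raw symbol totals F_i: f_i.pseudo = alpha * F_i (requires the background
    to carry totals).
``user-vector``
    an arbitrary non-negative pseudocount vector v:
    p_ij = (f_ij + v_i) / (N + sum(v)), for data-driven pseudocounts
    supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .alphabet import DNA, Alphabet
from .background import BackgroundModel
from .io import SequenceSet

__all__ = [
    "CountMatrix",
    "PseudocountSpec",
    "FrequencyMatrix",
    "PWMatrix",
    "ScoreResult",
    "count_matrix",
    "frequency_matrix",
    "weight_matrix",
    "build_pwm",
    "score_window",
    "scan",
    "information_content",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_meme",
]

DEFAULT_ALPHA = 0.0001


@dataclass(frozen=True)
class CountMatrix:
    """Site-specific residue counts f_ij (symbols x sites) for N aligned motifs."""

    counts: np.ndarray
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != self.alphabet.size:
            raise ValueError(
                f"count matrix must be ({self.alphabet.size} x L), got {c.shape}"
            )
        if c.shape[1] < 1:
            raise ValueError("motif width must be >= 1")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        colsums = c.sum(axis=0)
        if not np.all(colsums == colsums[0]):
            raise ValueError("every column must sum to the same number of motifs N")
        if colsums[0] < 1:
            raise ValueError("at least one aligned motif is required")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    @property
    def n_motifs(self) -> int:
        return int(self.counts[:, 0].sum())


@dataclass(frozen=True)
class PseudocountSpec:
    """How zero counts are regularized before taking logarithms."""

    scheme: Literal["add-background", "scaled-counts", "scaled-totals", "user-vector"] = "scaled-counts"
    alpha: float = DEFAULT_ALPHA
    vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("pseudocount weight alpha must be >= 0")
        if self.scheme == "user-vector":
            if self.vector is None:
                raise ValueError("user-vector scheme needs a pseudocount vector")
            v = np.asarray(self.vector, dtype=float)
            if np.any(v < 0):
                raise ValueError("pseudocount vector entries must be >= 0")
            object.__setattr__(self, "vector", v)

    def pseudocounts(self, background: BackgroundModel, n_motifs: int) -> np.ndarray:
        """Per-symbol pseudocount vector f_i.pseudo for a given data mass N."""
        if self.scheme == "add-background":
            return background.p.copy()
        if self.scheme == "scaled-counts":
            return self.alpha * background.p * n_motifs
        if self.scheme == "scaled-totals":
            if background.totals is None:
                raise ValueError(
                    "scaled-totals pseudocounts need a background with raw symbol totals"
                )
            return self.alpha * np.asarray(background.totals, dtype=float)
        if self.scheme == "user-vector":
            assert self.vector is not None
            if self.vector.size != background.p.size:
                raise ValueError("pseudocount vector length does not match alphabet")
            return self.vector.copy()
        raise ValueError(f"unknown pseudocount scheme {self.scheme!r}")


@dataclass(frozen=True)
class FrequencyMatrix:
    """Pseudocounted site-specific frequencies p_ij; columns sum to 1."""

    p: np.ndarray
    alphabet: Alphabet = DNA
    source: CountMatrix | None = field(default=None, compare=False)
    spec: PseudocountSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 2 or p.shape[0] != self.alphabet.size:
            raise ValueError(f"frequency matrix must be ({self.alphabet.size} x L)")
        if np.any(p < 0):
            raise ValueError("frequencies must be non-negative")
        if np.any(np.abs(p.sum(axis=0) - 1.0) > 1e-12):
            raise ValueError("every frequency column must sum to 1 within 1e-12")

    @property
    def width(self) -> int:
        return int(self.p.shape[1])


@dataclass(frozen=True)
class PWMatrix:
    """Log2-odds weights w_ij (bits); -inf marks a zero frequency with no pseudocount."""

    w: np.ndarray
    alphabet: Alphabet = DNA
    background: BackgroundModel | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 2 or w.shape[0] != self.alphabet.size:
            raise ValueError(f"weight matrix must be ({self.alphabet.size} x L)")
        if np.any(np.isnan(w)):
            raise ValueError("weight matrix contains NaN")

    @property
    def width(self) -> int:
        return int(self.w.shape[1])

    @property
    def finite(self) -> bool:
        return bool(np.all(np.isfinite(self.w)))


@dataclass(frozen=True)
class ScoreResult:
    """One scored window: start coordinate, PWMS in bits, odds ratio 2**PWMS."""

    start: int  # 0-based internally; CLI layers re-base for display
    pwms: float
    odds: float
    strand: str = "+"


def count_matrix(motifs: Iterable[str] | SequenceSet, alphabet: Alphabet = DNA) -> CountMatrix:
    """Tabulate site-specific counts from equal-length aligned motif windows."""
    if isinstance(motifs, SequenceSet):
        alphabet = motifs.alphabet
        encoded = list(motifs.encoded)
    else:
        encoded = [alphabet.encode(m, label=f"motif[{k}]") for k, m in enumerate(motifs)]
    if not encoded:
        raise ValueError("no motifs given")
    width = encoded[0].size
    if any(e.size != width for e in encoded):
        raise ValueError("aligned motifs must all have the same length")
    counts = np.zeros((alphabet.size, width), dtype=np.int64)
    for e in encoded:
        counts[e, np.arange(width)] += 1
    return CountMatrix(counts=counts, alphabet=alphabet)


def frequency_matrix(
    counts: CountMatrix,
    background: BackgroundModel,
    spec: PseudocountSpec = PseudocountSpec(),
) -> FrequencyMatrix:
    """Convert counts to pseudocounted frequencies p_ij."""
    if spec.scheme == "add-background":
        background.require_positive("the add-background pseudocount scheme")
    n = counts.n_motifs
    pseudo = spec.pseudocounts(background, n)
    p = (counts.counts + pseudo[:, None]) / (n + pseudo.sum())
    return FrequencyMatrix(p=p, alphabet=counts.alphabet, source=counts, spec=spec)


def weight_matrix(freqs: FrequencyMatrix, background: BackgroundModel) -> PWMatrix:
    """w_ij = log2(p_ij / p_i); a zero p_ij yields -inf, which scoring refuses to touch."""
    background.require_positive("building a weight matrix")
    with np.errstate(divide="ignore"):
        w = np.log2(freqs.p / background.p[:, None])
    return PWMatrix(w=w, alphabet=freqs.alphabet, background=background)


def build_pwm(
    motifs: Iterable[str] | SequenceSet,
    background: BackgroundModel,
    spec: PseudocountSpec = PseudocountSpec(),
) -> PWMatrix:
    """Convenience composition: counts -> frequencies -> weights."""
    return weight_matrix(frequency_matrix(count_matrix(motifs, background.alphabet), background, spec), background)


def _score_encoded(pwm: PWMatrix, window: np.ndarray) -> float:
    vals = pwm.w[window, np.arange(window.size)]
    if not np.all(np.isfinite(vals)):
        raise ValueError(
            "window touches a -inf weight (zero site frequency with no pseudocount)"
        )
    return float(vals.sum())


def score_window(pwm: PWMatrix, window: str) -> ScoreResult:
    """Score one window of exactly the matrix width."""
    enc = pwm.alphabet.encode(window, label="<window>")
    if enc.size != pwm.width:
        raise ValueError(f"window length {enc.size} != matrix width {pwm.width}")
    s = _score_encoded(pwm, enc)
    return ScoreResult(start=0, pwms=s, odds=2.0**s)


_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on the DNA index order


def scan(
    pwm: PWMatrix,
    seq: str | np.ndarray,
    strand: Literal["forward", "both"] = "forward",
) -> list[ScoreResult]:
    """Score every window of a sequence.

    Returns len(seq) - L + 1 forward windows ordered by start; with
    strand="both" the reverse-complement windows (scored on the minus strand,
    reported by their forward-strand start) are appended after the forward
    list.
    """
    enc = pwm.alphabet.encode(seq, label="<scan>") if isinstance(seq, str) else np.asarray(seq)
    L = pwm.width
    if enc.size < L:
        raise ValueError(f"sequence length {enc.size} < matrix width {L}")
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = pwm.w[windows, np.arange(L)].sum(axis=1)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scan touches a -inf weight; use pseudocounts")
    out = [
        ScoreResult(start=i, pwms=float(s), odds=float(2.0**s))
        for i, s in enumerate(scores)
    ]
    if strand == "both":
        if pwm.alphabet.size != 4:
            raise ValueError("reverse-complement scanning needs the nucleotide alphabet")
        rc = _COMPLEMENT[enc[::-1]]
        rc_windows = np.lib.stride_tricks.sliding_window_view(rc, L)
        rc_scores = pwm.w[rc_windows, np.arange(L)].sum(axis=1)
        n = enc.size - L + 1
        out.extend(
            ScoreResult(start=n - 1 - i, pwms=float(s), odds=float(2.0**s), strand="-")
            for i, s in enumerate(rc_scores)
        )
    elif strand != "forward":
        raise ValueError(f"unknown strand mode {strand!r}")
    return out


def information_content(counts: CountMatrix, pwm: PWMatrix) -> float:
    """Count-weighted information content F = sum_ij C_ij * w_ij (bits x counts).

    F is a Kullback-Leibler-type alignment-quality score: with no
    pseudocounts and the background equal to the pooled column frequencies it
    equals N times the summed per-site KL divergence from background, hence
    >= 0, and it grows with both motif sharpness and the number of aligned
    motifs.  Cells with zero count contribute nothing even if the weight
    there is -inf.
    """
    if counts.counts.shape != pwm.w.shape:
        raise ValueError("count and weight matrices differ in shape")
    c = counts.counts.astype(float)
    w = np.where(c > 0, pwm.w, 0.0)
    if not np.all(np.isfinite(w[c > 0])):
        raise ValueError("a nonzero count sits on a -inf weight")
    return float((c * w).sum())


# ---------------------------------------------------------------------------
# Matrix serialization: TSV (rows = symbols, columns = sites) and MEME minimal.
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: CountMatrix | PWMatrix | FrequencyMatrix, path: str | Path) -> None:
    data = matrix.counts if isinstance(matrix, CountMatrix) else (
        matrix.p if isinstance(matrix, FrequencyMatrix) else matrix.w
    )
    alphabet = matrix.alphabet
    width = data.shape[1]
    lines = ["Symbol\t" + "\t".join(str(j + 1) for j in range(width))]
    for i, sym in enumerate(alphabet.symbols):
        if np.issubdtype(data.dtype, np.integer):
            row = "\t".join(str(int(v)) for v in data[i])
        else:
            row = "\t".join(f"{v:.6f}" for v in data[i])
        lines.append(f"{sym}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path: str | Path, alphabet: Alphabet = DNA, kind: str = "auto"):
    """Read a symbols-x-sites TSV written by :func:`write_matrix_tsv`.

    kind: "counts", "weights", or "auto" (counts iff every cell parses as an
    integer).
    """
    rows: dict[int, list[float]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "Symbol":
            continue
        idx = alphabet.index_of(fields[0])
        rows[idx] = [float(x) for x in fields[1:]]
    if len(rows) != alphabet.size:
        raise ValueError(f"{path}: expected {alphabet.size} symbol rows, got {len(rows)}")
    data = np.array([rows[i] for i in range(alphabet.size)])
    if kind == "auto":
        kind = "counts" if np.all(data == np.round(data)) and np.all(data >= 0) else "weights"
    if kind == "counts":
        return CountMatrix(counts=data.astype(np.int64), alphabet=alphabet)
    return PWMatrix(w=data, alphabet=alphabet)


def write_meme(
    freqs: FrequencyMatrix,
    background: BackgroundModel,
    path: str | Path,
    name: str = "motif",
    nsites: int | None = None,
) -> None:
    """Export a frequency matrix in MEME minimal motif format."""
    a = freqs.alphabet
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {''.join(a.symbols)}",
        "",
        "Background letter frequencies",
        " ".join(f"{s} {p:.4f}" for s, p in zip(a.symbols, background.p)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= {a.size} w= {freqs.width}"
        + (f" nsites= {nsites}" if nsites else ""),
    ]
    for j in range(freqs.width):
        lines.append(" ".join(f"{freqs.p[i, j]:.6f}" for i in range(a.size)))
    Path(path).write_text("\n".join(lines) + "\n")
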
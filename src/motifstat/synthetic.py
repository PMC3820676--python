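"""Synthetic sequence generators and small published reference fixtures.

Everything downstream is testable without any external download: null
sequences are drawn i.i.d. from a background model, planted-motif benchmarks
carry a known ground truth for recovery scoring, and the fixtures expose the
published worked-example tables this package reproduces (the 246 yeast donor
splice-site count matrix, the intermediate C0/C bookkeeping states of the
Gibbs illustration, and the 40-nt sequence those states rescore).

The erythroid-style preset emulates the dimensions of the classic 29-sequence
GATA benchmark used to illustrate the site sampler: 29 DNA sequences, 1209
residues in total, overall composition close to A:325, C:316, G:267, T:301,
and exactly one planted occurrence of a 6-mer consensus per sequence.  The
sequences themselves are synthetic; only the dimensions and composition are
matched, so recovery rates measured on it characterize the algorithm, not the
original data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import DNA, Alphabet
from .background import BackgroundModel, make_background
from .io import SequenceSet
from .pwm import CountMatrix

__all__ = [
    "PlantedMotifSpec",
    "random_sequences",
    "plant_motifs",
    "erythroid_spec",
    "splice_site_counts",
    "splice_site_background",
    "gibbs_demo_states",
    "gibbs_demo_sequence",
]


def random_sequences(
    background: BackgroundModel,
    n: int,
    length: int | np.ndarray,
    rng: np.random.Generator,
    prefix: str = "rand",
) -> SequenceSet:
    """n sequences of i.i.d. residues drawn from the background."""
    background.require_positive("drawing random sequences")
    lengths = np.full(n, length, dtype=np.int64) if np.isscalar(length) else np.asarray(length)
    if lengths.size != n:
        raise ValueError("length vector must have n entries")
    cum = np.cumsum(background.p)
    encoded = tuple(
        np.searchsorted(cum, rng.random(int(L)), side="right").astype(np.int64)
        for L in lengths
    )
    names = tuple(f"{prefix}{i + 1}" for i in range(n))
    return SequenceSet(names=names, encoded=encoded, alphabet=background.alphabet)


@dataclass(frozen=True)
class PlantedMotifSpec:
    """A planted-motif benchmark: consensus, noise, occurrences, and shape."""

    consensus: str
    n_seqs: int
    length_min: int
    length_max: int
    background: BackgroundModel
    per_site_noise: float = 0.0
    occurrences_per_seq: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.per_site_noise < 1):
            raise ValueError("per_site_noise must be in [0, 1)")
        if self.occurrences_per_seq < 0:
            raise ValueError("occurrences_per_seq must be >= 0")
        if self.length_min > self.length_max or self.length_min < 1:
            raise ValueError("bad length range")
        m = len(self.consensus)
        if self.occurrences_per_seq * m > self.length_min:
            raise ValueError(
                f"{self.occurrences_per_seq} non-overlapping copies of a {m}-mer "
                f"cannot fit in a sequence of length {self.length_min}"
            )


def _mutate(
    motif: np.ndarray, noise: float, background: BackgroundModel, rng: np.random.Generator
) -> np.ndarray:
    """Per-site corruption: each position independently replaced with prob
    ``noise`` by a background-distributed draw over the *other* symbols."""
    out = motif.copy()
    size = background.p.size
    for j in range(out.size):
        if noise > 0 and rng.random() < noise:
            p = background.p.copy()
            p[out[j]] = 0.0
            p = p / p.sum()
            out[j] = rng.choice(size, p=p)
    return out


def plant_motifs(
    spec: PlantedMotifSpec, rng: np.random.Generator
) -> tuple[SequenceSet, list[list[int]]]:
    """Background sequences with non-overlapping mutated consensus copies planted.

    Returns the SequenceSet and, per sequence, the sorted list of 0-based
    planted start positions (ground truth for recovery scoring).
    """
    bg = spec.background
    bg.require_positive("planting motifs")
    alphabet = bg.alphabet
    consensus = alphabet.encode(spec.consensus, label="consensus")
    m = consensus.size
    cum = np.cumsum(bg.p)
    names = []
    encoded = []
    truth: list[list[int]] = []
    for i in range(spec.n_seqs):
        L = int(rng.integers(spec.length_min, spec.length_max + 1))
        seq = np.searchsorted(cum, rng.random(L), side="right").astype(np.int64)
        # rejection-sample non-overlapping starts
        starts: list[int] = []
        attempts = 0
        while len(starts) < spec.occurrences_per_seq:
            cand = int(rng.integers(0, L - m + 1))
            if all(abs(cand - s) >= m for s in starts):
                starts.append(cand)
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError("could not place non-overlapping motif copies")
        for s in sorted(starts):
            seq[s : s + m] = _mutate(consensus, spec.per_site_noise, bg, rng)
        names.append(f"Seq{i + 1}")
        encoded.append(seq)
        truth.append(sorted(starts))
    return (
        SequenceSet(names=tuple(names), encoded=tuple(encoded), alphabet=alphabet),
        truth,
    )


# -- the erythroid-style site-sampler benchmark ----------------------------

#: Overall composition of the 29-sequence erythroid benchmark: 1209 residues.
ERYTHROID_TOTALS = np.array([325, 316, 267, 301])
ERYTHROID_N_SEQS = 29
ERYTHROID_TOTAL_NT = 1209
ERYTHROID_CONSENSUS = "TTATCA"


def erythroid_spec(per_site_noise: float = 0.15) -> PlantedMotifSpec:
    """Planted-motif spec matching the erythroid benchmark's dimensions.

    29 sequences whose lengths average 1209/29 ~ 41.7 nt (drawn from 38..46
    so the expected total is 1209), background composition
    (325, 316, 267, 301)/1209, consensus TTATCA, one occurrence per sequence.
    """
    bg = BackgroundModel(
        p=ERYTHROID_TOTALS / ERYTHROID_TOTALS.sum(),
        alphabet=DNA,
        mode="user-specified",
        totals=ERYTHROID_TOTALS.copy(),
    )
    return PlantedMotifSpec(
        consensus=ERYTHROID_CONSENSUS,
        n_seqs=ERYTHROID_N_SEQS,
        length_min=38,
        length_max=45,  # uniform 38..45 has mean 41.5; close to 1209/29
        background=bg,
        per_site_noise=per_site_noise,
        occurrences_per_seq=1,
    )


# -- published worked-example fixtures --------------------------------------

# Site-specific counts of the 246 yeast donor splice sites (5 exonic +
# 12 intronic positions); columns A, C, G, U(T); each row sums to 246.
_SPLICE_COUNTS = """\
83 30 49 84
103 44 46 53
121 36 38 51
122 38 33 53
81 40 81 44
0 1 245 0
0 9 0 237
239 1 2 4
16 24 1 205
2 0 243 1
9 7 2 228
87 15 34 110
84 49 30 83
111 39 33 63
106 38 31 71
92 30 40 84
80 38 36 92
"""

#: Intron-wide background used with the splice-site matrix (A, C, G, U).
SPLICE_BACKGROUND = np.array([0.3279, 0.1915, 0.2043, 0.2763])


def splice_site_counts() -> CountMatrix:
    """The 17-site donor splice-site count matrix (246 aligned sites)."""
    rows = [
        [int(x) for x in line.split()] for line in _SPLICE_COUNTS.strip().splitlines()
    ]
    return CountMatrix(counts=np.array(rows).T, alphabet=DNA)


def splice_site_background() -> BackgroundModel:
    """Intron-wide nucleotide frequencies for the splice-site example."""
    return make_background("user-specified", SPLICE_BACKGROUND, DNA)


# Intermediate bookkeeping states of the worked Gibbs illustration
# (29 sequences, motif width 6).  Rows A, C, G, T.
_DEMO_STATES = {
    # initial random assignment: all 29 motifs in the tables
    "initial": {
        "c0": [278, 279, 230, 248],
        "c": [
            [8, 7, 9, 6, 10, 7],
            [3, 8, 5, 10, 6, 5],
            [7, 5, 6, 5, 3, 11],
            [11, 9, 9, 8, 10, 6],
        ],
    },
    # after withdrawing sequence 11's initial motif AGTGTG
    "withdrawn": {
        "c0": [279, 279, 233, 250],
        "c": [
            [7, 7, 9, 6, 10, 7],
            [3, 8, 5, 10, 6, 5],
            [7, 4, 6, 4, 3, 10],
            [11, 9, 8, 8, 9, 6],
        ],
    },
    # after depositing the new motif TCACAG at position 25
    "updated": {
        "c0": [277, 277, 232, 249],
        "c": [
            [7, 7, 10, 6, 11, 7],
            [3, 9, 5, 11, 6, 5],
            [7, 4, 6, 4, 3, 11],
            [12, 9, 8, 8, 9, 6],
        ],
    },
    # converged final alignment of the 29 discovered motifs
    "final": {
        "c0": [275, 285, 252, 223],
        "c": [
            [3, 0, 22, 0, 9, 16],
            [11, 0, 0, 0, 19, 1],
            [0, 7, 7, 0, 0, 1],
            [15, 22, 0, 29, 1, 11],
        ],
    },
}

#: The 40-nt sequence S11 rescored in the worked illustration, reconstructed
#: from its 35 overlapping 6-mers.
DEMO_S11 = "CATGCCCTCAAGTGTGCAGATTGGTCACAGCATTTCAAGG"

#: Published odds ratios for the 35 candidate starts of S11 against the
#: "withdrawn" state (1-based start -> odds).
DEMO_S11_ODDS = {
    1: 0.153, 2: 0.850, 3: 0.664, 4: 0.944, 5: 0.254, 6: 0.843, 7: 0.609,
    8: 0.717, 9: 0.613, 10: 0.426, 11: 0.967, 12: 0.546, 13: 0.594,
    14: 4.034, 15: 0.251, 16: 1.084, 17: 0.343, 18: 1.812, 19: 1.128,
    20: 0.408, 21: 1.194, 22: 0.888, 23: 1.005, 24: 0.596, 25: 5.888,
    26: 0.064, 27: 0.569, 28: 0.569, 29: 0.381, 30: 2.024, 31: 0.474,
    32: 1.317, 33: 4.293, 34: 2.475, 35: 1.279,
}


def gibbs_demo_states() -> dict[str, dict[str, np.ndarray]]:
    """The published C0/C bookkeeping states of the Gibbs walk-through."""
    return {
        name: {
            "c0": np.array(state["c0"], dtype=np.int64),
            "c": np.array(state["c"], dtype=np.int64),
        }
        for name, state in _DEMO_STATES.items()
    }


def gibbs_demo_sequence() -> str:
    """S11, the sequence rescored during the worked predictive update."""
    return DEMO_S11
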
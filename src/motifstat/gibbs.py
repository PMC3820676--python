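"""Gibbs site sampler for de novo motif discovery.

The site sampler assumes each input sequence carries exactly one occurrence
of an unknown motif of width ``m``.  Its state is the vector of motif start
positions A_i together with two count tables kept incrementally in sync with
it: ``C0``, the composition of all residues *outside* the current motif
windows, and ``C``, the (symbols x m) count matrix of the residues inside
them.  Residues are conserved: C0 plus the row sums of C always equals the
global symbol totals of the input.

One predictive-update step withdraws a sequence from the tables, builds a
weight matrix from the remaining N-1 motifs (background taken from C0 or
supplied by the caller), scores every candidate start in the withdrawn
sequence, picks a new start -- either by sampling proportionally to the
normalized odds or greedily by the maximum -- and deposits the sequence back.
A sweep visits every sequence once in a fresh random order (a fixed visiting
order is more prone to trapping the chain in a local optimum).  Alignment
quality is the information content F; the sampler keeps the best-F state per
restart and over restarts.

The motif-sampler extension (zero or many occurrences per sequence) is
realized by post-processing: re-scan the sequences with the final weight
matrix and keep every window whose odds ratio clears a cutoff (20 by
default, i.e. "motif" 20 times more likely than background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .background import BackgroundModel
from .io import SequenceSet, residue_counts
from .pwm import (
    CountMatrix,
    PseudocountSpec,
    PWMatrix,
    frequency_matrix,
    information_content,
    weight_matrix,
)

__all__ = [
    "GibbsState",
    "CandidateDistribution",
    "GibbsConfig",
    "GibbsResult",
    "MotifHit",
    "remove_window_counts",
    "add_window_counts",
    "initialize",
    "withdraw",
    "deposit",
    "state_pwm",
    "state_F",
    "candidate_scores",
    "candidate_distribution",
    "select_position",
    "sweep",
    "run_site_sampler",
    "motif_scan_postprocess",
]


# -- pure count bookkeeping -------------------------------------------------

def remove_window_counts(
    c0: np.ndarray, c: np.ndarray, window: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Move one motif window's residues out of C and into C0.

    Returns new (C0, C); inputs are not modified.  Raises if C would go
    negative (the window was not actually in the table).
    """
    c0 = c0.copy()
    c = c.copy()
    for j, sym in enumerate(window):
        c[sym, j] -= 1
        c0[sym] += 1
    if np.any(c < 0):
        raise ValueError("window is not present in the C matrix (double withdraw?)")
    return c0, c


def add_window_counts(
    c0: np.ndarray, c: np.ndarray, window: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Move one motif window's residues out of C0 and into C (inverse of remove)."""
    c0 = c0.copy()
    c = c.copy()
    for j, sym in enumerate(window):
        c[sym, j] += 1
        c0[sym] -= 1
    if np.any(c0 < 0):
        raise ValueError("C0 cannot supply the window's residues")
    return c0, c


@dataclass
class GibbsState:
    """Sampler state: assignments plus the synchronized C0 / C tables."""

    seqs: SequenceSet
    m: int
    assignments: np.ndarray  # 0-based starts; -1 marks a withdrawn sequence
    c0: np.ndarray
    c: np.ndarray
    totals: np.ndarray  # global symbol counts F_i, fixed for the run

    def window(self, i: int, start0: int | None = None) -> np.ndarray:
        s = self.assignments[i] if start0 is None else start0
        return self.seqs.encoded[i][s : s + self.m]

    @property
    def n_contributing(self) -> int:
        return int(np.sum(self.assignments >= 0))

    def check_invariants(self) -> None:
        """Residue conservation and column-sum laws; raises on violation."""
        n = self.n_contributing
        if not np.all(self.c.sum(axis=0) == n):
            raise AssertionError("C columns do not sum to the number of contributing sequences")
        if not np.all(self.c0 + self.c.sum(axis=1) == self.totals):
            raise AssertionError("residue conservation violated: C0 + rowsum(C) != totals")
        lengths = self.seqs.lengths
        for i, a in enumerate(self.assignments):
            if a >= 0 and not (0 <= a <= lengths[i] - self.m):
                raise AssertionError(f"assignment {a} out of range for sequence {i}")


@dataclass(frozen=True)
class CandidateDistribution:
    """Odds ratio per candidate start, plus the odds normalized to sum 1 (P_Norm)."""

    starts: np.ndarray  # 0-based
    odds: np.ndarray
    p_norm: np.ndarray


def _tabulate(seqs: SequenceSet, m: int, assignments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    size = seqs.alphabet.size
    c = np.zeros((size, m), dtype=np.int64)
    c0 = residue_counts(seqs)
    cols = np.arange(m)
    for i, a in enumerate(assignments):
        if a < 0:
            continue
        win = seqs.encoded[i][a : a + m]
        np.add.at(c, (win, cols), 1)
        c0 -= np.bincount(win, minlength=size)
    return c0, c


def initialize(seqs: SequenceSet, m: int, rng: np.random.Generator) -> GibbsState:
    """Random initialization: A_i uniform over the valid starts 0..L_i-m."""
    lengths = seqs.lengths
    if m < 1:
        raise ValueError("motif width must be >= 1")
    if np.any(lengths < m):
        short = int(np.argmin(lengths))
        raise ValueError(
            f"sequence {seqs.names[short]!r} (length {lengths[short]}) is shorter than m={m}"
        )
    assignments = np.array([rng.integers(0, L - m + 1) for L in lengths], dtype=np.int64)
    c0, c = _tabulate(seqs, m, assignments)
    return GibbsState(
        seqs=seqs, m=m, assignments=assignments, c0=c0, c=c, totals=residue_counts(seqs)
    )


def withdraw(state: GibbsState, i: int) -> GibbsState:
    """Remove sequence i's current motif from the tables (leave-one-out)."""
    if state.assignments[i] < 0:
        raise ValueError(f"sequence {i} is already withdrawn")
    c0, c = remove_window_counts(state.c0, state.c, state.window(i))
    assignments = state.assignments.copy()
    assignments[i] = -1
    return replace(state, assignments=assignments, c0=c0, c=c)


def deposit(state: GibbsState, i: int, new_start0: int) -> GibbsState:
    """Insert sequence i's motif at the (0-based) new start."""
    if state.assignments[i] >= 0:
        raise ValueError(f"sequence {i} is not withdrawn")
    L = state.seqs.lengths[i]
    if not (0 <= new_start0 <= L - state.m):
        raise ValueError(f"start {new_start0} invalid for sequence of length {L}")
    c0, c = add_window_counts(state.c0, state.c, state.window(i, new_start0))
    assignments = state.assignments.copy()
    assignments[i] = new_start0
    return replace(state, assignments=assignments, c0=c0, c=c)


# -- scoring ----------------------------------------------------------------

def _counts_to_pwm(
    c0: np.ndarray,
    c: np.ndarray,
    background: BackgroundModel | None,
    spec: PseudocountSpec,
    alphabet,
) -> PWMatrix:
    """Weight matrix from the C tables; background from C0 unless fixed."""
    if background is None:
        total = c0.sum()
        if total <= 0:
            raise ValueError("C0 is empty; cannot derive background frequencies")
        if np.any(c0 == 0):
            if spec.alpha == 0:
                raise ValueError(
                    "C0 has a zero symbol count and alpha=0; supply a fixed background"
                )
            # a symbol absent outside the motifs: spread the pseudocount mass
            # over the background so weights stay finite
            eps = spec.alpha * total / c0.shape[0]
            p = (c0 + eps) / (total + eps * c0.shape[0])
        else:
            p = c0 / total
        background = BackgroundModel(
            p=p, alphabet=alphabet, mode="from-input", totals=c0.copy()
        )
    counts = CountMatrix(counts=c, alphabet=alphabet)
    return weight_matrix(frequency_matrix(counts, background, spec), background)


def state_pwm(
    state: GibbsState,
    background: BackgroundModel | None = None,
    spec: PseudocountSpec = PseudocountSpec(),
) -> PWMatrix:
    """The weight matrix implied by the current tables (C0 background unless fixed)."""
    return _counts_to_pwm(state.c0, state.c, background, spec, state.seqs.alphabet)


def state_F(
    state: GibbsState,
    background: BackgroundModel | None = None,
    spec: PseudocountSpec = PseudocountSpec(),
) -> float:
    """Information content F of the current alignment."""
    pwm = state_pwm(state, background, spec)
    return information_content(CountMatrix(counts=state.c, alphabet=state.seqs.alphabet), pwm)


def candidate_distribution(
    c0: np.ndarray,
    c: np.ndarray,
    seq: np.ndarray,
    background: BackgroundModel | None = None,
    spec: PseudocountSpec = PseudocountSpec(),
    alphabet=None,
    windows: np.ndarray | None = None,
) -> CandidateDistribution:
    """Odds ratios for every candidate start of ``seq`` against the C tables.

    ``windows`` may carry a precomputed sliding-window view of the encoded
    sequence (performance path for the sampler loop).
    """
    from .alphabet import DNA

    alphabet = alphabet or DNA
    pwm = _counts_to_pwm(c0, c, background, spec, alphabet)
    m = pwm.width
    if windows is None:
        if seq.size < m:
            raise ValueError("sequence shorter than the motif width")
        windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    scores = pwm.w[windows, np.arange(m)].sum(axis=1)
    odds = np.exp2(scores)
    total = odds.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("all candidate odds are zero or non-finite")
    return CandidateDistribution(
        starts=np.arange(windows.shape[0]), odds=odds, p_norm=odds / total
    )


def candidate_scores(
    state: GibbsState,
    i: int,
    background: BackgroundModel | None = None,
    spec: PseudocountSpec = PseudocountSpec(),
) -> CandidateDistribution:
    """Candidate distribution for the withdrawn sequence ``i``."""
    if state.assignments[i] >= 0:
        raise ValueError(f"sequence {i} must be withdrawn before rescoring")
    return candidate_distribution(
        state.c0, state.c, state.seqs.encoded[i], background, spec, state.seqs.alphabet
    )


def select_position(
    dist: CandidateDistribution,
    strategy: Literal["sample", "argmax"],
    rng: np.random.Generator | None = None,
) -> int:
    """Pick the new start: multinomial draw on P_Norm, or the greedy maximum.

    Greedy ties break to the lowest start index (deterministic).
    """
    if strategy == "sample":
        if rng is None:
            raise ValueError("sample strategy needs an rng")
        return int(dist.starts[rng.choice(dist.starts.size, p=dist.p_norm)])
    if strategy == "argmax":
        return int(dist.starts[int(np.argmax(dist.odds))])
    raise ValueError(f"unknown strategy {strategy!r}")


def sweep(
    state: GibbsState,
    rng: np.random.Generator,
    background: BackgroundModel | None = None,
    spec: PseudocountSpec = PseudocountSpec(),
    strategy: Literal["sample", "argmax"] = "sample",
    order: Sequence[int] | None = None,
    windows: list[np.ndarray] | None = None,
    mask: dict[int, set[int]] | None = None,
) -> tuple[GibbsState, float]:
    """One full predictive-update pass; returns the updated state and its F.

    Each sequence is withdrawn, rescored against the other N-1, and
    redeposited, visiting sequences in ``order`` (a fresh uniform random
    permutation when not given).  ``mask`` forbids specific starts per
    sequence (used to exclude previously reported motifs).
    """
    n = len(state.seqs)
    if order is None:
        order = rng.permutation(n)
    cols = np.arange(state.m)
    c0, c = state.c0.copy(), state.c.copy()
    assignments = state.assignments.copy()
    for i in order:
        win = state.seqs.encoded[i][assignments[i] : assignments[i] + state.m]
        # inline withdraw
        np.subtract.at(c, (win, cols), 1)
        c0 += np.bincount(win, minlength=c0.shape[0])
        w = windows[i] if windows is not None else np.lib.stride_tricks.sliding_window_view(
            state.seqs.encoded[i], state.m
        )
        dist = candidate_distribution(
            c0, c, state.seqs.encoded[i], background, spec, state.seqs.alphabet, windows=w
        )
        if mask and i in mask:
            odds = dist.odds.copy()
            odds[list(mask[i])] = 0.0
            total = odds.sum()
            if total <= 0:
                raise ValueError(f"mask removes every candidate of sequence {i}")
            dist = CandidateDistribution(starts=dist.starts, odds=odds, p_norm=odds / total)
        new_start = select_position(dist, strategy, rng)
        assignments[i] = new_start
        win = state.seqs.encoded[i][new_start : new_start + state.m]
        np.add.at(c, (win, cols), 1)
        c0 -= np.bincount(win, minlength=c0.shape[0])
    new_state = replace(state, assignments=assignments, c0=c0, c=c)
    return new_state, state_F(new_state, background, spec)


@dataclass(frozen=True)
class GibbsConfig:
    """Run parameters for the multi-restart site sampler."""

    max_sweeps: int = 200
    restarts: int = 20
    patience: int = 3  # sweeps without F improvement that end a restart
    strategy: Literal["sample", "argmax"] = "sample"
    background: BackgroundModel | None = None  # None = derive from C0
    spec: PseudocountSpec = field(default_factory=PseudocountSpec)
    seed: int = 0
    # stop early once the best local optimum has been reproduced by this many
    # restarts; None runs every restart.  Off by default: near-optimal
    # attractors (e.g. one-column phase shifts) can repeat before the true
    # optimum is ever visited, and restarts are cheap.
    stop_on_repeat: int | None = None


@dataclass(frozen=True)
class MotifHit:
    name: str
    motif: str
    start: int  # 0-based
    odds: float


@dataclass(frozen=True)
class GibbsResult:
    state: GibbsState
    F: float
    hits: tuple[MotifHit, ...]
    mean_odds: float
    sd_odds: float
    seed: int
    restarts_run: int

    @property
    def assignments(self) -> np.ndarray:
        return self.state.assignments


def run_site_sampler(
    seqs: SequenceSet,
    m: int,
    config: GibbsConfig = GibbsConfig(),
    mask: dict[int, set[int]] | None = None,
) -> GibbsResult:
    """Multi-restart Gibbs site sampler; returns the highest-F alignment found.

    Each restart re-initializes at random and hill-climbs on F: sweeps
    continue until ``patience`` consecutive sweeps bring no F improvement or
    ``max_sweeps`` is reached, and the best-F state of the restart is kept.
    The run ends after ``restarts`` restarts, or earlier once two restarts
    converge to the identical assignment vector.  Fully deterministic given
    the seed.
    """
    if config.background is None and float(np.mean(seqs.lengths)) < 5 * m:
        warnings.warn(
            "mean sequence length < 5x motif width: a C0-derived background is "
            "biased for short sequences; consider a fixed background",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    windows = [
        np.lib.stride_tricks.sliding_window_view(e, m) for e in seqs.encoded
    ]
    best_state: GibbsState | None = None
    best_F = -np.inf
    best_key: tuple[int, ...] | None = None
    solution_counts: dict[tuple[int, ...], int] = {}
    restarts_run = 0
    for _ in range(config.restarts):
        restarts_run += 1
        state = initialize(seqs, m, rng)
        local_best = state
        local_F = state_F(state, config.background, config.spec)
        stale = 0
        for _ in range(config.max_sweeps):
            state, F = sweep(
                state,
                rng,
                config.background,
                config.spec,
                config.strategy,
                windows=windows,
                mask=mask,
            )
            if F > local_F + 1e-9:
                local_F, local_best = F, state
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        key = tuple(int(a) for a in local_best.assignments)
        solution_counts[key] = solution_counts.get(key, 0) + 1
        if local_F > best_F:
            best_F, best_state, best_key = local_F, local_best, key
        # optional convergence stop: best local optimum reproduced independently
        if (
            config.stop_on_repeat is not None
            and solution_counts.get(best_key, 0) >= config.stop_on_repeat
        ):
            break
    assert best_state is not None
    pwm = state_pwm(best_state, config.background, config.spec)
    hits = []
    odds_list = []
    for i in range(len(seqs)):
        start = int(best_state.assignments[i])
        win = best_state.window(i)
        score = float(pwm.w[win, np.arange(m)].sum())
        odds = float(2.0**score)
        odds_list.append(odds)
        hits.append(
            MotifHit(name=seqs.names[i], motif=seqs.alphabet.decode(win), start=start, odds=odds)
        )
    odds_arr = np.array(odds_list)
    return GibbsResult(
        state=best_state,
        F=best_F,
        hits=tuple(hits),
        mean_odds=float(odds_arr.mean()),
        sd_odds=float(odds_arr.std(ddof=1)) if odds_arr.size > 1 else 0.0,
        seed=config.seed,
        restarts_run=restarts_run,
    )


def motif_scan_postprocess(
    pwm: PWMatrix,
    seqs: SequenceSet,
    cutoff_odds: float = 20.0,
) -> dict[str, list[MotifHit]]:
    """Motif-sampler style re-scan: keep every window with odds > cutoff.

    A sequence may contribute zero, one, or many hits; overlaps are not
    suppressed.
    """
    if not pwm.finite:
        raise ValueError("post-processing needs a finite weight matrix")
    m = pwm.width
    out: dict[str, list[MotifHit]] = {}
    cols = np.arange(m)
    for name, enc in seqs:
        hits: list[MotifHit] = []
        if enc.size >= m:
            wins = np.lib.stride_tricks.sliding_window_view(enc, m)
            scores = pwm.w[wins, cols].sum(axis=1)
            odds = np.exp2(scores)
            for start in np.flatnonzero(odds > cutoff_odds):
                hits.append(
                    MotifHit(
                        name=name,
                        motif=seqs.alphabet.decode(wins[start]),
                        start=int(start),
                        odds=float(odds[start]),
                    )
                )
        out[name] = hits
    return out
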
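# Methods

This note documents the models implemented in `motifstat`, the numerical
conventions behind them, and what the synthetic benchmarks do and do not
demonstrate.

## Position weight matrices

Given `N` aligned motif windows of width `L` over an alphabet of `N_code`
symbols (4 for nucleotides, 20 for amino acids), the site-specific counts
`f_ij` are converted to frequencies `p_ij` and compared with background
frequencies `p_i`:

    PWM_ij = log2(p_ij / p_i)          (bits)
    PWMS(window) = sum_j PWM_{w_j, j}  (the log2 likelihood ratio)

`PWMS` is the log-odds of the hypothesis "this window is a motif occurrence,
with site-specific residue preferences" against "this window is background,
each residue drawn independently from `p_i`"; `2^PWMS` is the corresponding
odds ratio.

**Backgrounds.** Three modes: uniform, computed from the input sequences, or
user-specified. The user-specified, problem-matched background (genome-wide
or intron-wide frequencies, for instance) is the recommended default. An
input-derived background has a pathology: a perfectly conserved motif set
(all sequences `UUUU...`) yields `p_U = 1` and a flat, uninformative matrix.
A uniform background in an AT-rich genome manufactures apparent A/T
preferences with no site-specific signal. Zero background entries may be
stored but any operation dividing by `p_i` raises immediately.

**Pseudocounts.** Zero counts make `log2` undefined, so four regularization
schemes are provided:

| scheme | `p_ij` | notes |
|---|---|---|
| `add-background` | `(f_ij + p_i) / (N + 1)` | one background-distributed pseudo-observation; poor at small N |
| `scaled-counts` (default) | `(f_ij + α p_i N) / (N (1 + α))` | pseudocount mass proportional to the data mass |
| `scaled-totals` | `(f_ij + α F_i) / (N + α ΣF)` | mass proportional to the background's raw symbol totals `F_i` |
| `user-vector` | `(f_ij + v_i) / (N + Σv)` | arbitrary data-driven pseudocounts supplied by the caller |

The default is `scaled-counts` with `α = 0.0001` (unitless). A small α keeps
the expected weight of random sequences near 0; the two `scaled-*` variants
exist because "pseudocount proportional to the frequency of symbol i" can be
read against either the background proportion or the raw totals — the
proportional reading is the default since its pseudocount mass is
independent of how much sequence happened to surround the motifs. Cells
that remain zero (α = 0) are stored as `-inf`, and any scoring operation
that touches such a cell raises rather than silently propagating `-inf`
through a sum.

**Conventions.** Log base 2 everywhere (bits). Coordinates are 0-based
half-open internally; the CLI reports 1-based starts by default with
`--coords 0` available, since both conventions are common in published
motif tables. Reverse-complement scanning is off by default (`--strand
both` appends minus-strand windows tagged and indexed by their
forward-strand start).

## Information content F

    F = sum_i sum_j C_ij * PWM_ij     (bits · counts)

where `C` is the count matrix of the aligned motifs. With α = 0 and the
background equal to the pooled column frequencies, `F = N · Σ_j
KL(column_j ‖ background) ≥ 0` — a count-weighted Kullback–Leibler
alignment-quality score. It is the hill-climbing objective of the Gibbs
sampler and the statistic of the resampling matrix test.

A consequence used by the tests: under the null (columns drawn i.i.d. from
the background) and large `N`, `F` is asymptotically
`χ²_{(N_code−1)·L} / (2 ln 2)`: the count weighting cancels the `1/N`
shrinkage of the sampling noise, so null critical values of `F` are nearly
independent of `N`. `F` grows with `N` only when a genuine site-specific
signal is present.

## Gibbs site sampler

The site sampler assumes exactly one motif occurrence of width `m` per
sequence. State: start positions `A_i`, the outside-motif composition
vector `C0`, and the inside-motif count matrix `C`. Residues are conserved:
`C0 + rowsum(C)` equals the global symbol totals after every operation (an
exact integer identity, asserted by `GibbsState.check_invariants`).

One predictive update: withdraw sequence `i` from the tables, build a
weight matrix from the remaining `N−1` motifs (background from the
normalized `C0` by default, or fixed by the caller), score the `L_i − m + 1`
candidate starts, select a new start, deposit. Selection is either a
multinomial draw proportional to the normalized odds (`sample`, the
default) or the greedy maximum (`argmax`, ties to the lowest start). A
sweep visits all sequences once in a fresh uniform random permutation —
a fixed visiting order is more prone to trapping the chain.

Per restart, sweeps continue until `patience` (default 3) consecutive
sweeps bring no F improvement or `max_sweeps` (200) is reached; the best-F
state of the restart is retained, so the sequence of accepted F values is
non-decreasing by construction. The run keeps the best state over
`restarts` (default 20) random initializations.

**Convergence across restarts.** An optional early stop ends the run once
the best local optimum has been reproduced by `stop_on_repeat` independent
restarts. It is *off* by default: near-optimal attractors exist whose basin
rivals the true optimum's — most prominently the ±1 *phase shift*, the
alignment of all sequences one column off the true motif, which scores
`m−1` conserved columns and is a fixed point of single-sequence updates.
On noise-free planted data the shifted solution can repeat across restarts
before the true basin is visited, so stopping at the first repeat
measurably costs recovery, while completing all restarts is cheap. Phase-
shift proposal moves (shifting the whole alignment by ±1 as a single move)
are a known refinement and are out of scope here; restarts carry that
burden instead.

**Short sequences.** When the mean sequence length is below `5·m`, a
`C0`-derived background is biased (the motif's own composition leaks into
the background, penalizing motif-like candidates), so the sampler warns
and recommends a fixed background.

**Motif-sampler post-processing.** The one-occurrence assumption is relaxed
by re-scanning the input with the final weight matrix and keeping every
window whose odds ratio exceeds a cutoff (default 20, i.e. the motif
hypothesis 20× more likely than background). Sequences may contribute
zero, one, or many hits; overlaps are not suppressed. Masking previously
reported windows (`mask` argument) lets a second run search for weaker
secondary motifs.

## Significance tests

**Per-site χ².** Each motif column is tested against expected counts
`N·p_i`: plain Pearson statistic, `df = N_code − 1`, no continuity
correction, no pooling of small cells (the published worked-example values
reproduce only under exactly this convention). Multiplicity over the `L`
sites is handled by:

- familywise corrections — exact `1−(1−α₀)^{1/N}`, Bonferroni `α₀/N`, and
  the second-order rule `Nα−(N−1)α² = α₀` solved by the quadratic formula
  (small root). At `N = 17` the three differ by under 3% relative;
- FDR step-up — Benjamini–Hochberg criticals `q·i/N` at ascending-p rank
  `i`, Benjamini–Yekutieli dividing them by the harmonic sum `Σ 1/k`
  (valid under arbitrary dependence). The largest qualifying rank `k`
  rejects ranks `1..k`. Ties sort stably and share the most favorable
  qualifying rank; the BY rejection set is always a subset of BH's.

**Resampling test of the matrix.** Pseudocounts shift the null of `F` above
zero, so `F` is calibrated empirically: `reps` (default 5000) datasets of
the observed shape are drawn i.i.d. from the background, each is pushed
through the identical counts → frequencies → weights pipeline, and the
95th/99th percentiles of the null `F` are the critical values. The
replicate loop is vectorized (drawing, tabulating, and scoring all
replicates in chunked array operations), which keeps the 2000 × 500
calibration experiment in seconds.

**Extreme-value test of the best score.** The score of one random window is
approximately normal; its `(μ, σ)` are estimated by scoring `n_samples`
(default 1000) background-drawn windows. The maximum of `N` scanned
windows then has CDF `Φ((x−μ)/σ)^N`, giving the closed-form tail

    P(max ≥ x_obs) = 1 − Φ((x_obs−μ)/σ)^N

evaluated in log space for stability. A quadrature evaluation of the
equivalent extreme-value density `N·p(x)·G(x)^{N−1}` is provided as a
cross-check and agrees to 1e-6. Two printed-formula corrections are
deliberate: the null density's exponent is negative (the standard normal
density), and the lower integration limit of `G` is `−∞`, not 0 — scores
can be negative, and only a proper CDF makes `1 − G^N` a probability.
The quick alternative is the Bonferroni-corrected normal quantile
`μ + z_{α₀/N}·σ`, with `N` always the computed window count of the scan.

## Synthetic benchmarks

`random_sequences` draws i.i.d. residues from a background model (the
"tetranomial" null). `plant_motifs` embeds, per sequence, a fixed number of
non-overlapping copies of a consensus at uniformly random valid starts,
each position independently corrupted with probability `per_site_noise` by
a background-distributed draw over the other symbols — the simplest
corruption consistent with the PWM's site-independence assumption. Ground
truth starts are returned for recovery scoring.

The `erythroid` preset emulates the dimensions of the classic 29-sequence
GATA site-sampler benchmark: 29 sequences with lengths uniform on 38–45
(expected total ≈ 1209 nt), background composition (325, 316, 267, 301)/1209,
consensus `TTATCA`, one occurrence per sequence, per-site noise 0.15. The
original sequences were never published in machine-readable form; only the
dimensions and composition are emulated, so results on this preset
characterize the algorithm under realistic conditions, not the original
dataset.

**Recovery metric.** A reported site counts as recovered when its window
overlaps the planted window (standard site-level sensitivity in motif-
discovery assessment); a run recovers the motif when more than half of its
sites are recovered. Exact-start recovery is also reported but is not a
meaningful target at noise 0.15: a planted copy carrying two or more
mutations is often genuinely outscored by a background pseudo-site, and
the measured F of the sampler's solution exceeds the F of the planted
truth — the objective, not the optimizer, moves those assignments. On
noise-free planted data, exact recovery of every site is the expectation
and is asserted.

## Problem sizes and determinism

All stochastic procedures take an explicit seed (`numpy.random.Generator`)
and are bit-reproducible given it. Default replicate counts follow the
recommended practice: 5000 resampling replicates for the matrix test, 1000
windows for the null-normal fit. The packaged calibration experiments use
2000 outer × 500 inner replicates for the type-I error of the resampling
test (expected rate ≈ 0.052 by the order statistics of a 500-sample
percentile) and 50 seeded sampler runs for planted-motif recovery, sizes
chosen to give stable estimates at interactive runtimes.

## Known limitations

- Single-motif, fixed-width model; no gapped motifs, no dinucleotide or
  higher-order backgrounds, no simultaneous multi-width search.
- No phase-shift/column-shift refinement moves in the sampler (restarts
  substitute).
- The published PWM cells of the splice-site worked example reproduce only
  to ±0.02 bits: the printed background is rounded to four decimals and the
  table's own χ² column, which does match, is treated as authoritative.
- Sequence logos are not rendered; matrices export as TSV or MEME minimal
  format for downstream tools.
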
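"""Significance tests for the three outputs of a PWM analysis.

1.  *Per-site frequencies*: a Pearson chi-square test of each motif column
    against the expected background counts, with the multiplicity of sites
    handled either by familywise error-rate corrections (exact, Bonferroni,
    second-order Bonferroni) or -- preferably -- by false discovery rate
    step-up procedures (Benjamini-Hochberg, Benjamini-Yekutieli).
2.  *The matrix itself*: pseudocounts shift the null distribution of the
    information content F away from zero, so F is calibrated by resampling:
    datasets of the same shape are drawn i.i.d. from the background and the
    empirical percentiles of their F values give the critical values.
3.  *Individual window scores*: the score of a random window is
    approximately normal; the maximum of N such scores from a scan follows
    the induced extreme-value distribution, giving a p-value for the best
    hit, with a Bonferroni-corrected normal quantile as the quick
    alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .background import BackgroundModel
from .pwm import CountMatrix, PseudocountSpec, PWMatrix, frequency_matrix, weight_matrix

__all__ = [
    "SiteTestResult",
    "MultipleTestingResult",
    "EVDModel",
    "chi2_site_test",
    "chi2_site_tests",
    "familywise_alpha",
    "fdr_critical",
    "null_f_values",
    "resample_f_null",
    "FNullResult",
    "fit_null_normal",
    "evd_max_pvalue",
    "evd_max_pvalue_quadrature",
    "bonferroni_max_critical",
    "normal_upper_limit",
]


# -- per-site chi-square ----------------------------------------------------

@dataclass(frozen=True)
class SiteTestResult:
    """Pearson chi-square of one motif column against the background."""

    chi2: float
    df: int
    p: float


def chi2_site_test(counts_row: np.ndarray, background: BackgroundModel) -> SiteTestResult:
    """Test one site's observed symbol counts against expected N * p_i.

    Plain Pearson statistic, df = alphabet size - 1, no continuity correction
    and no pooling of small cells.
    """
    obs = np.asarray(counts_row, dtype=float)
    background.require_positive("the chi-square site test")
    if obs.shape != background.p.shape:
        raise ValueError("counts row and background differ in length")
    n = obs.sum()
    if n <= 0:
        raise ValueError("site has zero total count")
    expected = n * background.p
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    return SiteTestResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def chi2_site_tests(counts: CountMatrix, background: BackgroundModel) -> list[SiteTestResult]:
    """One chi-square test per motif site (column)."""
    return [chi2_site_test(counts.counts[:, j], background) for j in range(counts.width)]


# -- familywise corrections -------------------------------------------------

def familywise_alpha(alpha0: float, n_tests: int, method: str = "exact") -> float:
    """Per-test significance level controlling the familywise rate alpha0.

    exact
        alpha = 1 - (1 - alpha0)**(1/N) (Dunn-Sidak).
    bonferroni
        alpha = alpha0 / N.
    second_order
        the root in (0, 1/N] of N*alpha - (N-1)*alpha**2 = alpha0.
    """
    if not (0 < alpha0 < 1):
        raise ValueError("alpha0 must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("need at least one test")
    n = float(n_tests)
    if method == "exact":
        return 1.0 - (1.0 - alpha0) ** (1.0 / n)
    if method == "bonferroni":
        return alpha0 / n
    if method == "second_order":
        if n_tests == 1:
            return alpha0
        # (N-1) a^2 - N a + alpha0 = 0; take the small root
        disc = n * n - 4.0 * (n - 1.0) * alpha0
        return (n - np.sqrt(disc)) / (2.0 * (n - 1.0))
    raise ValueError(f"unknown method {method!r}")


# -- false discovery rate ---------------------------------------------------

@dataclass(frozen=True)
class MultipleTestingResult:
    """Step-up FDR outcome over a family of p-values.

    ``order`` maps rank (ascending p) to the original hypothesis index;
    ``critical`` holds the per-rank critical values q*i/N (BH) optionally
    divided by the harmonic sum (BY); ``rejected`` flags hypotheses in the
    original input order.
    """

    method: str
    q: float
    pvalues: np.ndarray
    order: np.ndarray
    critical: np.ndarray
    rejected: np.ndarray
    harmonic_sum: float | None = None

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def fdr_critical(pvalues, q: float = 0.05, method: str = "BH") -> MultipleTestingResult:
    """Benjamini-Hochberg or Benjamini-Yekutieli step-up procedure.

    Ranks are assigned in ascending-p order; the critical value at rank i is
    q*i/N, divided for BY by the harmonic sum H_N = sum_{k=1..N} 1/k.  The
    largest rank k with p_(k) <= critical_k determines the rejection set
    {ranks 1..k}.  Tied p-values sort stably and thus share the outcome of
    the most favorable (largest) qualifying rank, the standard step-up
    behaviour.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    method = method.upper()
    n = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    critical = q * ranks / n
    harmonic = None
    if method == "BY":
        harmonic = float(np.sum(1.0 / ranks))
        critical = critical / harmonic
    elif method != "BH":
        raise ValueError(f"unknown FDR method {method!r}")
    sorted_p = p[order]
    qualifying = np.flatnonzero(sorted_p <= critical)
    rejected = np.zeros(n, dtype=bool)
    if qualifying.size:
        k = qualifying[-1] + 1  # step-up: reject ranks 1..k
        rejected[order[:k]] = True
    return MultipleTestingResult(
        method=method,
        q=q,
        pvalues=p,
        order=order,
        critical=critical,
        rejected=rejected,
        harmonic_sum=harmonic,
    )


# -- resampling null for the information content F --------------------------

def null_f_values(
    background: BackgroundModel,
    n_seqs: int,
    width: int,
    reps: int,
    spec: PseudocountSpec = PseudocountSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """F values of ``reps`` datasets drawn i.i.d. from the background.

    Each replicate draws an (n_seqs x width) block of residues from the
    multinomial background, tabulates the count matrix, builds the weight
    matrix with the same pseudocount spec as the observed analysis, and
    evaluates F.  Fully vectorized over replicates.
    """
    background.require_positive("resampling the F null")
    if rng is None:
        rng = np.random.default_rng()
    size = background.p.size
    p = background.p
    if spec.scheme not in ("scaled-counts", "add-background"):
        raise ValueError("null_f_values supports the scaled-counts and add-background schemes")
    cum = np.cumsum(p)
    out = np.empty(reps)
    chunk = max(1, min(reps, 50_000_000 // max(1, n_seqs * width)))
    pos = 0
    while pos < reps:
        r = min(chunk, reps - pos)
        draws = np.searchsorted(cum, rng.random((r, n_seqs, width)), side="right")
        # counts[rep, site, symbol] via one shared bincount
        flat = (np.arange(r)[:, None, None] * width + np.arange(width)[None, None, :]) * size + draws
        counts = np.bincount(flat.ravel(), minlength=r * width * size).reshape(r, width, size)
        counts = counts.transpose(0, 2, 1).astype(float)  # (rep, symbol, site)
        if spec.scheme == "scaled-counts":
            pseudo = spec.alpha * p * n_seqs
        else:  # add-background
            pseudo = p
        pij = (counts + pseudo[:, None]) / (n_seqs + pseudo.sum())
        w = np.log2(pij / p[:, None])
        out[pos : pos + r] = (counts * w).sum(axis=(1, 2))
        pos += r
    return out


@dataclass(frozen=True)
class FNullResult:
    """Empirical null distribution of F with its upper critical values."""

    percentiles: dict[float, float]
    critical_05: float
    critical_01: float
    reps: int
    values: np.ndarray


def resample_f_null(
    background: BackgroundModel,
    n_seqs: int,
    width: int,
    reps: int = 5000,
    spec: PseudocountSpec = PseudocountSpec(),
    rng: np.random.Generator | None = None,
) -> FNullResult:
    """Resampling null for F; the 95th/99th percentiles are the critical values."""
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    values = null_f_values(background, n_seqs, width, reps, spec, rng)
    pct_points = (50.0, 90.0, 95.0, 99.0)
    pct = {q: float(np.percentile(values, q)) for q in pct_points}
    return FNullResult(
        percentiles=pct,
        critical_05=pct[95.0],
        critical_01=pct[99.0],
        reps=reps,
        values=values,
    )


# -- extreme-value significance of the maximum window score -----------------

@dataclass(frozen=True)
class EVDModel:
    """Normal null for a single window score plus the number of scanned windows."""

    mu: float
    sigma: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_windows < 1:
            raise ValueError("need at least one window")


def fit_null_normal(
    pwm: PWMatrix,
    background: BackgroundModel,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Estimate (mu, sigma) of the null score by scoring random windows.

    Draws ``n_samples`` windows of the matrix width i.i.d. from the
    background and returns the sample mean and standard deviation of their
    scores.  With small pseudocounts the mean sits slightly above zero.
    """
    if not pwm.finite:
        raise ValueError("null fitting needs a finite weight matrix")
    background.require_positive("sampling null windows")
    if rng is None:
        rng = np.random.default_rng()
    cum = np.cumsum(background.p)
    draws = np.searchsorted(cum, rng.random((n_samples, pwm.width)), side="right")
    scores = pwm.w[draws, np.arange(pwm.width)].sum(axis=1)
    sd = float(scores.std(ddof=1)) if n_samples > 1 else 0.0
    return float(scores.mean()), sd


def evd_max_pvalue(model: EVDModel, x_obs: float) -> float:
    """P(max of N null scores >= x_obs) under the fitted normal null.

    Closed form 1 - Phi(z)**N with z = (x_obs - mu)/sigma: the maximum of N
    independent normal draws falls below x exactly when all N do.
    """
    if not np.isfinite(x_obs):
        raise ValueError("x_obs must be finite")
    z = (x_obs - model.mu) / model.sigma
    # log-space for numerical stability when Phi(z)**N underflows to 1
    log_cdf_n = model.n_windows * stats.norm.logcdf(z)
    return float(-np.expm1(log_cdf_n))


def evd_max_pvalue_quadrature(model: EVDModel, x_obs: float) -> float:
    """Quadrature evaluation of the same tail probability.

    Integrates the extreme-value density N * p(x) * G(x)**(N-1) (p the normal
    density, G its CDF) from x_obs upward; cross-checks the closed form.
    """
    if not np.isfinite(x_obs):
        raise ValueError("x_obs must be finite")
    mu, sigma, n = model.mu, model.sigma, model.n_windows

    def density(x: float) -> float:
        return n * stats.norm.pdf(x, mu, sigma) * stats.norm.cdf(x, mu, sigma) ** (n - 1)

    upper = mu + 12 * sigma
    if x_obs >= upper:
        return 0.0
    val, _ = integrate.quad(density, x_obs, upper, limit=200)
    return float(val)


def bonferroni_max_critical(
    mu: float, sigma: float, alpha0: float, n_windows: int
) -> float:
    """Score needed for the best of ``n_windows`` to reach familywise alpha0.

    mu + z * sigma with z the upper-tail normal quantile at alpha0/n_windows.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    per_test = alpha0 / n_windows
    if per_test >= 1:
        raise ValueError("alpha0/n_windows must be < 1")
    return float(mu + stats.norm.isf(per_test) * sigma)


def normal_upper_limit(mu: float, sigma: float, z: float) -> float:
    """Single-test upper confidence limit mu + z * sigma (e.g. z = 2.58 for 99%)."""
    return float(mu + z * sigma)
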
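"""Validation and inferential statistics for contamination surveys.

Implements the percentage-deviation descriptives used to validate mixture
recovery, the chi-square one-sample proportion test (no continuity
correction, null proportion 0.5) used for contaminated-vs-uncontaminated
counts, and Pearson contingency tests with Cramer's V effect size and a
row-wise multinomial bootstrap confidence interval.

Far-tail p-values (down to ~1e-300) come from the regularized upper
incomplete gamma function, so values like 1e-18 are computed to full
relative precision rather than underflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


def chi2_sf(x: float, df: int) -> float:
    """Chi-square survival function P(X >= x) via Q(df/2, x/2)."""
    if x < 0 or df < 1:
        raise ValueError("need x >= 0 and df >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


# ---------------------------------------------------------------------------
# Percentage deviations (expected - observed), descriptives on absolute values

def percentage_deviation(expected, observed) -> np.ndarray:
    """Element-wise expected - observed, sign preserved."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape:
        raise ValueError("expected and observed must have the same shape")
    return e - o


@dataclass(frozen=True)
class DeviationStats:
    n: int
    min: float
    max: float
    median: float
    mean_abs: float
    sd: float
    variance: float
    degenerate: bool  # n == 1: sd/variance reported as 0 by convention


def describe_deviations(deviations) -> DeviationStats:
    """Descriptive statistics of percentage deviations.

    All statistics are computed on absolute deviations (the convention of
    the validation summary): mean of |d|, median/sd/variance of |d| with
    the sample (n-1) denominator, min and max of |d|.
    """
    d = np.abs(np.asarray(deviations, dtype=float))
    if d.size == 0:
        raise ValueError("no deviations given")
    degenerate = d.size == 1
    sd = 0.0 if degenerate else float(np.std(d, ddof=1))
    return DeviationStats(
        n=int(d.size),
        min=float(d.min()),
        max=float(d.max()),
        median=float(np.median(d)),
        mean_abs=float(d.mean()),
        sd=sd,
        variance=sd ** 2,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Chi-square proportion test (no continuity correction)

@dataclass(frozen=True)
class ProportionTestResult:
    k: int
    n: int
    p0: float
    chi2: float
    df: int
    p_value: float


def prop_test(k: int, n: int, p0: float = 0.5) -> ProportionTestResult:
    """One-sample proportion test: chi2 = n (k/n - p0)^2 / (p0 (1 - p0)).

    Equivalent to the square of the one-sample z statistic; no Yates
    correction is applied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    chi2 = n * (k / n - p0) ** 2 / (p0 * (1 - p0))
    return ProportionTestResult(k, n, p0, float(chi2), 1, chi2_sf(chi2, 1))


# ---------------------------------------------------------------------------
# Contingency test with Cramer's V

@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, ...], ...]
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    v_ci_low: float
    v_ci_high: float
    n_obs: int


def _pearson_chi2(tables: np.ndarray) -> np.ndarray:
    """Pearson chi-square for a batch of tables, shape (..., r, c)."""
    t = tables.astype(float)
    n = t.sum(axis=(-2, -1), keepdims=True)
    rows = t.sum(axis=-1, keepdims=True)
    cols = t.sum(axis=-2, keepdims=True)
    expected = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=(-2, -1))


def contingency_test(
    table,
    bootstrap_reps: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ContingencyResult:
    """Pearson chi-square test of independence with Cramer's V.

    V = sqrt(chi2 / (n_obs * min(r-1, c-1))).  The 95% CI on V is a
    nonparametric bootstrap over rows: each row is resampled as a
    multinomial of its own total, V recomputed per replicate, and the
    percentile interval taken (degenerate replicates with an empty column
    are dropped).  Deterministic under a fixed seed.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or t.sum() == 0:
        raise ValueError("table must be non-negative with a positive total")
    r, c = t.shape
    n_obs = int(t.sum())
    chi2 = float(_pearson_chi2(t))
    df = (r - 1) * (c - 1)
    p = chi2_sf(chi2, df)
    v = float(np.sqrt(chi2 / (n_obs * min(r - 1, c - 1))))

    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, r, c), dtype=np.int64)
    for i in range(r):
        row_total = int(t[i].sum())
        probs = t[i] / row_total if row_total else np.full(c, 1.0 / c)
        boot[:, i, :] = rng.multinomial(row_total, probs, size=bootstrap_reps)
    valid = (boot.sum(axis=1) > 0).all(axis=1)
    chi2_b = _pearson_chi2(boot[valid])
    v_b = np.sqrt(chi2_b / (n_obs * min(r - 1, c - 1)))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(v_b, [alpha / 2, 1 - alpha / 2])
    return ContingencyResult(
        table=tuple(tuple(int(x) for x in row) for row in t),
        chi2=chi2, df=df, p_value=p, cramers_v=v,
        v_ci_low=float(lo), v_ci_high=float(hi), n_obs=n_obs,
    )
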
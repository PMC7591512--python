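"""Statistical procedures used throughout the pipeline.

Welch's unequal-variance t-test, Pearson chi-squared tests (goodness of
fit and 2x2, no continuity correction), Benjamini-Hochberg step-up
adjustment and squared Pearson correlation.  The test statistics are
computed here from their closed forms; tail probabilities come from
scipy's survival functions, which are log-space safe, so extremely small
p-values (1e-200 and below) are reported as computed rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "welch_ttest",
    "chi_square_gof",
    "chi_square_2x2",
    "bh_adjust",
    "pearson_r2",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def welch_ttest(values_a, values_b) -> TestResult:
    """Two-sided two-sample t-test assuming unequal variances.

    Degenerate groups (both variances zero) give p = 1 for equal means and
    p = 0 for different means, the limits of the statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        same = a.mean() == b.mean()
        return TestResult(
            0.0 if same else np.inf, float(na + nb - 2),
            1.0 if same else 0.0, "welch_ttest",
        )
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), min(float(p), 1.0), "welch_ttest")


def chi_square_gof(observed_counts, expected_proportions) -> TestResult:
    """Pearson goodness-of-fit chi-squared test, df = k - 1."""
    obs = np.asarray(observed_counts, dtype=float)
    prop = np.asarray(expected_proportions, dtype=float)
    if obs.shape != prop.shape:
        raise ValueError("observed and expected shapes differ")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be > 0")
    if not np.isclose(prop.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    exp = prop * obs.sum()
    if (exp == 0).any():
        raise ValueError("expected count of 0 in some class")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return TestResult(stat, float(df), float(sps.chi2.sf(stat, df)),
                      "chi_square_gof")


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-squared on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    exp = np.outer(rows, cols) / n
    stat = float(((t - exp) ** 2 / exp).sum())
    return TestResult(stat, 1.0, float(sps.chi2.sf(stat, 1)), "chi_square_2x2")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    vx, vy = (xc**2).sum(), (yc**2).sum()
    if vx == 0 or vy == 0:
        raise ValueError("zero variance")
    r = (xc * yc).sum() / np.sqrt(vx * vy)
    return float(r**2)
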
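"""Contrast test statistics and multivariate-t multiplicity adjustment.

For normal responses with a common variance the vector of model
contrast statistics follows, under the null, a central multivariate t
distribution with ``N - k - 1`` degrees of freedom and the correlation
matrix induced by the contrast coefficients and allocations.  Adjusted
p-values and equicoordinate critical values are obtained from that
distribution by randomized quasi-Monte-Carlo integration (seeded, with
an error estimate attached to every probability).

All tests are one-sided for a response *increase* over placebo; negate
the responses for endpoints where a decrease is the improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .contrasts import Contrast, correlation_matrix
from .models import DoseDesign

__all__ = [
    "TrialData",
    "SummaryStats",
    "TestResult",
    "summarize",
    "contrast_statistics",
    "equicoordinate_prob",
    "adjusted_pvalues",
    "critical_value",
    "max_t_test",
]

#: target absolute integration error for multivariate-t probabilities
MVT_ABSEPS = 1e-4
#: QMC points per probability evaluation (noise well below MVT_ABSEPS)
MVT_MAXPTS = 30_000
#: correlations within this of 1 mark numerically identical contrasts
_DUP_TOL = 1e-12
#: ridge applied to rank-deficient correlation matrices (see _regularize)
_RIDGE = 1e-7


@dataclass(frozen=True)
class TrialData:
    """Per-patient responses grouped by arm index (0 = placebo)."""

    arm: np.ndarray
    response: np.ndarray

    def __init__(self, arm: Sequence[int], response: Sequence[float]):
        arm = np.asarray(arm, dtype=int)
        response = np.asarray(response, dtype=float)
        if arm.shape != response.shape or arm.ndim != 1:
            raise ValueError("arm and response must be equal-length vectors")
        if not np.all(np.isfinite(response)):
            raise ValueError("responses must be finite")
        if np.any(arm < 0):
            raise ValueError("arm indices must be nonnegative")
        arm.flags.writeable = False
        response.flags.writeable = False
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "response", response)

    @classmethod
    def from_arm_responses(cls, groups: Sequence[Sequence[float]]) -> "TrialData":
        arm = np.concatenate([np.full(len(g), i, dtype=int)
                              for i, g in enumerate(groups)])
        y = np.concatenate([np.asarray(g, dtype=float) for g in groups])
        return cls(arm, y)

    def by_arm(self, n_arms: int) -> list[np.ndarray]:
        return [self.response[self.arm == i] for i in range(n_arms)]


@dataclass(frozen=True)
class SummaryStats:
    """Arm means, pooled variance and its degrees of freedom.

    The pooled variance always uses *all* arms of the design, also when
    later tests restrict attention to a subset of doses.
    """

    means: np.ndarray
    s2: float
    df: int
    allocations: tuple[int, ...]

    def __init__(self, means, s2: float, df: int, allocations):
        means = np.asarray(means, dtype=float)
        allocations = tuple(int(n) for n in allocations)
        if s2 <= 0:
            raise ValueError("pooled variance must be positive")
        if df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if df != sum(allocations) - len(allocations):
            raise ValueError("df must equal N - (number of arms)")
        means.flags.writeable = False
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "s2", float(s2))
        object.__setattr__(self, "df", int(df))
        object.__setattr__(self, "allocations", allocations)

    @property
    def s(self) -> float:
        return float(np.sqrt(self.s2))

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.allocations, dtype=float)


def summarize(data: TrialData, design: DoseDesign) -> SummaryStats:
    """Arm means and pooled variance (denominator ``N - k - 1``)."""
    groups = data.by_arm(len(design))
    counts = [len(g) for g in groups]
    if any(c < 2 for c in counts):
        raise ValueError("every arm needs at least 2 observations")
    means = np.array([g.mean() for g in groups])
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df = sum(counts) - len(groups)
    if sse <= 0:
        raise ValueError("zero pooled variance: all responses identical")
    return SummaryStats(means, sse / df, df, counts)


def contrast_statistics(
    stats_: SummaryStats, contrasts: Sequence[Contrast]
) -> np.ndarray:
    """Studentized contrast statistics ``c'Ybar / (S sqrt(sum c²/n))``."""
    C = np.array([np.asarray(c) for c in contrasts], dtype=float)
    if C.shape[1] != len(stats_.means):
        raise ValueError("contrast length must match the number of arms")
    scale = stats_.s * np.sqrt((C**2 / stats_.n).sum(axis=1))
    return (C @ stats_.means) / scale


# ---------------------------------------------------------------------------
# multivariate-t machinery


def _dedupe(R: np.ndarray) -> np.ndarray:
    """Indices of one representative per group of identical contrasts."""
    keep: list[int] = []
    for m in range(R.shape[0]):
        if not any(R[m, j] >= 1.0 - _DUP_TOL for j in keep):
            keep.append(m)
    return np.asarray(keep)


def _check_correlation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(np.diag(R) - 1.0) > 1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.min(np.linalg.eigvalsh(R)) < -1e-9:
        raise ValueError("correlation matrix is not positive semidefinite")
    return R


def _regularize(R: np.ndarray) -> np.ndarray:
    """Lift rank-deficient correlation matrices to full rank.

    M model contrasts on k + 1 arms span at most a k-dimensional space,
    so for M > k the correlation matrix is singular.  The probability
    of the (degenerate) equicoordinate region is continuous in R; a
    tiny ridge makes the QMC integrator applicable with a bias far
    below the integration tolerance.
    """
    if np.min(np.linalg.eigvalsh(R)) > 1e-6:
        return R
    Rj = (1.0 - _RIDGE) * R + _RIDGE * np.eye(R.shape[0])
    d = np.sqrt(np.diag(Rj))
    return Rj / np.outer(d, d)


def _mvt_cdf_once(
    upper: np.ndarray, R: np.ndarray, df: int, rng: np.random.Generator
) -> float:
    return float(
        stats.multivariate_t.cdf(
            upper,
            loc=np.zeros(len(upper)),
            shape=R,
            df=df,
            maxpts=MVT_MAXPTS,
            random_state=rng,
        )
    )


def equicoordinate_prob(
    t: float, R: np.ndarray, df: int, seed: int | None = None
) -> tuple[float, float]:
    """``P(T_1 <= t, ..., T_M <= t)`` for a central multivariate t.

    Returns ``(probability, error_estimate)``.  Numerically identical
    coordinates (correlation 1) are collapsed before integration; the
    univariate case is exact.  The error estimate is the half-range of
    two independently randomized quasi-Monte-Carlo evaluations.
    """
    R = _check_correlation(R)
    keep = _dedupe(R)
    Ru = _regularize(R[np.ix_(keep, keep)])
    if len(keep) == 1:
        return float(stats.t.cdf(t, df)), 0.0
    upper = np.full(len(keep), float(t))
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    vals = [
        _mvt_cdf_once(upper, Ru, df, np.random.default_rng(child))
        for child in ss.spawn(2)
    ]
    value = float(np.clip(np.mean(vals), 0.0, 1.0))
    err = abs(vals[0] - vals[1]) / 2.0
    return value, err


def adjusted_pvalues(
    statistics: Sequence[float],
    correlation: np.ndarray,
    df: int,
    seed: int | None = None,
    return_error: bool = False,
):
    """maxT-adjusted p-values ``q_m = 1 - P(max_j T_j <= t_m)``.

    Each observed statistic is referred to the joint null distribution
    of *all* M statistics, so every ``q_m`` is already multiplicity
    adjusted; the minimum over m is the p-value of the maximum test.
    """
    t = np.asarray(statistics, dtype=float)
    out = np.empty_like(t)
    errs = np.empty_like(t)
    for m, tm in enumerate(t):
        p, e = equicoordinate_prob(tm, correlation, df, seed=seed)
        out[m] = 1.0 - p
        errs[m] = e
    out = np.clip(out, 0.0, 1.0)
    if return_error:
        return out, errs
    return out


def critical_value(
    correlation: np.ndarray,
    df: int,
    alpha: float = 0.025,
    seed: int | None = None,
) -> float:
    """Equicoordinate quantile ``c`` with ``P(max T_m <= c) = 1 - alpha``.

    Found by root bracketing/bisection on the seeded QMC probability,
    to a quantile tolerance of 1e-6 (subject to integration error).
    Dual to :func:`adjusted_pvalues`: the maximum statistic exceeds
    ``c`` exactly when the minimum adjusted p-value falls below alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    R = _check_correlation(correlation)
    keep = _dedupe(R)
    if len(keep) == 1:
        return float(stats.t.ppf(1.0 - alpha, df))
    Ru = _regularize(R[np.ix_(keep, keep)])
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    state = ss.generate_state(4)  # one fixed QMC randomization: f monotone

    def f(c: float) -> float:
        rng = np.random.default_rng(state)
        prob = _mvt_cdf_once(np.full(len(keep), c), Ru, df, rng)
        return prob - (1.0 - alpha)

    lo = float(stats.t.ppf(1.0 - alpha, df))  # Bonferroni bounds
    hi = float(stats.t.ppf(1.0 - alpha / len(keep), df))
    flo, fhi = f(lo), f(hi)
    if flo >= 0:
        return lo
    if fhi <= 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one maximum contrast test."""

    statistics: np.ndarray
    adjusted_p: np.ndarray
    critical_value: float
    alpha: float
    integration_error: np.ndarray

    @property
    def pmin(self) -> float:
        return float(np.min(self.adjusted_p))

    @property
    def tmax(self) -> float:
        return float(np.max(self.statistics))

    @property
    def reject(self) -> bool:
        return self.pmin < self.alpha


def max_t_test(
    stats_: SummaryStats,
    contrasts: Sequence[Contrast],
    design: DoseDesign,
    alpha: float = 0.025,
    seed: int | None = None,
) -> TestResult:
    """Run the maximum contrast test for one set of model contrasts."""
    R = correlation_matrix(contrasts, design)
    t = contrast_statistics(stats_, contrasts)
    q, err = adjusted_pvalues(t, R, stats_.df, seed=seed, return_error=True)
    c = critical_value(R, stats_.df, alpha=alpha, seed=seed)
    return TestResult(t, q, c, alpha, err)
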
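"""Reference many-to-one procedures: Dunnett, Hochberg, Bonferroni,
fixed sequence, and unadjusted pairwise t-tests.

These are the benchmarks the closed MCP-Mod procedure is compared
against.  Bonferroni and Hochberg adjustments are delegated to
statsmodels; the (step-down) Dunnett tests reuse this package's
multivariate-t machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .contrasts import Contrast, correlation_matrix
from .inference import SummaryStats, critical_value, equicoordinate_prob
from .models import DoseDesign

__all__ = [
    "AdjustedPValues",
    "pairwise_t_pvalues",
    "bonferroni",
    "hochberg",
    "fixed_sequence",
    "stepdown_dunnett",
    "singlestep_dunnett",
    "dunnett_correlation",
]


@dataclass(frozen=True)
class AdjustedPValues:
    """Per-hypothesis adjusted p-values and rejections for one procedure."""

    procedure: str
    adjusted_p: np.ndarray
    reject: np.ndarray
    alpha: float

    def __post_init__(self):
        p = np.asarray(self.adjusted_p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("adjusted p-values must lie in [0, 1]")


def pairwise_t_pvalues(stats_: SummaryStats, design: DoseDesign) -> np.ndarray:
    """One-sided dose-vs-placebo t-test p-values (pooled variance)."""
    n = stats_.n
    t = (stats_.means[1:] - stats_.means[0]) / (
        stats_.s * np.sqrt(1.0 / n[1:] + 1.0 / n[0])
    )
    return sps.t.sf(t, stats_.df)


def bonferroni(p, alpha: float = 0.025) -> AdjustedPValues:
    """Bonferroni adjustment ``min(1, k p)``."""
    p = np.asarray(p, dtype=float)
    reject, padj, *_ = multipletests(p, alpha=alpha, method="bonferroni")
    return AdjustedPValues("bonferroni", padj, reject, alpha)


def hochberg(p, alpha: float = 0.025) -> AdjustedPValues:
    """Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=float)
    reject, padj, *_ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return AdjustedPValues("hochberg", padj, reject, alpha)


def fixed_sequence(p, alpha: float = 0.025) -> AdjustedPValues:
    """Hierarchical testing in the pre-specified order of ``p``.

    ``p`` must already be ordered by the testing sequence (highest dose
    first by convention); each hypothesis is tested at the full alpha
    and the sequence stops at the first failure, so the adjusted
    p-values are the running maxima.
    """
    p = np.asarray(p, dtype=float)
    padj = np.maximum.accumulate(p)
    return AdjustedPValues("fixed_sequence", padj, padj < alpha, alpha)


def dunnett_correlation(design: DoseDesign) -> np.ndarray:
    """Correlation of the k dose-vs-placebo t statistics."""
    singles = []
    for i in range(1, len(design)):
        c = np.zeros(len(design))
        c[0], c[i] = -1.0, 1.0
        c /= np.sqrt(2.0)
        singles.append(Contrast(c, support=(0, i)))
    return correlation_matrix(singles, design)


def singlestep_dunnett(
    stats_: SummaryStats,
    design: DoseDesign,
    alpha: float = 0.025,
    seed: int | None = None,
) -> AdjustedPValues:
    """Single-step Dunnett adjusted p-values (one-sided)."""
    R = dunnett_correlation(design)
    p = pairwise_t_pvalues(stats_, design)
    t = sps.t.isf(p, stats_.df)
    padj = np.array(
        [1.0 - equicoordinate_prob(ti, R, stats_.df, seed=seed)[0] for ti in t]
    )
    padj = np.clip(np.maximum(padj, p), 0.0, 1.0)
    return AdjustedPValues("singlestep_dunnett", padj, padj < alpha, alpha)


def stepdown_dunnett(
    stats_: SummaryStats,
    design: DoseDesign,
    alpha: float = 0.025,
    seed: int | None = None,
) -> AdjustedPValues:
    """Step-down Dunnett test (shortcut of the closed Dunnett test).

    The ordered statistics are referred to shrinking equicoordinate
    multivariate-t critical surfaces: the j-th largest statistic is
    judged against the joint distribution of the statistics not yet
    rejected.  Adjusted p-values are the running maxima of the
    corresponding equicoordinate tail probabilities.
    """
    R = dunnett_correlation(design)
    p = pairwise_t_pvalues(stats_, design)
    t = sps.t.isf(p, stats_.df)
    order = np.argsort(-t)
    padj = np.empty_like(p)
    running = 0.0
    for step, idx in enumerate(order):
        remaining = order[step:]
        sub = R[np.ix_(remaining, remaining)]
        praw = 1.0 - equicoordinate_prob(t[idx], sub, stats_.df, seed=seed)[0]
        running = max(running, min(1.0, praw))
        padj[idx] = running
    padj = np.maximum(padj, p)
    return AdjustedPValues("stepdown_dunnett", padj, padj < alpha, alpha)


def stepdown_dunnett_critical_values(
    design: DoseDesign, df: int, alpha: float = 0.025, seed: int | None = None
) -> dict[frozenset, float]:
    """Critical value for every nonempty subset of doses (for simulation)."""
    R = dunnett_correlation(design)
    out: dict[frozenset, float] = {}
    k = design.k
    from itertools import combinations

    for r in range(1, k + 1):
        for S in combinations(range(1, k + 1), r):
            idx = [i - 1 for i in S]
            out[frozenset(S)] = critical_value(
                R[np.ix_(idx, idx)], df, alpha=alpha, seed=seed
            )
    return out
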
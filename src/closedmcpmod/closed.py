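"""Closed MCP-Mod: closed testing with model-based contrast tests.

Every nonempty subset I of the active doses defines an intersection
hypothesis H_I ("none of the doses in I beats placebo").  Each H_I is
tested at level alpha with a maximum contrast test whose per-model
contrasts are re-optimized on the control arm plus the doses in I,
while the pooled variance keeps using all arms.  A dose is declared
superior to placebo exactly when every intersection containing it is
rejected; by the closed test principle this controls the familywise
error rate — strongly so when the constrained contrasts are used.

The procedure is deliberately exhaustive (2^k - 1 intersection tests):
it is not consonant, so no step-down shortcut is valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .contrasts import (
    Contrast,
    DegenerateContrastError,
    constrained_contrast,
    correlation_matrix,
    optimal_contrast,
)
from .inference import (
    SummaryStats,
    TrialData,
    adjusted_pvalues,
    contrast_statistics,
    critical_value,
    summarize,
)
from .models import CandidateSet, DoseDesign, scaled_mean_profile

__all__ = [
    "enumerate_intersections",
    "test_intersection",
    "closed_mcpmod",
    "IntersectionResult",
    "ClosedMCPMod",
    "ClosedMCPModResults",
]


def enumerate_intersections(k: int) -> list[tuple[int, ...]]:
    """All 2^k - 1 nonempty subsets of {1..k}, largest first.

    Ordered by decreasing cardinality, lexicographically within equal
    cardinality, so the global intersection {1..k} comes first.
    """
    if not 1 <= k <= 15:
        raise ValueError("k must be between 1 and 15")
    out: list[tuple[int, ...]] = []
    for r in range(k, 0, -1):
        out.extend(combinations(range(1, k + 1), r))
    return out


def _intersection_contrasts(
    I: Sequence[int],
    design: DoseDesign,
    cset: CandidateSet,
    constrained: bool,
):
    """Per-model contrasts on {0} ∪ I; degenerate models are dropped."""
    solver = constrained_contrast if constrained else optimal_contrast
    contrasts: list[Contrast] = []
    labels: list[str] = []
    for model in cset:
        mu = scaled_mean_profile(model, design, 1.0)
        try:
            c = solver(mu, design, subset=I)
        except DegenerateContrastError:
            warnings.warn(
                f"model {model.label!r} is degenerate on intersection "
                f"{tuple(I)}; dropped for this hypothesis",
                stacklevel=3,
            )
            continue
        contrasts.append(c)
        labels.append(model.label)
    if not contrasts:
        raise DegenerateContrastError(
            f"all candidate models are degenerate on intersection {tuple(I)}"
        )
    return contrasts, labels


@dataclass(frozen=True)
class IntersectionResult:
    """Maximum contrast test of one intersection hypothesis."""

    intersection: tuple[int, ...]
    model_labels: tuple[str, ...]
    adjusted_p: np.ndarray  # per model, multiplicity adjusted within H_I
    statistics: np.ndarray
    critical_value: float
    alpha: float
    contrasts: tuple[Contrast, ...] = field(repr=False)

    @property
    def p_value(self) -> float:
        """p-value of H_I: the minimum per-model adjusted p-value."""
        return float(np.min(self.adjusted_p))

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def test_intersection(
    I: Sequence[int],
    stats: SummaryStats,
    design: DoseDesign,
    cset: CandidateSet,
    constrained: bool = True,
    alpha: float = 0.025,
    seed: int | None = None,
) -> IntersectionResult:
    """Test H_I with contrasts re-optimized on the doses in I.

    For the full index set this is the original MCP-Mod proof-of-concept
    test; for singletons every model collapses to the same two-sample
    comparison and the p-value equals the one-sided t-test p-value.
    """
    I = tuple(sorted(int(i) for i in I))
    contrasts, labels = _intersection_contrasts(I, design, cset, constrained)
    R = correlation_matrix(contrasts, design)
    t = contrast_statistics(stats, contrasts)
    q = adjusted_pvalues(t, R, stats.df, seed=seed)
    c = critical_value(R, stats.df, alpha=alpha, seed=seed)
    return IntersectionResult(I, tuple(labels), q, t, c, alpha, tuple(contrasts))


class ClosedMCPMod:
    """Closed MCP-Mod model for per-dose comparisons against placebo.

    Parameters
    ----------
    data
        :class:`~closedmcpmod.inference.TrialData` (arm 0 is placebo).
    design
        Dose grid and allocations.
    candidate_set
        Candidate dose-response shapes driving the contrasts.
    constrained
        Use nonnegative dose weights (default).  The unconstrained
        variant matches the original optimal contrasts but strong
        familywise error control is then unproven for k >= 3.

    Examples
    --------
    >>> res = ClosedMCPMod(data, design, candidate_set).fit(alpha=0.025)
    >>> res.summary()
    """

    def __init__(
        self,
        data: TrialData,
        design: DoseDesign,
        candidate_set: CandidateSet,
        constrained: bool = True,
    ):
        self.data = data
        self.design = design
        self.candidate_set = candidate_set
        self.constrained = bool(constrained)
        if not self.constrained and design.k >= 3:
            warnings.warn(
                "unconstrained contrasts: strong familywise error control "
                "is proven only for k <= 2; consider constrained=True",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        design: DoseDesign,
        candidate_set: CandidateSet,
        dose_col: str = "dose",
        response_col: str = "response",
        **kwargs,
    ) -> "ClosedMCPMod":
        """Build from a tidy per-patient table with dose and response."""
        from .io import trial_data_from_frame

        data = trial_data_from_frame(frame, design, dose_col, response_col)
        return cls(data, design, candidate_set, **kwargs)

    def fit(self, alpha: float = 0.025, seed: int | None = None
            ) -> "ClosedMCPModResults":
        """Run the full closed test and return the results object."""
        stats = summarize(self.data, self.design)
        results = [
            test_intersection(
                I, stats, self.design, self.candidate_set,
                constrained=self.constrained, alpha=alpha, seed=seed,
            )
            for I in enumerate_intersections(self.design.k)
        ]
        return ClosedMCPModResults(self, stats, results, alpha, seed)


class ClosedMCPModResults:
    """Results of a fitted closed MCP-Mod procedure.

    Carries the full table of intersection tests, the per-dose closed
    adjusted p-values (max over containing intersections) and rejection
    flags, and the global proof-of-concept p-value.
    """

    def __init__(self, model, stats, intersection_results, alpha, seed):
        self.model = model
        self.stats = stats
        self.intersection_results: list[IntersectionResult] = list(
            intersection_results
        )
        self.alpha = float(alpha)
        self.seed = seed
        k = model.design.k
        self._by_set = {r.intersection: r for r in self.intersection_results}
        adj = np.empty(k)
        rej = np.empty(k, dtype=bool)
        for i in range(1, k + 1):
            containing = [r for r in self.intersection_results
                          if i in r.intersection]
            adj[i - 1] = max(r.p_value for r in containing)
            rej[i - 1] = all(r.reject for r in containing)
        self.adjusted_p = adj
        self.rejected = rej

    @property
    def design(self) -> DoseDesign:
        return self.model.design

    @property
    def global_p(self) -> float:
        """p-value of the proof-of-concept (global intersection) test."""
        full = tuple(range(1, self.design.k + 1))
        return self._by_set[full].p_value

    def intersection(self, I: Sequence[int]) -> IntersectionResult:
        return self._by_set[tuple(sorted(int(i) for i in I))]

    def pvalue_table(self) -> pd.DataFrame:
        """Per-intersection, per-model adjusted p-values (one row per H_I)."""
        labels = self.model.candidate_set.labels
        rows = []
        index = []
        for r in self.intersection_results:
            row = {lab: np.nan for lab in labels}
            row.update(dict(zip(r.model_labels, r.adjusted_p)))
            rows.append(row)
            index.append("H_{" + ",".join(map(str, r.intersection)) + "}")
        return pd.DataFrame(rows, index=index, columns=labels)

    def summary(self) -> str:
        """Human-readable report of the closed test."""
        d = self.design
        variant = "constrained" if self.model.constrained else "unconstrained"
        lines = [
            "Closed MCP-Mod (" + variant + " contrasts)",
            "=" * 46,
            f"arms: {len(d)}  N: {d.N}  alpha (one-sided): {self.alpha:g}",
            f"pooled SD: {self.stats.s:.4f}  df: {self.stats.df}",
            f"global dose-response p-value: {self.global_p:.4f}",
            "",
            "Intersection hypotheses",
            "-" * 46,
        ]
        for r in self.intersection_results:
            name = "H_{" + ",".join(map(str, r.intersection)) + "}"
            flag = "reject" if r.reject else "      "
            lines.append(f"{name:<14} p = {r.p_value:.4f}  {flag}")
        lines += ["", "Dose versus placebo (closed adjusted)", "-" * 46]
        for i in range(1, d.k + 1):
            flag = "reject" if self.rejected[i - 1] else "      "
            lines.append(
                f"dose {d.doses[i]:<6g} p = {self.adjusted_p[i - 1]:.4f}  {flag}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ClosedMCPModResults k={self.design.k} "
            f"rejected={int(self.rejected.sum())} global_p={self.global_p:.4g}>"
        )


def closed_mcpmod(
    data: TrialData,
    design: DoseDesign,
    cset: CandidateSet,
    constrained: bool = True,
    alpha: float = 0.025,
    seed: int | None = None,
) -> ClosedMCPModResults:
    """Convenience wrapper: build :class:`ClosedMCPMod` and fit it."""
    return ClosedMCPMod(data, design, cset, constrained=constrained).fit(
        alpha=alpha, seed=seed
    )
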
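"""Closed MCP-Mod for a primary plus a secondary endpoint.

Hypotheses are organized as a weighted graph: nodes carry local
significance levels (fractions of the total one-sided alpha) and
directed edges say where a rejected hypothesis's level flows.  For each
intersection of primary/secondary dose hypotheses, the standard
node-removal algebra yields local levels; the intersection is then
tested with a Bonferroni split between the endpoint groups, each group
using the constrained maximum contrast test on its doses at the sum of
its local levels.  Exhaustive closure over all 2^(2k) - 1 intersections
gives strong familywise error control across both endpoints.

The default graph splits alpha equally across the k primary hypotheses,
passes a rejected primary's level to its own-dose secondary, and
returns a rejected secondary's level in equal halves to the other
doses' primaries.  With that graph a secondary hypothesis can only be
rejected after the primary hypothesis of the same dose — the
successiveness emerges from the level algebra and is not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np

from .closed import _intersection_contrasts
from .contrasts import correlation_matrix
from .inference import (
    SummaryStats,
    TrialData,
    adjusted_pvalues,
    contrast_statistics,
    summarize,
)
from .models import CandidateSet, DoseDesign

__all__ = [
    "GraphMTP",
    "local_levels",
    "test_intersection_graphical",
    "closed_graphical_mcpmod",
    "GraphicalClosedMCPMod",
    "GraphicalResults",
]


def _hyp_label(endpoint: int, dose: int) -> str:
    return f"H{endpoint}{dose}"


@dataclass(frozen=True)
class GraphMTP:
    """Weighted hypothesis graph: node levels plus a transition matrix.

    ``levels`` are fractions of alpha (nonnegative, summing to <= 1);
    ``transitions`` has zero diagonal and row sums <= 1.
    """

    labels: tuple[str, ...]
    levels: np.ndarray
    transitions: np.ndarray

    def __init__(self, labels, levels, transitions):
        labels = tuple(labels)
        levels = np.asarray(levels, dtype=float)
        g = np.asarray(transitions, dtype=float)
        m = len(labels)
        if len(set(labels)) != m:
            raise ValueError("hypothesis labels must be unique")
        if levels.shape != (m,) or g.shape != (m, m):
            raise ValueError("levels/transitions dimensions must match labels")
        if np.any(levels < -1e-12) or levels.sum() > 1.0 + 1e-9:
            raise ValueError("levels must be nonnegative and sum to <= 1")
        if np.any(np.abs(np.diag(g)) > 1e-12):
            raise ValueError("transition matrix must have zero diagonal")
        if np.any(g < -1e-12) or np.any(g.sum(axis=1) > 1.0 + 1e-9):
            raise ValueError("transition rows must be nonnegative, sum <= 1")
        levels.flags.writeable = False
        g.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "transitions", g)

    @classmethod
    def two_endpoint_default(cls, k: int = 3, x: float = 1.0) -> "GraphMTP":
        """Symmetric primary/secondary graph for k doses.

        Primary nodes each start at level 1/k (fraction of alpha),
        secondaries at 0.  Each primary sends weight ``x`` to its
        own-dose secondary and ``(1 - x)/2``-style equal shares to the
        other primaries (zero for the default ``x = 1``); each secondary
        returns its level in equal shares to the other doses'
        primaries.
        """
        if not 0.0 <= x <= 1.0:
            raise ValueError("edge weight x must be in [0, 1]")
        labels = [_hyp_label(1, i) for i in range(1, k + 1)] + [
            _hyp_label(2, i) for i in range(1, k + 1)
        ]
        m = 2 * k
        levels = np.zeros(m)
        levels[:k] = 1.0 / k
        g = np.zeros((m, m))
        for i in range(k):
            g[i, k + i] = x  # primary -> own secondary
            for j in range(k):
                if j != i and k > 1:
                    g[i, j] = (1.0 - x) / (k - 1)  # primary -> other primaries
                    g[k + i, j] = 1.0 / (k - 1)  # secondary -> other primaries
        return cls(labels, levels, g)


def local_levels(
    graph: GraphMTP, intersection: Sequence[str], alpha: float = 1.0
) -> dict[str, float]:
    """Local significance levels for one intersection hypothesis.

    Sequentially removes every hypothesis *not* in the intersection:
    the removed node's level flows along its outgoing edges and the
    remaining edges are rewired by the standard update
    ``g[l, m] <- (g[l, m] + g[l, j] g[j, m]) / (1 - g[l, j] g[j, l])``.
    The result does not depend on the removal order.  Levels are
    returned as multiples of ``alpha`` (default: fractions).
    """
    idx = {lab: i for i, lab in enumerate(graph.labels)}
    I = [str(h) for h in intersection]
    unknown = [h for h in I if h not in idx]
    if unknown:
        raise ValueError(f"labels not in graph: {unknown}")
    if not I:
        raise ValueError("intersection must be nonempty")
    keep = set(I)
    levels = graph.levels.copy()
    g = graph.transitions.copy()
    alive = list(graph.labels)
    for lab in [h for h in graph.labels if h not in keep]:
        j = idx[lab]
        alive_idx = [idx[h] for h in alive if h != lab]
        for l in alive_idx:
            levels[l] += levels[j] * g[j, l]
        newg = g.copy()
        for l in alive_idx:
            for mcol in alive_idx:
                if l == mcol:
                    continue
                denom = 1.0 - g[l, j] * g[j, l]
                if denom > 1e-12:
                    newg[l, mcol] = (g[l, mcol] + g[l, j] * g[j, mcol]) / denom
                else:
                    newg[l, mcol] = 0.0
        g = newg
        levels[j] = 0.0
        g[j, :] = 0.0
        g[:, j] = 0.0
        alive.remove(lab)
    return {h: float(levels[idx[h]] * alpha) for h in I}


def _split_groups(intersection: Sequence[str]) -> tuple[list[int], list[int]]:
    """Dose indices of the primary and secondary hypotheses in I."""
    prim, sec = [], []
    for h in intersection:
        endpoint, dose = int(h[1]), int(h[2:])
        (prim if endpoint == 1 else sec).append(dose)
    return sorted(prim), sorted(sec)


def _group_pvalue(
    doses: list[int],
    stats: SummaryStats,
    design: DoseDesign,
    cset: CandidateSet,
    seed: int | None,
) -> float:
    """Constrained maximum-contrast-test p-value on one dose group."""
    contrasts, _ = _intersection_contrasts(doses, design, cset, True)
    R = correlation_matrix(contrasts, design)
    t = contrast_statistics(stats, contrasts)
    q = adjusted_pvalues(t, R, stats.df, seed=seed)
    return float(np.min(q))


def test_intersection_graphical(
    intersection: Sequence[str],
    levels: Mapping[str, float],
    stats_by_endpoint: Sequence[SummaryStats],
    design: DoseDesign,
    cset: CandidateSet,
    alpha: float = 0.025,
    seed: int | None = None,
    _group_cache: dict | None = None,
) -> tuple[bool, float]:
    """Bonferroni-split test of one mixed intersection hypothesis.

    Each endpoint group is tested by the constrained maximum contrast
    test on its doses at the sum of its members' local levels; the
    intersection is rejected if either group test is significant.  A
    group whose summed level is zero can never be significant.

    Returns ``(reject, p_value)`` where the p-value is the smallest
    total alpha at which the intersection would be rejected (group p
    divided by the group's fraction of alpha, minimized over groups).
    """
    prim, sec = _split_groups(intersection)
    p_adj = np.inf
    for endpoint, doses in ((1, prim), (2, sec)):
        if not doses:
            continue
        w = sum(
            levels[_hyp_label(endpoint, i)] for i in doses
        )  # absolute level
        frac = w / alpha
        if frac <= 0.0:
            continue
        key = (endpoint, tuple(doses))
        if _group_cache is not None and key in _group_cache:
            p_group = _group_cache[key]
        else:
            p_group = _group_pvalue(
                doses, stats_by_endpoint[endpoint - 1], design, cset, seed
            )
            if _group_cache is not None:
                _group_cache[key] = p_group
        p_adj = min(p_adj, p_group / frac)
    p_adj = float(min(p_adj, 1.0))
    return p_adj < alpha, p_adj


class GraphicalClosedMCPMod:
    """Closed MCP-Mod over primary and secondary endpoint hypotheses.

    ``data`` holds one :class:`TrialData` per endpoint, observed on the
    same arms; the candidate set is shared across endpoints.
    """

    def __init__(
        self,
        data: Sequence[TrialData],
        design: DoseDesign,
        candidate_set: CandidateSet,
        graph: GraphMTP | None = None,
    ):
        if len(data) != 2:
            raise ValueError("expected exactly two endpoints")
        self.data = tuple(data)
        self.design = design
        self.candidate_set = candidate_set
        self.graph = (
            graph
            if graph is not None
            else GraphMTP.two_endpoint_default(design.k)
        )
        expected = {_hyp_label(e, i) for e in (1, 2)
                    for i in range(1, design.k + 1)}
        if set(self.graph.labels) != expected:
            raise ValueError(
                "graph labels must be H1i/H2i for every design dose"
            )

    def fit(self, alpha: float = 0.025, seed: int | None = None
            ) -> "GraphicalResults":
        stats = [summarize(d, self.design) for d in self.data]
        labels = list(self.graph.labels)
        results: dict[frozenset, tuple[bool, float]] = {}
        subsets = chain.from_iterable(
            combinations(labels, r) for r in range(len(labels), 0, -1)
        )
        cache: dict = {}  # group p-values shared across intersections
        for I in subsets:
            lv = local_levels(self.graph, I, alpha=alpha)
            results[frozenset(I)] = test_intersection_graphical(
                I, lv, stats, self.design, self.candidate_set,
                alpha=alpha, seed=seed, _group_cache=cache,
            )
        return GraphicalResults(self, stats, results, alpha)


class GraphicalResults:
    """Closed-test report over the 2k primary/secondary hypotheses."""

    def __init__(self, model, stats, intersection_results, alpha):
        self.model = model
        self.stats = stats
        self.intersection_results = dict(intersection_results)
        self.alpha = float(alpha)
        labels = list(model.graph.labels)
        self.adjusted_p = {}
        self.rejected = {}
        for h in labels:
            containing = [
                res for I, res in self.intersection_results.items() if h in I
            ]
            self.adjusted_p[h] = max(p for _, p in containing)
            self.rejected[h] = all(rej for rej, _ in containing)

    def summary(self) -> str:
        lines = [
            "Closed MCP-Mod, primary + secondary endpoint",
            "=" * 46,
            f"alpha (one-sided): {self.alpha:g}   "
            f"intersections tested: {len(self.intersection_results)}",
            "",
            f"{'hypothesis':<12}{'adj. p':>10}   decision",
        ]
        for h in self.model.graph.labels:
            flag = "reject" if self.rejected[h] else ""
            lines.append(f"{h:<12}{self.adjusted_p[h]:>10.4f}   {flag}")
        return "\n".join(lines)


def closed_graphical_mcpmod(
    data: Sequence[TrialData],
    design: DoseDesign,
    cset: CandidateSet,
    graph: GraphMTP | None = None,
    alpha: float = 0.025,
    seed: int | None = None,
) -> GraphicalResults:
    """Convenience wrapper over :class:`GraphicalClosedMCPMod`."""
    return GraphicalClosedMCPMod(data, design, cset, graph=graph).fit(
        alpha=alpha, seed=seed
    )
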
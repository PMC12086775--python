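"""Optimal and nonnegativity-constrained contrast coefficients.

A contrast test for an assumed mean profile ``mu0`` uses coefficients
``c`` with ``sum(c) = 0`` that maximize the noncentrality

    c' mu0 / sqrt(c' A c),

where ``A`` is the covariance (up to the residual variance) of the arm
mean estimates, ``diag(1/n_i)`` without covariates.  The closed testing
engine re-derives these contrasts for every intersection hypothesis,
restricting the support to the control arm plus the doses in the
intersection.

The unconstrained maximizer has the closed form ``c_i ∝ n_i (mu_i -
mu_bar)`` (generalized below to arbitrary ``A``).  It may place negative
weight on an active dose, which makes the resulting test two-sided in
disguise; the *constrained* variant additionally requires every active
dose coefficient to be nonnegative and is solved exactly by enumerating
support subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .models import DoseDesign, MeanProfile

__all__ = [
    "Contrast",
    "PrecisionSpec",
    "DegenerateContrastError",
    "optimal_contrast",
    "constrained_contrast",
    "correlation_matrix",
    "contrast_table",
]

#: weights below this are treated as genuinely negative (infeasible)
_NEG_TOL = 1e-12


class DegenerateContrastError(ValueError):
    """Profile constant over the requested arms: no contrast exists."""


@dataclass(frozen=True)
class Contrast:
    """Unit-norm, zero-sum contrast aligned to a dose design."""

    coefficients: np.ndarray
    support: tuple[int, ...]

    def __init__(self, coefficients: Sequence[float], support: Sequence[int]):
        c = np.asarray(coefficients, dtype=float)
        c.flags.writeable = False
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "support", tuple(int(j) for j in support))
        if abs(c.sum()) > 1e-10:
            raise ValueError("contrast coefficients must sum to 0")
        if abs(c @ c - 1.0) > 1e-10:
            raise ValueError("contrast coefficients must have unit norm")
        off = np.setdiff1d(np.arange(len(c)), self.support)
        if np.any(c[off] != 0.0):
            raise ValueError("coefficients outside the support must be 0")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.coefficients, dtype=dtype)

    def noncentrality(self, profile, precision: "PrecisionSpec") -> float:
        """Signed objective c'mu / sqrt(c'Ac) for this contrast."""
        c = self.coefficients
        mu = np.asarray(profile, dtype=float)
        return float(c @ mu / np.sqrt(c @ precision.A @ c))


@dataclass(frozen=True)
class PrecisionSpec:
    """Covariance (up to scale) of the arm-mean estimates.

    Without covariates this is ``diag(1/n_i)``; an arbitrary symmetric
    positive-definite matrix is accepted for generality.
    """

    A: np.ndarray

    def __init__(self, A: Sequence[Sequence[float]]):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("A must be symmetric")
        if np.min(np.linalg.eigvalsh(A)) <= 0:
            raise ValueError("A must be positive definite")
        A.flags.writeable = False
        object.__setattr__(self, "A", A)

    @classmethod
    def from_design(cls, design: DoseDesign) -> "PrecisionSpec":
        return cls(np.diag(1.0 / design.n))


def _as_profile_array(profile) -> np.ndarray:
    if isinstance(profile, MeanProfile):
        return np.asarray(profile.values)
    return np.asarray(profile, dtype=float)


def _check_subset(subset: Sequence[int], k: int) -> list[int]:
    I = sorted(int(i) for i in subset)
    if not I:
        raise ValueError("intersection index set must be nonempty")
    if I[0] < 1 or I[-1] > k or len(set(I)) != len(I):
        raise ValueError(f"subset must contain distinct indices in 1..{k}")
    return I


def _solve_unconstrained(mu_J: np.ndarray, A_J: np.ndarray) -> np.ndarray:
    # maximizer of c'mu / sqrt(c'Ac) subject to 1'c = 0 on the sub-arms:
    # c ∝ A^{-1} (mu - mu_bar 1), mu_bar = 1'A^{-1}mu / 1'A^{-1}1.
    ones = np.ones_like(mu_J)
    Ainv_mu = np.linalg.solve(A_J, mu_J)
    Ainv_1 = np.linalg.solve(A_J, ones)
    mu_bar = (ones @ Ainv_mu) / (ones @ Ainv_1)
    c = Ainv_mu - mu_bar * Ainv_1
    nrm = np.linalg.norm(c)
    if nrm <= 1e-12 * max(1.0, np.max(np.abs(mu_J))):
        raise DegenerateContrastError(
            "profile is constant over the requested arms"
        )
    c /= nrm
    if c @ mu_J < 0:  # orient toward benefit
        c = -c
    return c


def _embed(c_J: np.ndarray, J: Sequence[int], n_arms: int) -> Contrast:
    full = np.zeros(n_arms)
    full[list(J)] = c_J
    return Contrast(full, support=J)


def optimal_contrast(
    profile,
    design: DoseDesign,
    subset: Sequence[int] | None = None,
    precision: PrecisionSpec | None = None,
) -> Contrast:
    """Unconstrained optimal contrast for ``profile`` on ``{0} ∪ subset``.

    Maximizes the noncentrality over zero-sum vectors supported on the
    control arm plus the doses indexed by ``subset`` (1-based; default
    all doses), normalized to unit norm and oriented so that
    ``c' profile > 0``.  Arms outside the support get coefficient 0.
    """
    mu = _as_profile_array(profile)
    if len(mu) != len(design):
        raise ValueError("profile length must match the design")
    I = _check_subset(subset if subset is not None else range(1, design.k + 1),
                      design.k)
    prec = precision if precision is not None else PrecisionSpec.from_design(design)
    J = [0] + I
    c_J = _solve_unconstrained(mu[J], prec.A[np.ix_(J, J)])
    return _embed(c_J, J, len(design))


def constrained_contrast(
    profile,
    design: DoseDesign,
    subset: Sequence[int] | None = None,
    precision: PrecisionSpec | None = None,
) -> Contrast:
    """Optimal contrast with nonnegative active-dose coefficients.

    Solves the noncentrality maximization under ``c_i >= 0`` for every
    active dose (equivalently nonnegative placebo-difference weights) by
    exhaustive enumeration of nonempty support subsets ``S ⊆ subset``:
    each candidate is the unconstrained solution on ``{0} ∪ S``, screened
    for feasibility, and the feasible candidate with the largest
    objective wins.  Exact for the diagonal (and any positive-definite)
    precision; singleton supports are always feasible, so a solution
    always exists.
    """
    mu = _as_profile_array(profile)
    if len(mu) != len(design):
        raise ValueError("profile length must match the design")
    I = _check_subset(subset if subset is not None else range(1, design.k + 1),
                      design.k)
    prec = precision if precision is not None else PrecisionSpec.from_design(design)

    best: tuple[float, Contrast] | None = None
    degenerate_all = True
    for r in range(1, len(I) + 1):
        for S in combinations(I, r):
            J = [0, *S]
            try:
                c_J = _solve_unconstrained(mu[J], prec.A[np.ix_(J, J)])
            except DegenerateContrastError:
                continue
            degenerate_all = False
            # the cone-constrained maximizer is a (possibly negatively
            # oriented, for everywhere-decreasing profiles) stationary
            # solution on the relative interior of some support face
            for cand_J in (c_J, -c_J):
                if np.any(cand_J[1:] < -_NEG_TOL):
                    continue
                cand_J = np.where(np.abs(cand_J) < _NEG_TOL, 0.0, cand_J)
                # re-balance after clipping so the invariants hold exactly
                cand_J[0] = -cand_J[1:].sum()
                cand_J /= np.linalg.norm(cand_J)
                cand = _embed(cand_J, J, len(design))
                obj = cand.noncentrality(mu, prec)
                if best is None or obj > best[0] + 1e-15:
                    best = (obj, cand)
    if degenerate_all or best is None:
        raise DegenerateContrastError(
            "profile is constant over every support subset"
        )
    return best[1]


def correlation_matrix(
    contrasts: Sequence[Contrast],
    design: DoseDesign,
    precision: PrecisionSpec | None = None,
) -> np.ndarray:
    """Correlation matrix of the contrast test statistics.

    ``R[m, m'] = c_m' A c_m' / sqrt((c_m' A c_m)(c_m'' A c_m''))`` with
    ``A = diag(1/n_i)`` by default.  This is the correlation entering
    the multivariate-t reference distribution of the maximum statistic.
    """
    prec = precision if precision is not None else PrecisionSpec.from_design(design)
    C = np.array([np.asarray(c) for c in contrasts], dtype=float)
    if C.shape[1] != len(design):
        raise ValueError("contrasts must be aligned to the design")
    G = C @ prec.A @ C.T
    d = np.sqrt(np.diag(G))
    if np.any(d <= 0):
        raise ValueError("zero contrast has no correlation")
    R = G / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def contrast_table(design, cset, constrained: bool = False, effect: float = 1.0):
    """Per-intersection, per-model contrast coefficients as a DataFrame.

    One row per (intersection hypothesis, candidate model); columns are
    the arms.  The intersections are all nonempty subsets of the active
    doses, largest first — the layout of the case-study contrast tables.
    """
    import pandas as pd

    from .closed import enumerate_intersections
    from .models import scaled_mean_profile

    solver = constrained_contrast if constrained else optimal_contrast
    rows = []
    index = []
    for I in enumerate_intersections(design.k):
        for model in cset:
            mu = scaled_mean_profile(model, design, effect)
            c = solver(mu, design, subset=I)
            rows.append(np.asarray(c))
            index.append(("H_{" + ",".join(map(str, I)) + "}", model.label))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["hypothesis", "model"]),
        columns=[f"dose_{d:g}" for d in design.doses],
    )
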
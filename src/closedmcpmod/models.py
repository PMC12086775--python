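"""Candidate dose-response shapes and placebo-anchored mean profiles.

The procedure implemented by this package never fits a dose-response
model to data.  Candidate models enter only through their *standardized*
shape ``f0(d, theta0)`` evaluated at the design doses with guessed shape
parameters ``theta0``: the resulting mean profile determines the optimal
contrast coefficients, and an affine rescaling of the shape (handled by
:func:`scaled_mean_profile`) pins the placebo effect at 0 and the maximum
effect at a chosen size for simulation truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DoseDesign",
    "CandidateModel",
    "CandidateSet",
    "MeanProfile",
    "DegenerateProfileError",
    "standardized_response",
    "scaled_mean_profile",
    "max_effect_dose",
    "default_candidate_set",
]

#: model family -> required shape parameters
_FAMILIES: dict[str, tuple[str, ...]] = {
    "emax": ("ed50",),
    "sigEmax": ("ed50", "h"),
    "betaMod": ("delta1", "delta2", "scale"),
    "exponential": ("delta",),
    "linear": (),
}


class DegenerateProfileError(ValueError):
    """Raised when a candidate shape is constant over the doses considered."""


@dataclass(frozen=True)
class DoseDesign:
    """Dose grid (placebo first) and per-arm allocations.

    Parameters
    ----------
    doses
        Strictly increasing dose levels; ``doses[0]`` is the control arm.
    allocations
        Per-arm sample sizes, aligned with ``doses``.
    """

    doses: tuple[float, ...]
    allocations: tuple[int, ...]

    def __init__(self, doses: Sequence[float], allocations: Sequence[int]):
        doses = tuple(float(d) for d in doses)
        allocations = tuple(int(n) for n in allocations)
        if len(doses) < 2:
            raise ValueError("need a control arm plus at least one dose")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if len(allocations) != len(doses):
            raise ValueError("one allocation per arm required")
        if any(n <= 0 for n in allocations):
            raise ValueError("allocations must be positive")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "allocations", allocations)

    @property
    def k(self) -> int:
        """Number of active doses (arms minus control)."""
        return len(self.doses) - 1

    @property
    def N(self) -> int:
        return sum(self.allocations)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.allocations, dtype=float)

    @property
    def dose_array(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class CandidateModel:
    """A standardized dose-response shape with guessed parameters.

    ``family`` is one of ``emax``, ``sigEmax``, ``betaMod``,
    ``exponential`` or ``linear``; ``params`` holds the family's shape
    parameters (e.g. ``{"ed50": 0.05}``).  Only the shape matters: every
    standardized model is defined up to an affine transform that is
    absorbed when profiles are scaled.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; "
                f"choose from {sorted(_FAMILIES)}"
            )
        required = _FAMILIES[self.family]
        missing = [p for p in required if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} requires parameters {missing}")
        for name in ("ed50", "scale", "delta", "h"):
            if name in self.params and not self.params[name] > 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(self, "params", dict(self.params))
        if self.label is None:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if not self.params:
            return self.family
        inner = ",".join(f"{k}={v:g}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})"

    def standardized_response(self, dose):
        return standardized_response(self, dose)


def standardized_response(model: CandidateModel, dose) -> np.ndarray | float:
    """Evaluate the standardized shape ``f0(d, theta0)`` at ``dose``.

    Vectorized over ``dose``.  All shapes are anchored at ``f0(0) = 0``;
    the beta shape requires ``dose <= scale``.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    p = model.params
    if model.family == "emax":
        out = d / (p["ed50"] + d)
    elif model.family == "sigEmax":
        h, ed50 = p["h"], p["ed50"]
        out = d**h / (ed50**h + d**h)
    elif model.family == "betaMod":
        s = p["scale"]
        if np.any(d > s):
            raise ValueError("betaMod is defined only for dose <= scale")
        x = d / s
        out = x ** p["delta1"] * (1.0 - x) ** p["delta2"]
    elif model.family == "exponential":
        out = np.expm1(d / p["delta"])
    elif model.family == "linear":
        out = d
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown family {model.family!r}")
    return out if out.ndim else float(out)


def max_effect_dose(model: CandidateModel, design: DoseDesign) -> float:
    """Design dose at which the standardized shape is largest.

    Ties break toward the smallest such dose.  Raises
    :class:`DegenerateProfileError` if the shape is flat over the design.
    """
    f = np.asarray(standardized_response(model, design.dose_array))
    if np.ptp(f) <= 0:
        raise DegenerateProfileError(
            f"{model.label} is constant over the design doses"
        )
    return design.doses[int(np.argmax(f))]


@dataclass(frozen=True)
class MeanProfile:
    """Arm mean vector aligned to a dose design (response units)."""

    values: np.ndarray

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("profile values must be finite")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)


def scaled_mean_profile(
    model: CandidateModel, design: DoseDesign, effect: float
) -> MeanProfile:
    """Mean profile with 0 at placebo and ``effect`` at the best dose.

    The standardized shape is shifted and rescaled (affine transform) so
    that the placebo mean is exactly 0 and the largest mean over the
    design equals ``effect``.  For ``effect = 0`` the profile is flat.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    f = np.asarray(standardized_response(model, design.dose_array))
    f = f - f[0]
    span = np.max(f)
    if effect == 0.0:
        return MeanProfile(np.zeros(len(design)))
    if span <= 0:
        raise DegenerateProfileError(
            f"{model.label} is constant (or non-increasing everywhere) "
            "over the design doses; cannot scale to a positive effect"
        )
    return MeanProfile(effect * f / span)


class CandidateSet:
    """Ordered collection of candidate models with unique labels."""

    def __init__(self, models: Sequence[CandidateModel]):
        models = list(models)
        if not models:
            raise ValueError("candidate set must contain at least one model")
        labels = [m.label for m in models]
        if len(set(labels)) != len(labels):
            raise ValueError("candidate model labels must be unique")
        self.models = models

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> CandidateModel:
        return self.models[i]

    @classmethod
    def from_config(cls, entries: Sequence[Mapping]) -> "CandidateSet":
        """Build from config entries ``{label, family, params}``."""
        models = []
        for e in entries:
            extra = set(e) - {"label", "family", "params"}
            if extra:
                raise ValueError(f"unknown candidate-set keys {sorted(extra)}")
            models.append(
                CandidateModel(
                    family=e["family"],
                    params=e.get("params", {}),
                    label=e.get("label"),
                )
            )
        return cls(models)


def default_candidate_set() -> CandidateSet:
    """The neuropathic-pain case-study candidate set.

    Three Emax shapes (ED50 = 0.05, 0.2, 0.7) and two sigmoid-Emax
    shapes (h = 3 with ED50 = 0.25; h = 2 with ED50 = 0.6), all
    monotone, chosen at the design stage of the motivating trial.
    """
    return CandidateSet(
        [
            CandidateModel("emax", {"ed50": 0.05}, label="Emax1"),
            CandidateModel("emax", {"ed50": 0.2}, label="Emax2"),
            CandidateModel("emax", {"ed50": 0.7}, label="Emax3"),
            CandidateModel("sigEmax", {"ed50": 0.25, "h": 3}, label="sigEmax1"),
            CandidateModel("sigEmax", {"ed50": 0.6, "h": 2}, label="sigEmax2"),
        ]
    )
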
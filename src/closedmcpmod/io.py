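"""CSV/YAML/JSON plumbing: trial tables, run configuration, reports,
and a deterministic packaged fixture generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .closed import ClosedMCPModResults, closed_mcpmod
from .inference import TrialData
from .models import CandidateModel, CandidateSet, DoseDesign

__all__ = [
    "RunConfig",
    "read_trial_csv",
    "trial_data_from_frame",
    "write_report",
    "report_to_dict",
    "make_fixture",
]


def _canonical(x) -> float:
    """Parse a dose value to a canonical float (exact matching, no fuzz)."""
    return float(str(x).strip())


def trial_data_from_frame(
    frame: pd.DataFrame,
    design: DoseDesign,
    dose_col: str = "dose",
    response_col: str = "response",
) -> TrialData:
    """Match each row's dose exactly to a design arm."""
    for col in (dose_col, response_col):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    dose_to_arm = {_canonical(d): i for i, d in enumerate(design.doses)}
    doses = frame[dose_col].map(_canonical)
    unmatched = ~doses.isin(dose_to_arm)
    if unmatched.any():
        bad = frame.index[unmatched].tolist()[:10]
        raise ValueError(
            f"{int(unmatched.sum())} rows have doses not in the design "
            f"(first offending rows: {bad})"
        )
    arm = doses.map(dose_to_arm).to_numpy(dtype=int)
    return TrialData(arm, frame[response_col].to_numpy(dtype=float))


def read_trial_csv(
    path,
    design: DoseDesign,
    dose_col: str = "dose",
    response_col: str = "response",
    endpoint_col: str = "endpoint",
):
    """Read per-patient (dose, response[, endpoint]) records.

    Returns a single :class:`TrialData`, or a list of them (one per
    endpoint level, in sorted order) when the endpoint column is
    present.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    if endpoint_col in frame.columns:
        return [
            trial_data_from_frame(g, design, dose_col, response_col)
            for _, g in frame.groupby(endpoint_col, sort=True)
        ]
    return trial_data_from_frame(frame, design, dose_col, response_col)


def report_to_dict(res: ClosedMCPModResults) -> dict:
    d = res.design
    return {
        "alpha": res.alpha,
        "constrained": res.model.constrained,
        "seed": res.seed,
        "doses": list(d.doses),
        "allocations": list(d.allocations),
        "pooled_sd": res.stats.s,
        "df": res.stats.df,
        "global_p": res.global_p,
        "elementary": [
            {
                "dose": d.doses[i],
                "adjusted_p": float(res.adjusted_p[i - 1]),
                "reject": bool(res.rejected[i - 1]),
            }
            for i in range(1, d.k + 1)
        ],
        "intersections": [
            {
                "intersection": list(r.intersection),
                "models": list(r.model_labels),
                "adjusted_p": [float(q) for q in r.adjusted_p],
                "p_value": r.p_value,
                "critical_value": r.critical_value,
                "reject": r.reject,
            }
            for r in res.intersection_results
        ],
    }


def write_report(res: ClosedMCPModResults, path, format: str = "json") -> Path:
    """Write a fitted report as json, csv (intersection table) or text."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(res), indent=2))
    elif format == "csv":
        res.pvalue_table().to_csv(path)
    elif format == "text":
        path.write_text(res.summary() + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (design + candidates + options)."""

    design: DoseDesign
    candidate_set: CandidateSet
    alpha: float = 0.025
    constrained: bool = True
    seed: int = 0

    _KEYS = {"doses", "allocations", "candidates", "alpha", "constrained", "seed"}

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RunConfig":
        unknown = set(cfg) - cls._KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("doses", "allocations", "candidates"):
            if key not in cfg:
                raise ValueError(f"config is missing required key {key!r}")
        design = DoseDesign(cfg["doses"], cfg["allocations"])
        cset = CandidateSet.from_config(cfg["candidates"])
        alpha = float(cfg.get("alpha", 0.025))
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return cls(
            design=design,
            candidate_set=cset,
            alpha=alpha,
            constrained=bool(cfg.get("constrained", True)),
            seed=int(cfg.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        cfg = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_mapping(cfg)


def make_fixture(
    seed: int,
    design: DoseDesign | None = None,
    cset: CandidateSet | None = None,
    model: CandidateModel | None = None,
    effect: float = 0.4,
    sigma: float = 1.0,
    alpha: float = 0.025,
):
    """Deterministic synthetic trial plus its fitted report.

    Emulates the case-study setting by default: 100 patients per arm on
    doses (0, 0.1, 0.4, 1), Emax2 truth with maximum effect 0.4 and
    residual SD 1.  Returns ``(frame, results)`` where ``frame`` is the
    per-patient (dose, response) table and ``results`` the constrained
    closed MCP-Mod report for it.
    """
    from .models import default_candidate_set
    from .simulate import Scenario, simulate_trial

    design = design or DoseDesign((0.0, 0.1, 0.4, 1.0), (100, 100, 100, 100))
    cset = cset or default_candidate_set()
    model = model or CandidateModel("emax", {"ed50": 0.2}, label="truth")
    sc = Scenario(
        design=design, model=model, effect=effect, sigma=sigma,
        nsim=1, seed=seed,
    )
    data = simulate_trial(sc, 0)
    frame = pd.DataFrame(
        {
            "dose": [design.doses[a] for a in data.arm],
            "response": data.response,
        }
    )
    results = closed_mcpmod(
        data, design, cset, constrained=True, alpha=alpha, seed=seed
    )
    return frame, results
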
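"""Edge-of-failure scanning: artifact severity x correction method.

A scan sweeps one artifact severity axis (free-AMC spike, substrate
reduction, tissue-factor dose, antithrombin fraction), simulates a plate
at each severity, runs every requested correction method, and classifies
each cell against the simulator's ground truth.  The *set point* of a
method is the smallest severity at which it stops returning an
acceptable curve -- the computational analogue of an edge-of-failure
determination on the bench.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .calibrate import FailureThresholds, Method, STATUS_OK
from .io import ReportDoc
from .params import ParamDefs, TGParams, extract_params
from .pipeline import analyze_plate
from .simulate import generate_plate
from .calibrate import ThrombinCurve, FailureStatus

__all__ = [
    "SeverityGrid",
    "SetPoint",
    "CellResult",
    "EdgeReport",
    "run_scan",
    "find_set_point",
    "summarize_table",
]

# severity axes and how a value is injected into a scenario config
_AXES = ("amc_spike", "substrate_total", "tf_pM", "at_fraction")

#: a corrected peak more than this factor above truth counts as
#: overestimated in the qualitative outcome label
OVERESTIMATE_RATIO = 1.1
#: cells with relative TPH error below this are "within tolerance"
TPH_TOL = 0.10


@dataclass
class SeverityGrid:
    """One artifact axis with severities ordered from benign to harsh."""

    axis: str
    values: list[float]
    replicates: int = 1
    seeds: list[int] | None = None

    def validate(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}")
        if not self.values:
            raise ValueError("empty severity grid")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class CellResult:
    """One (severity, method, replicate) outcome."""

    severity: float
    method: str
    replicate: int
    params: TGParams
    status_code: str
    tph_err: float = float("nan")  # |TPH - TPH_true| / TPH_true
    etp_err: float = float("nan")
    tph_true: float = float("nan")
    etp_true: float = float("nan")


@dataclass
class SetPoint:
    """First failing severity for a method (None if the method never
    fails on the grid)."""

    method: str
    axis: str
    value: float | None
    basis: str | None  # dominant failure code at the set point


@dataclass
class EdgeReport:
    grid: SeverityGrid
    methods: list[str]
    cells: dict[tuple[float, str], list[CellResult]] = field(
        default_factory=dict
    )
    meta: dict = field(default_factory=dict)


def _scenario_for(axis: str, value: float, base: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in (base or {}).items()}
    cfg["scenario"] = "custom"
    cond = dict(cfg.get("params", {}).get("condition", {}))
    kin = dict(cfg.get("params", {}).get("kinetics", {}))
    if axis in ("amc_spike", "substrate_total"):
        cond[axis] = float(value)
    else:
        kin[axis] = float(value)
    label = f"{axis}={value:g}"
    cfg["params"] = {
        "conditions": [
            {"label": label, "condition": cond, "kinetics": kin}
        ]
    }
    return cfg


def run_scan(
    grid: SeverityGrid,
    methods: list[str | Method],
    base_scenario: dict | None = None,
    seeds: list[int] | None = None,
    thresholds: FailureThresholds | None = None,
    param_defs: ParamDefs | None = None,
) -> EdgeReport:
    """Sweep the severity grid and analyze with every method.

    One plate is simulated per (severity, replicate); all methods see
    the same plates, matching the bench design where every software
    package reanalyzes the same raw fluorescence.  Deterministic given
    the seed list.
    """
    grid.validate()
    if not methods:
        raise ValueError("empty method list")
    mnames = [m.name if isinstance(m, Method) else m for m in methods]
    seeds = seeds if seeds is not None else grid.seeds
    if seeds is None:
        seeds = list(range(1, grid.replicates + 1))
    if len(seeds) < grid.replicates:
        raise ValueError("need one seed per replicate")
    report = EdgeReport(grid=grid, methods=mnames,
                        meta={"base_scenario": base_scenario or {}})
    for value in grid.values:
        cfg = _scenario_for(grid.axis, value, base_scenario or {})
        for m in mnames:
            report.cells[(value, m)] = []
        for rep in range(grid.replicates):
            plate = generate_plate(cfg, seed=int(seeds[rep]))
            sample = plate.sample_wells()[0]
            truth = plate.truth[sample.well_id]
            truth_curve = ThrombinCurve(
                times=truth.times,
                free_thrombin=truth.free_thrombin,
                status=FailureStatus(),
            )
            tp = extract_params(truth_curve, param_defs)
            for m, name in zip(methods, mnames):
                res = analyze_plate(plate, m, thresholds, param_defs)[0]
                cell = CellResult(
                    severity=float(value),
                    method=name,
                    replicate=rep,
                    params=res.params,
                    status_code=res.curve.status.code,
                    tph_true=tp.tph,
                    etp_true=tp.etp,
                )
                if np.isfinite(res.params.tph) and tp.tph > 0:
                    cell.tph_err = abs(res.params.tph - tp.tph) / tp.tph
                if np.isfinite(res.params.etp) and tp.etp > 0:
                    cell.etp_err = abs(res.params.etp - tp.etp) / tp.etp
                report.cells[(value, name)].append(cell)
    return report


def find_set_point(report: EdgeReport, method: str) -> SetPoint:
    """Smallest severity at which at least half the replicates fail."""
    if method not in report.methods:
        raise ValueError(f"method {method!r} not covered by the report")
    for value in report.grid.values:
        cells = report.cells[(value, method)]
        failing = [c.status_code for c in cells
                   if c.status_code != STATUS_OK]
        if 2 * len(failing) >= len(cells) and failing:
            basis = Counter(failing).most_common(1)[0][0]
            return SetPoint(method=method, axis=report.grid.axis,
                            value=float(value), basis=basis)
    return SetPoint(method=method, axis=report.grid.axis, value=None,
                    basis=None)


def _cell_entry(cells: list[CellResult]) -> dict:
    """Aggregate replicate cells into one JSON-safe report entry."""
    codes = Counter(c.status_code for c in cells)
    worst = "no_curve" if codes.get("no_curve") else (
        "nonphysical" if codes.get("nonphysical") else "ok"
    )
    def _mean(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")
    return {
        "lag_time": _mean([c.params.lag_time for c in cells]),
        "time_to_peak": _mean([c.params.time_to_peak for c in cells]),
        "tph": _mean([c.params.tph for c in cells]),
        "etp": _mean([c.params.etp for c in cells]),
        "tph_err": _mean([c.tph_err for c in cells]),
        "etp_err": _mean([c.etp_err for c in cells]),
        "status": worst,
        "n_replicates": len(cells),
        "n_failed": sum(v for k, v in codes.items() if k != STATUS_OK),
    }


def summarize_table(report: EdgeReport) -> ReportDoc:
    """Condense a scan into a report document.

    One entry per (severity, method) plus one set-point row per method
    with a qualitative label: ``failed`` when the method stops reporting
    curves (no_curve basis), ``overestimated`` when it returns finite
    but inflated peaks (nonphysical basis or TPH more than 10% above
    truth), ``corrected`` otherwise.  Each row also records the largest
    severity at which the TPH error stays below 10%.
    """
    conditions = [f"{report.grid.axis}={v:g}" for v in report.grid.values]
    doc = ReportDoc(conditions=conditions, methods=list(report.methods),
                    meta={"axis": report.grid.axis,
                          "replicates": report.grid.replicates})
    for v, cond in zip(report.grid.values, conditions):
        for m in report.methods:
            doc.entries[(cond, m)] = _cell_entry(report.cells[(v, m)])
    for m in report.methods:
        sp = find_set_point(report, m)
        over = any(
            np.isfinite(c.params.tph) and c.tph_true > 0
            and c.params.tph > OVERESTIMATE_RATIO * c.tph_true
            for v in report.grid.values
            for c in report.cells[(v, m)]
        )
        if sp.value is not None and sp.basis == "no_curve":
            label = "failed"
        elif over or (sp.value is not None):
            label = "overestimated"
        else:
            label = "corrected"
        within = [
            v for v in report.grid.values
            if all(np.isfinite(c.tph_err) and c.tph_err < TPH_TOL
                   for c in report.cells[(v, m)])
        ]
        doc.set_points.append({
            "method": m,
            "axis": report.grid.axis,
            "set_point": sp.value,
            "basis": sp.basis,
            "label": label,
            "max_severity_within_tol": max(within) if within else None,
        })
    doc.validate()
    return doc
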
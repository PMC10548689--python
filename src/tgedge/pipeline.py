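"""End-to-end analysis of a plate: calibrate, correct, subtract, extract.

Ties the modules together the way the assay is actually analyzed: for
each sample condition, the paired calibrator wells are averaged and
fitted; every sample well is differentiated, calibrated with the chosen
method, stripped of its alpha2M tail, screened by the failure detector,
and reduced to TG parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import (
    CalibModel,
    FailureThresholds,
    Method,
    PRESETS,
    ThrombinCurve,
    cat_correct,
    detect_failure,
    fit_calibrator,
    internal_linear,
)
from .params import ParamDefs, TGParams, extract_params
from .plate import Plate, Well, ROLE_CALIBRATOR
from .smoothing import differentiate

__all__ = ["WellResult", "analyze_well", "analyze_plate", "mean_calibrator"]


@dataclass
class WellResult:
    """Per-well analysis output."""

    well_id: str
    condition_label: str
    method: str
    curve: ThrombinCurve
    params: TGParams
    calib: CalibModel | None = None


def mean_calibrator(calib_wells: list[Well]) -> Well:
    """Average replicate calibrator wells into one (shared grid)."""
    if not calib_wells:
        raise ValueError("no calibrator wells supplied")
    first = calib_wells[0]
    for w in calib_wells[1:]:
        if w.times.shape != first.times.shape or not np.allclose(
            w.times, first.times
        ):
            raise ValueError("calibrator wells do not share a time grid")
    rfu = np.mean([w.rfu for w in calib_wells], axis=0)
    return Well(
        well_id="+".join(w.well_id for w in calib_wells),
        role=ROLE_CALIBRATOR,
        condition=first.condition,
        times=first.times.copy(),
        rfu=rfu,
    )


def _resolve_method(method: str | Method) -> Method:
    if isinstance(method, Method):
        return method
    if method not in PRESETS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(PRESETS)}"
        )
    return PRESETS[method]


def analyze_well(
    sample_well: Well,
    calib: CalibModel,
    method: str | Method,
    thresholds: FailureThresholds | None = None,
    param_defs: ParamDefs | None = None,
) -> WellResult:
    """Run one sample well through the chosen calibration method."""
    m = _resolve_method(method)
    spec = m.spec
    if m.kind == "internal":
        rate = differentiate(sample_well, spec.smoother)
        ac = internal_linear(rate, calib)
    else:
        ac = cat_correct(sample_well, calib, spec)
    from .calibrate import subtract_alpha2m

    k = spec.alpha2m_k if spec.alpha2m == "fixed_k" else None
    tc = subtract_alpha2m(ac, mode=spec.alpha2m, k=k)
    tc.status = detect_failure(tc, calib.activity, thresholds)
    return WellResult(
        well_id=sample_well.well_id,
        condition_label=sample_well.condition.label,
        method=m.name,
        curve=tc,
        params=extract_params(tc, param_defs),
        calib=calib,
    )


def analyze_plate(
    plate: Plate,
    method: str | Method,
    thresholds: FailureThresholds | None = None,
    param_defs: ParamDefs | None = None,
) -> list[WellResult]:
    """Analyze every sample well on a plate with one method.

    The calibrator group paired with each condition label is averaged
    and fitted once per condition; the polynomial order comes from the
    method's correction spec.
    """
    m = _resolve_method(method)
    plate.validate()
    results: list[WellResult] = []
    for label in plate.condition_labels():
        cal = mean_calibrator(plate.calibrator_wells(label))
        calib = fit_calibrator(cal, order=m.spec.poly_order)
        for w in plate.sample_wells(label):
            results.append(
                analyze_well(w, calib, m, thresholds, param_defs)
            )
    return results
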
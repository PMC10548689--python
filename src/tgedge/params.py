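"""Thrombin-generation curve parameters, normalization and comparison.

Four curve parameters are extracted: lag time, time to peak, thrombin
peak height (TPH, the curve maximum in nM) and endogenous thrombin
potential (ETP, the area under the curve in nM*min, by the trapezoid
rule over the full record).  The lag time uses a hybrid threshold,
max(lag_abs_nM, lag_frac * TPH), which is robust both for hemophilia
curves (low peaks) and normal curves.

Normalization expresses a test curve relative to the peak height of a
reference sample (e.g. FVIII-deficient plasma supplemented with 1 IU/mL
FVIII); artifacts affecting test and reference alike cancel in the
ratio, which is why normalization can substitute for algorithmic
artifact correction when a matched reference exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .calibrate import (
    ActivityCurve,
    FailureStatus,
    STATUS_NO_CURVE,
    STATUS_NONPHYSICAL,
    ThrombinCurve,
)

__all__ = [
    "ParamDefs",
    "TGParams",
    "NormalizedResult",
    "PairedComparison",
    "extract_params",
    "normalize_to_reference",
    "paired_compare",
]


@dataclass
class ParamDefs:
    """Parameter-extraction definitions.

    lag_abs_nM : absolute lag threshold, nM
    lag_frac   : fractional lag threshold (fraction of TPH)
    clip_negatives : clip negative curve values to 0 for TPH/ETP/lag
        (raw values are kept on the curve itself for noise statistics)
    """

    lag_abs_nM: float = 2.0
    lag_frac: float = 0.10
    clip_negatives: bool = True


@dataclass
class TGParams:
    """Extracted thrombin-generation parameters (nan when unavailable)."""

    lag_time: float = float("nan")
    time_to_peak: float = float("nan")
    tph: float = float("nan")
    etp: float = float("nan")
    status: FailureStatus = field(default_factory=FailureStatus)


@dataclass
class NormalizedResult:
    """A curve or peak height expressed relative to a reference TPH."""

    tph_ratio: float
    reference_label: str = "reference"
    ratio_curve: np.ndarray | None = None


@dataclass
class PairedComparison:
    """Two-group comparison of TG parameter values via a t-test."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_stat: float
    p_value: float
    alpha: float = 0.05
    mode: str = "paired"
    flag: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _curve_values(curve) -> tuple[np.ndarray, np.ndarray, FailureStatus]:
    if isinstance(curve, ThrombinCurve):
        return curve.times, curve.free_thrombin, curve.status
    if isinstance(curve, ActivityCurve):
        return curve.times, curve.amidolytic, curve.status
    raise TypeError("expected a ThrombinCurve or ActivityCurve")


def extract_params(curve, defs: ParamDefs | None = None) -> TGParams:
    """Extract lag time, time to peak, TPH and ETP from a curve.

    A ``no_curve`` input yields no parameters.  A curve whose peak never
    reaches the lag threshold (e.g. an all-zero curve) has no defined
    lag and is marked ``nonphysical`` for parameter purposes.
    """
    if defs is None:
        defs = ParamDefs()
    t, v, status = _curve_values(curve)
    if status.code == STATUS_NO_CURVE:
        return TGParams(status=replace(status))
    vv = np.maximum(v, 0.0) if defs.clip_negatives else v
    tph = float(np.max(vv))
    i_peak = int(np.argmax(vv))  # first maximum
    etp = float(np.trapezoid(vv, t))
    thr = max(defs.lag_abs_nM, defs.lag_frac * tph)
    above = np.nonzero(vv >= thr)[0]
    if tph <= 0 or above.size == 0:
        st = replace(status)
        st.code = STATUS_NONPHYSICAL
        st.detail = (st.detail + "; " if st.detail else "") + \
            "curve never reaches the lag threshold"
        return TGParams(tph=tph, etp=etp, status=st)
    lag = float(t[above[0]])
    return TGParams(
        lag_time=lag,
        time_to_peak=float(t[i_peak]),
        tph=tph,
        etp=etp,
        status=replace(status),
    )


def normalize_to_reference(
    test, reference_tph: float, reference_label: str = "reference"
) -> NormalizedResult:
    """Normalize a curve or TGParams against a reference peak height."""
    if not np.isfinite(reference_tph) or reference_tph <= 0:
        raise ValueError("reference_tph must be > 0")
    if isinstance(test, TGParams):
        return NormalizedResult(
            tph_ratio=test.tph / reference_tph,
            reference_label=reference_label,
        )
    t, v, _status = _curve_values(test)
    ratio_curve = v / reference_tph
    return NormalizedResult(
        tph_ratio=float(np.max(np.maximum(v, 0.0))) / reference_tph,
        reference_label=reference_label,
        ratio_curve=ratio_curve,
    )


def paired_compare(
    values_a,
    values_b,
    alpha: float = 0.05,
    mode: str = "paired",
) -> PairedComparison:
    """Compare two sets of TG parameter values with a t-test.

    ``paired`` (default) performs a paired t-test on the differences;
    ``two_sample`` an independent two-sample t-test.  Degenerate paired
    input with identical nonzero differences and zero variance reports a
    machine-floor p-value with a flag instead of NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if mode == "paired" and a.size != b.size:
        raise ValueError("paired mode requires equal-length inputs")
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    flag = ""
    if mode == "paired":
        d = a - b
        if np.allclose(d, d[0]) and abs(float(d[0])) > 0:
            t_stat = float("inf") if d[0] > 0 else float("-inf")
            p = float(np.nextafter(0.0, 1.0))
            flag = "zero-variance differences with nonzero mean"
        elif np.allclose(d, 0.0):
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)
    elif mode == "two_sample":
        res = stats.ttest_ind(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):
            p = float(np.nextafter(0.0, 1.0))
            flag = "degenerate variance"
    else:
        raise ValueError("mode must be 'paired' or 'two_sample'")
    return PairedComparison(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        t_stat=t_stat,
        p_value=p,
        alpha=alpha,
        mode=mode,
        flag=flag,
    )
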
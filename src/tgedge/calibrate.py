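"""Conversion of rate curves to thrombin-equivalent activity.

Two calibration routes are implemented, mirroring how published
thrombin-generation analysis tools work:

* **Internal linear calibration** -- the uncalibrated rate curve is
  multiplied by a single coefficient, activity / slope0, where slope0 is
  the initial linear slope of the calibrator fluorescence curve.  This
  converts RFU/min to nM without correcting any fluorescence artifact,
  and it never fails.

* **Calibrator-based (CAT-style) correction** -- the calibrator
  fluorescence curve is fitted with a 3rd- or 4th-order polynomial; for
  every sample time point the calibrator time t* at which the fitted
  calibrator fluorescence matches the sample fluorescence is located by
  root finding, and the sample rate is divided by the calibrator
  velocity at that matched fluorescence.  Because the calibrator's
  activity is constant, its velocity at a given fluorescence level
  encodes how much the optics (inner filter effect) and substrate
  consumption attenuate the signal at that level, so the quotient
  linearizes the sample's signal.  Sample fluorescence beyond the
  calibrator's observed range either aborts the well (``refuse``, the
  behavior of the commercial software that "does not report" distorted
  curves) or extrapolates with a capped correction factor
  (``extrapolate``, the behavior of the open implementations whose
  curves shoot up when the cap would be exceeded).

After calibration the residual alpha2-macroglobulin--thrombin activity is
removed by discrete deconvolution, and failure heuristics (activity cap,
second-peak artifact, noise amplification) classify the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .plate import Well, ROLE_CALIBRATOR
from .smoothing import RateCurve, SmootherSpec, differentiate

__all__ = [
    "CalibModel",
    "CorrectionSpec",
    "ActivityCurve",
    "ThrombinCurve",
    "FailureStatus",
    "FailureThresholds",
    "Method",
    "PRESETS",
    "fit_calibrator",
    "internal_linear",
    "cat_correct",
    "subtract_alpha2m",
    "detect_failure",
]

STATUS_OK = "ok"
STATUS_OUT_OF_RANGE = "out_of_range"
STATUS_NONPHYSICAL = "nonphysical"
STATUS_NO_CURVE = "no_curve"


@dataclass
class FailureStatus:
    """Outcome classification of a calibrated curve.

    noise_amplification is the ratio of the detrended tail standard
    deviation to the detrended pre-lag standard deviation; correction
    algorithms amplify fluorescence noise wherever their correction
    factor is large, and this ratio quantifies it.
    """

    code: str = STATUS_OK
    detail: str = ""
    noise_amplification: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.code == STATUS_OK


@dataclass
class CalibModel:
    """Fitted calibrator curve.

    poly is a numpy Polynomial of the baseline-subtracted calibrator
    fluorescence vs time (minutes); slope0 its derivative at the first
    fitted time; t_turn the end of the monotone-increasing branch used
    for fluorescence-matched inversion.
    """

    poly: np.polynomial.Polynomial
    order: int
    slope0: float
    activity: float
    f_range: tuple[float, float]
    t_range: tuple[float, float]
    t_turn: float
    baseline: float
    monotone_ok: bool = True


@dataclass
class CorrectionSpec:
    """Parameters of a calibrator-based correction variant."""

    poly_order: int = 3
    smoother: SmootherSpec = field(
        default_factory=lambda: SmootherSpec("savgol", 5, 2)
    )
    range_policy: str = "extrapolate"  # or "refuse"
    alpha2m: str = "auto_k"  # "off" | "fixed_k" | "auto_k"
    alpha2m_k: float = 0.0  # used when alpha2m == "fixed_k"
    max_gain: float = 20.0

    def validate(self) -> None:
        if self.poly_order not in (3, 4):
            raise ValueError("poly_order must be 3 or 4")
        if self.range_policy not in ("refuse", "extrapolate"):
            raise ValueError("range_policy must be refuse|extrapolate")
        if self.alpha2m not in ("off", "fixed_k", "auto_k"):
            raise ValueError("alpha2m must be off|fixed_k|auto_k")
        if self.max_gain <= 1:
            raise ValueError("max_gain must be > 1")
        self.smoother.validate()


@dataclass
class ActivityCurve:
    """Amidolytic activity in nM thrombin-equivalent, before alpha2M
    subtraction."""

    times: np.ndarray
    amidolytic: np.ndarray
    status: FailureStatus = field(default_factory=FailureStatus)
    correction_factor: np.ndarray | None = None


@dataclass
class ThrombinCurve:
    """Free thrombin in nM after alpha2M subtraction."""

    times: np.ndarray
    free_thrombin: np.ndarray
    k_a2m_used: float = 0.0
    status: FailureStatus = field(default_factory=FailureStatus)


@dataclass
class Method:
    """A named analysis preset: calibration route plus correction spec."""

    name: str
    kind: str  # "internal" | "cat"
    spec: CorrectionSpec


def _preset(name: str, kind: str, **kw) -> Method:
    return Method(name=name, kind=kind, spec=CorrectionSpec(**kw))


#: Analysis presets exposed on the command line.  ``linear`` applies the
#: internal linear calibration (no artifact correction).  ``cat3sg`` uses
#: a 3rd-order calibrator polynomial with a Savitzky-Golay smoothed
#: derivative; ``cat4ss`` a 4th-order polynomial with SuperSmoother
#: smoothing; ``cat_strict`` is the refuse-on-out-of-range variant that
#: aborts rather than extrapolate.
PRESETS: dict[str, Method] = {
    "linear": _preset(
        "linear", "internal", smoother=SmootherSpec("none"),
        alpha2m="auto_k",
    ),
    "cat3sg": _preset(
        "cat3sg", "cat", poly_order=3,
        smoother=SmootherSpec("savgol", 5, 2),
        range_policy="extrapolate", alpha2m="auto_k",
    ),
    "cat4ss": _preset(
        "cat4ss", "cat", poly_order=4,
        smoother=SmootherSpec("supersmoother"),
        range_policy="extrapolate", alpha2m="auto_k",
    ),
    "cat_strict": _preset(
        "cat_strict", "cat", poly_order=3,
        smoother=SmootherSpec("savgol", 5, 2),
        range_policy="refuse", alpha2m="auto_k",
    ),
}


def fit_calibrator(
    calib_well: Well,
    order: int = 3,
    activity: float | None = None,
    initial_skip: int = 0,
) -> CalibModel:
    """Least-squares polynomial fit of a calibrator fluorescence curve.

    The fluorescence at the first retained point is subtracted as the
    baseline before fitting (samples are baseline-subtracted the same
    way before correction).  slope0 is the fitted derivative at the
    start of the window -- the "initial linear slope" used by internal
    linear calibration.  ``initial_skip`` drops early points, e.g. to
    exclude the settling transient some instruments show.
    """
    if order not in (3, 4):
        raise ValueError("order must be 3 or 4")
    if calib_well.role != ROLE_CALIBRATOR:
        raise ValueError(
            f"well {calib_well.well_id!r} is not a calibrator well"
        )
    if activity is None:
        activity = calib_well.condition.calibrator_activity
    if activity <= 0:
        raise ValueError("calibrator activity must be > 0")
    t = calib_well.times[initial_skip:]
    if t.size < order + 3:
        raise ValueError(f"calibrator needs >= {order + 3} points")
    baseline = float(calib_well.rfu[initial_skip])
    y = calib_well.rfu[initial_skip:] - baseline
    poly = np.polynomial.Polynomial.fit(t, y, order)
    dpoly = poly.deriv()
    slope0 = float(dpoly(t[0]))
    if slope0 <= 0:
        raise ValueError(
            "fitted initial calibrator slope is not positive; the well "
            "does not look like an active calibrator"
        )
    # monotone-increasing branch: up to the first root of the derivative
    t_turn = float(t[-1])
    monotone_ok = True
    roots = dpoly.roots()
    real = roots[np.isreal(roots)].real if roots.size else np.array([])
    inside = real[(real > t[0] + 1e-12) & (real < t[-1] - 1e-12)]
    if inside.size:
        t_turn = float(inside.min())
        monotone_ok = False
    return CalibModel(
        poly=poly,
        order=order,
        slope0=slope0,
        activity=float(activity),
        f_range=(float(y.min()), float(y.max())),
        t_range=(float(t[0]), float(t[-1])),
        t_turn=t_turn,
        baseline=baseline,
        monotone_ok=monotone_ok,
    )


def internal_linear(rate: RateCurve, calib: CalibModel) -> ActivityCurve:
    """Single-coefficient calibration: activity * rate / slope0.

    Applies the same conversion factor at every fluorescence level, so
    inner-filter and consumption artifacts pass through uncorrected.
    Never fails.
    """
    if calib.slope0 <= 0:
        raise ValueError("calibrator slope0 must be > 0")
    amid = calib.activity * rate.rate / calib.slope0
    return ActivityCurve(times=rate.times.copy(), amidolytic=amid)


def _invert_poly(
    calib: CalibModel, f_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map sample fluorescence levels onto calibrator times t* with
    fitted F_cal(t*) = F, on the monotone branch [t0, t_turn].

    Returns (t_star, out_of_range mask).  Levels below the branch clamp
    to t0 (the correction factor there is ~1); levels above the branch
    maximum are flagged out of range.
    """
    t0 = calib.t_range[0]
    t1 = calib.t_turn
    grid = np.linspace(t0, t1, 2048)
    fgrid = calib.poly(grid)
    f_hi = fgrid[-1]
    out = f_values > f_hi
    t_star = np.interp(f_values, fgrid, grid, left=t0, right=t1)
    # polish interior points with a couple of Newton steps
    dpoly = calib.poly.deriv()
    for _ in range(3):
        fv = calib.poly(t_star)
        dv = dpoly(t_star)
        safe = dv > 0
        step = np.where(safe, (fv - f_values) / np.where(safe, dv, 1.0), 0.0)
        t_star = np.clip(t_star - step, t0, t1)
    return t_star, out


def cat_correct(
    sample_well: Well,
    calib: CalibModel,
    spec: CorrectionSpec | None = None,
) -> ActivityCurve:
    """Fluorescence-matched calibrator correction of a sample well.

    For each sample time t the calibrator time t* at matched (fitted)
    fluorescence is found; the amidolytic activity is
    activity * dF_sample/dt / v*(F_sample) with v* the calibrator
    velocity at the matched level.  Sample and calibrator are referred
    to the *calibrator's* initial reading (the shared instrument
    baseline): a sample whose fluorophore load is elevated at the start
    (e.g. by spiked free AMC) is thereby matched onto the later, more
    attenuated part of the calibrator curve, which is exactly how the
    calibrator encodes the inner filter effect at that signal level.
    The running correction factor slope0 / v* (1 at the start, growing
    as the calibrator curve bends) is capped at ``max_gain``; capped
    points mark the curve ``nonphysical``.  With
    ``range_policy='refuse'``, any sample fluorescence above the
    calibrator's fitted range aborts the whole well with ``no_curve``.
    """
    if spec is None:
        spec = CorrectionSpec()
    spec.validate()
    rate = differentiate(sample_well, spec.smoother)
    ys = sample_well.rfu - calib.baseline
    t_star, out = _invert_poly(calib, ys)
    # the refuse policy keys on the *observed* calibrator range; the
    # fitted monotone branch may end slightly earlier or later
    out_obs = ys > calib.f_range[1]
    if out_obs.any() and spec.range_policy == "refuse":
        i = int(np.argmax(out_obs))
        status = FailureStatus(
            code=STATUS_NO_CURVE,
            detail=(
                f"sample fluorescence exceeds the calibrator range from "
                f"t={sample_well.times[i]:.2f} min; refusing to report"
            ),
        )
        nan = np.full_like(ys, np.nan)
        return ActivityCurve(times=sample_well.times.copy(),
                             amidolytic=nan, status=status)
    v = calib.poly.deriv()(t_star)
    v = np.where(out, 0.0, v)  # beyond range: force the cap
    with np.errstate(divide="ignore", over="ignore"):
        factor = np.where(v > 0, calib.slope0 / np.maximum(v, 1e-300),
                          np.inf)
    clamped = factor > spec.max_gain
    factor = np.minimum(factor, spec.max_gain)
    amid = calib.activity * rate.rate * factor / calib.slope0
    if clamped.any():
        i = int(np.argmax(clamped))
        status = FailureStatus(
            code=STATUS_NONPHYSICAL,
            detail=(
                f"correction factor capped at {spec.max_gain:g} from "
                f"t={sample_well.times[i]:.2f} min "
                f"({int(clamped.sum())} points)"
            ),
        )
    else:
        status = FailureStatus(code=STATUS_OK)
    return ActivityCurve(
        times=sample_well.times.copy(),
        amidolytic=amid,
        status=status,
        correction_factor=calib.activity / np.maximum(v, 1e-300),
    )


def _deconvolve(E: np.ndarray, times: np.ndarray, k: float) -> np.ndarray:
    """Remove alpha2M-complex activity: T_i = E_i - k * sum_{j<i} T_j dt_j.

    The complex accumulates as the running integral of free thrombin, so
    its contribution is peeled off by this left-Riemann discrete
    deconvolution (k folds in the complex's amidolytic fraction).
    Negative intermediate values are retained.
    """
    n = E.size
    T = np.empty(n)
    dt = np.diff(times)
    acc = 0.0  # sum T_j dt_j over j < i
    T[0] = E[0]
    for i in range(1, n):
        acc += T[i - 1] * dt[i - 1]
        T[i] = E[i] - k * acc
    return T


AUTO_K_HI = 1.0  # 1/min, upper cap for the auto-k search
AUTO_K_TOL = 1e-4  # relative convergence tolerance of the k iteration


def subtract_alpha2m(
    activity: ActivityCurve,
    mode: str = "auto_k",
    k: float | None = None,
    tail_fraction: float = 0.1,
) -> ThrombinCurve:
    """Subtract the thrombin--alpha2M tail from an activity curve.

    ``fixed_k`` uses the supplied effective capture rate; ``auto_k``
    chooses k >= 0 so the mean free thrombin over the final
    ``tail_fraction`` of the record is zero (free thrombin is fully
    inhibited by the end of a record, so any residual mean signal there
    is complex activity).  The zero is located by the fixed-point
    iteration k <- mean_tail(E) / mean_tail(integral of T_k), which
    converges from below to the smallest root and stays finite even
    when smoothing bias leaves the estimated tail with a slight slope
    (where a naive root bracket would run away to the cap).  If the
    tail mean is already negative at k=0 the subtraction falls back to
    k=0 with a warning in the status detail.
    """
    if activity.status.code == STATUS_NO_CURVE:
        return ThrombinCurve(
            times=activity.times.copy(),
            free_thrombin=np.full_like(activity.amidolytic, np.nan),
            k_a2m_used=float("nan"),
            status=replace(activity.status),
        )
    if mode == "off":
        return ThrombinCurve(
            times=activity.times.copy(),
            free_thrombin=activity.amidolytic.copy(),
            k_a2m_used=0.0,
            status=replace(activity.status),
        )
    E = activity.amidolytic
    t = activity.times
    n_tail = max(2, int(round(tail_fraction * E.size)))
    status = replace(activity.status)
    if mode == "fixed_k":
        if k is None or k < 0:
            raise ValueError("fixed_k mode requires k >= 0")
        T = _deconvolve(E, t, k)
        return ThrombinCurve(times=t.copy(), free_thrombin=T,
                             k_a2m_used=float(k), status=status)
    if mode != "auto_k":
        raise ValueError("mode must be off|fixed_k|auto_k")

    mean_E_tail = float(np.mean(E[-n_tail:]))
    if mean_E_tail < 0:
        status.detail = (status.detail + "; " if status.detail else "") + \
            "auto_k infeasible (negative tail at k=0), using k=0"
        return ThrombinCurve(times=t.copy(), free_thrombin=E.copy(),
                             k_a2m_used=0.0, status=status)
    dt = np.diff(t)
    k_star = 0.0
    for _ in range(200):
        T = _deconvolve(E, t, k_star)
        # running integral of T with the same left-Riemann convention
        A = np.concatenate([[0.0], np.cumsum(T[:-1] * dt)])
        mean_A_tail = float(np.mean(A[-n_tail:]))
        if mean_A_tail <= 0:
            break
        k_new = min(mean_E_tail / mean_A_tail, AUTO_K_HI)
        if abs(k_new - k_star) <= AUTO_K_TOL * max(k_new, 1e-12):
            k_star = k_new
            break
        k_star = k_new
    T = _deconvolve(E, t, k_star)
    return ThrombinCurve(times=t.copy(), free_thrombin=T,
                         k_a2m_used=float(k_star), status=status)


@dataclass
class FailureThresholds:
    """Heuristic limits used by :func:`detect_failure`.

    cap_mult         : activity cap as a multiple of the calibrator
                       activity; corrected values beyond it are deemed
                       artifacts of runaway correction
    second_peak_ratio: a post-peak excursion above this multiple of the
                       first peak marks the depletion "second peak"
    noise_amp_max    : maximum tolerated tail/pre-lag noise ratio
    window_frac      : fraction of the record used for each noise window
    min_tail_frac    : tail noise must also exceed this fraction of the
                       curve maximum before the ratio counts as failure
                       (guards against flagging negligible wiggle)
    """

    cap_mult: float = 10.0
    second_peak_ratio: float = 1.2
    noise_amp_max: float = 5.0
    window_frac: float = 0.1
    min_tail_frac: float = 0.02


def _detrended_sd(t: np.ndarray, v: np.ndarray) -> float:
    """Noise level of a window: residual sd about a smooth local fit.

    A smooth fit (rather than a straight line) keeps slow curve shape
    out of the noise estimate, so late-onset thrombin curves are not
    mistaken for noisy tails.
    """
    n = v.size
    if n < 5:
        return 0.0
    from scipy.signal import savgol_filter

    win = min(11, n if n % 2 == 1 else n - 1)
    if win < 5:
        return 0.0
    smooth = savgol_filter(v, win, 2, mode="interp")
    return float(np.std(v - smooth))


def detect_failure(
    curve: ThrombinCurve | ActivityCurve,
    activity: float,
    thresholds: FailureThresholds | None = None,
) -> FailureStatus:
    """Classify a calibrated curve as ok / nonphysical / no_curve.

    A ``no_curve`` upstream status propagates.  ``nonphysical`` is
    assigned when corrected values exceed ``cap_mult`` times the
    calibrator activity, when the curve re-ascends above its first peak
    by more than ``second_peak_ratio`` (the substrate-depletion "second
    peak" artifact), or when the tail noise exceeds ``noise_amp_max``
    times the pre-lag noise.  The noise-amplification ratio is always
    reported.
    """
    if thresholds is None:
        thresholds = FailureThresholds()
    v = curve.free_thrombin if isinstance(curve, ThrombinCurve) \
        else curve.amidolytic
    t = curve.times
    prior = curve.status
    if prior.code == STATUS_NO_CURVE:
        return replace(prior)
    n = v.size
    nw = max(3, int(round(thresholds.window_frac * n)))
    pre_sd = _detrended_sd(t[:nw], v[:nw])
    tail_sd = _detrended_sd(t[-nw:], v[-nw:])
    scale = float(np.max(np.abs(v))) if n else 0.0
    floor = 1e-9 * max(1.0, scale)
    ratio = tail_sd / max(pre_sd, floor)
    problems: list[str] = []
    if np.any(np.abs(v) > thresholds.cap_mult * activity):
        problems.append(
            f"activity exceeds {thresholds.cap_mult:g}x calibrator level"
        )
    # second-peak artifact: locate the first prominent local maximum
    from scipy.signal import find_peaks

    vmax = float(np.max(v)) if n else 0.0
    if vmax > 0:
        # only substantial peaks qualify as "the" TG peak; small noise
        # bumps before the true peak must not trigger the re-ascent test
        peaks, _props = find_peaks(v, prominence=0.25 * vmax)
        if peaks.size:
            p1 = int(peaks[0])
            if p1 + 1 < n and float(np.max(v[p1 + 1:])) > \
                    thresholds.second_peak_ratio * v[p1]:
                problems.append(
                    "curve re-ascends above its first peak "
                    "(substrate-depletion artifact)"
                )
    if pre_sd > floor and ratio > thresholds.noise_amp_max \
            and tail_sd > thresholds.min_tail_frac * vmax:
        problems.append(
            f"tail noise amplified {ratio:.1f}x over pre-lag noise"
        )
    if problems or prior.code == STATUS_NONPHYSICAL:
        detail = "; ".join(
            ([prior.detail] if prior.detail else []) + problems
        )
        return FailureStatus(code=STATUS_NONPHYSICAL, detail=detail,
                             noise_amplification=ratio)
    return FailureStatus(code=STATUS_OK, detail=prior.detail,
                         noise_amplification=ratio)
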
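"""Derivative and smoothing primitives for fluorescence curves.

The first derivative of a well's fluorescence trace is the uncalibrated
thrombin-generation curve in RFU/min.  Three differentiation routes are
provided:

* ``none`` -- plain central differences (one-sided at the ends); exact
  for quadratics on a uniform grid.
* ``savgol`` -- Savitzky-Golay local-polynomial smoothed derivative
  (scipy backend, polynomial end handling).
* ``supersmoother`` -- the series is first smoothed with Friedman's
  variable-span SuperSmoother (local linear fits at tweeter/midrange/
  woofer spans, blended by leave-one-out cross-validation), then
  differentiated by central differences.

All outputs live on the native time grid of the input so that downstream
calibration and area integration share one grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .plate import Well

__all__ = [
    "SmootherSpec",
    "RateCurve",
    "smooth_savgol",
    "smooth_supersmoother",
    "differentiate",
]

_KINDS = ("none", "savgol", "supersmoother")

# canonical SuperSmoother spans (fractions of n): tweeter, midrange, woofer
SUPSMU_SPANS = (0.05, 0.2, 0.5)


@dataclass
class SmootherSpec:
    """Selects and parametrizes the smoothing applied before/while
    differentiating.

    kind      : 'none' | 'savgol' | 'supersmoother'
    window    : points, odd (savgol)
    polyorder : local polynomial order (savgol); window >= polyorder + 2
    span      : 'auto' (cross-validated spans) or a fixed fraction of n
                in (0, 1] (supersmoother)
    """

    kind: str = "none"
    window: int = 5
    polyorder: int = 2
    span: str | float = "auto"

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind == "savgol":
            if self.window % 2 == 0:
                raise ValueError("savgol window must be odd")
            if self.window < self.polyorder + 2:
                raise ValueError("savgol window must be >= polyorder + 2")
        if self.kind == "supersmoother" and self.span != "auto":
            if not (0.0 < float(self.span) <= 1.0):
                raise ValueError("span must lie in (0, 1] or be 'auto'")


@dataclass
class RateCurve:
    """Uncalibrated rate curve, RFU/min, on the source grid."""

    times: np.ndarray
    rate: np.ndarray
    smoother: SmootherSpec = field(default_factory=SmootherSpec)


def _check_series(times: np.ndarray, values: np.ndarray,
                  min_points: int = 3) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have the same length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("NaN or infinite values in input series")
    return t, y


def smooth_savgol(values: np.ndarray, window: int, polyorder: int
                  ) -> np.ndarray:
    """Savitzky-Golay least-squares local polynomial smoothing.

    Ends are handled by fitting the polynomial on the truncated window
    (scipy's ``interp`` mode).  Exact for polynomials of degree up to
    ``polyorder``.
    """
    y = np.asarray(values, dtype=float)
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > y.size:
        raise ValueError("window exceeds series length")
    return savgol_filter(y, window, polyorder, mode="interp")


def _running_linear(t: np.ndarray, y: np.ndarray, half: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Local linear fit in a running window of ``half`` points per side.

    Returns the smoothed values and the absolute leave-one-out
    cross-validation residuals.  O(n) via cumulative sums.
    """
    n = t.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    m = c1[hi + 1] - c1[lo]
    st = ct[hi + 1] - ct[lo]
    sy = cy[hi + 1] - cy[lo]
    stt = ctt[hi + 1] - ctt[lo]
    sty = cty[hi + 1] - cty[lo]
    tbar = st / m
    ybar = sy / m
    var = stt - st * tbar  # sum (t - tbar)^2
    cov = sty - st * ybar  # sum (t - tbar)(y - ybar)
    tiny = 1e-30 * max(1.0, float(np.max(t * t)))
    slope = np.where(var > tiny, cov / np.maximum(var, tiny), 0.0)
    fit = ybar + slope * (t - tbar)
    # leverage of the center point in its own window
    h = 1.0 / m + np.where(
        var > tiny, (t - tbar) ** 2 / np.maximum(var, tiny), 0.0
    )
    denom = np.maximum(1.0 - h, 1e-10)
    cv = np.abs((y - fit) / denom)
    return fit, cv


def _span_half(frac: float, n: int) -> int:
    return max(2, int(round(frac * n / 2.0)))


def smooth_supersmoother(
    times: np.ndarray,
    values: np.ndarray,
    span: str | float = "auto",
    spans: tuple[float, float, float] = SUPSMU_SPANS,
) -> np.ndarray:
    """Friedman's variable-span SuperSmoother (bass enhancement 0).

    Local linear fits are computed at the tweeter, midrange and woofer
    spans; the span minimizing the (midrange-smoothed) leave-one-out
    absolute residual is chosen pointwise, the chosen spans are smoothed,
    and the fitted values are interpolated between the bracketing spans.
    Deterministic.  A numeric ``span`` skips the cross-validation and
    applies a single fixed-span local linear smooth.
    """
    t, y = _check_series(times, values, min_points=3)
    n = t.size
    if span != "auto":
        return _running_linear(t, y, _span_half(float(span), n))[0]
    if n < 10:
        raise ValueError("auto-span supersmoother needs >= 10 points")
    spans = tuple(sorted(spans))
    fits = []
    cvs = []
    mid_half = _span_half(spans[1], n)
    for frac in spans:
        fit, cv = _running_linear(t, y, _span_half(frac, n))
        fits.append(fit)
        # smooth the CV residuals with the midrange span
        cvs.append(_running_linear(t, cv, mid_half)[0])
    fits = np.asarray(fits)
    cvs = np.asarray(cvs)
    best = np.argmin(cvs, axis=0)
    span_arr = np.asarray(spans)[best]
    # smooth the chosen spans, then interpolate between bracketing spans
    span_smooth = np.clip(
        _running_linear(t, span_arr, mid_half)[0], spans[0], spans[-1]
    )
    out = np.empty(n)
    for i in range(n):
        s = span_smooth[i]
        j = int(np.searchsorted(spans, s))
        if j == 0:
            out[i] = fits[0, i]
        elif j >= len(spans):
            out[i] = fits[-1, i]
        else:
            w = (s - spans[j - 1]) / (spans[j] - spans[j - 1])
            out[i] = (1 - w) * fits[j - 1, i] + w * fits[j, i]
    # final pass at the tweeter span stabilizes the blend
    out = _running_linear(t, out, _span_half(spans[0], n))[0]
    return out


def differentiate(
    curve: Well | tuple[np.ndarray, np.ndarray],
    spec: SmootherSpec | None = None,
) -> RateCurve:
    """First derivative of a fluorescence series, RFU/min.

    Accepts a :class:`~tgedge.plate.Well` or a ``(times, values)`` pair.
    Interior points use central differences (exact for quadratics on a
    uniform grid); the ends are one-sided.  ``savgol`` computes the
    smoothed derivative directly from the local polynomial fit and
    requires a uniform grid; ``supersmoother`` smooths first, then
    differentiates.
    """
    if spec is None:
        spec = SmootherSpec()
    spec.validate()
    if isinstance(curve, Well):
        t, y = curve.times, curve.rfu
    else:
        t, y = curve
    t, y = _check_series(t, y)
    if spec.kind == "none":
        rate = np.gradient(y, t)
    elif spec.kind == "savgol":
        if spec.window > y.size:
            raise ValueError("fewer points than the savgol window")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("savgol derivative requires a uniform grid")
        rate = savgol_filter(
            y, spec.window, spec.polyorder, deriv=1, delta=dt[0],
            mode="interp",
        )
    else:  # supersmoother
        ys = smooth_supersmoother(t, y, span=spec.span)
        rate = np.gradient(ys, t)
    return RateCurve(times=t.copy(), rate=rate, smoother=spec)
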
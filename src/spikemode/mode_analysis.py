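"""Slope and powerlaw analysis of the operation-mode measures.

For each decay time, the per-neuron measure points (x = effective
integration interval in ms, y = number of contributing input spikes) are
fitted with a least-squares line through the coordinate origin. The slope
as a function of decay time is then fitted with an offset powerlaw
``s(t) = a * t**b + c``; the offset absorbs brightness-driven shifts while
``a`` and ``b`` capture the curve's shape.

Axis convention (configurable via ``swap_axes``): steeper slopes mean more
near-simultaneous contributing spikes per millisecond of integration — the
coincidence-detector end of the spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .attribution import MeasurePoint
from .errors import FitError, ValidationError


@dataclass
class SlopeCurve:
    """Origin-constrained fit slope per decay time."""

    decay_times: np.ndarray  # ms
    slopes: np.ndarray  # contributing spikes per ms
    n_points_per_fit: np.ndarray

    def __post_init__(self):
        self.decay_times = np.asarray(self.decay_times, dtype=np.float64)
        self.slopes = np.asarray(self.slopes, dtype=np.float64)
        self.n_points_per_fit = np.asarray(self.n_points_per_fit, dtype=np.int64)
        if not np.all(np.isfinite(self.slopes)):
            raise ValidationError("slopes must be finite")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"decay_time_ms": self.decay_times,
                             "slope": self.slopes,
                             "n_points": self.n_points_per_fit})


@dataclass
class PowerlawFit:
    """Parameters of ``s(t) = a * t**b + c`` with fit diagnostics."""

    a: float
    b: float
    c: float
    residual: float  # sum of squared residuals
    init_trace: list = field(default_factory=list)

    def __call__(self, t) -> np.ndarray:
        return self.a * np.asarray(t, dtype=np.float64) ** self.b + self.c

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c,
                "residual": self.residual, "init_trace": self.init_trace}


def origin_fit(points) -> float:
    """Least-squares slope of a line through the origin.

    Closed form ``slope = sum(x*y) / sum(x**2)`` over points ``(x, y)``.

    Raises
    ------
    ValidationError
        If no point has ``x > 0`` (undefined slope; callers exclude such
        decay groups from the curve).
    """
    pts = np.asarray(list(points), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValidationError("points must be a non-empty list of (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValidationError("all x values are 0: origin slope undefined")
    return float(np.dot(x, y) / sxx)


def slope_curve(measures: list[MeasurePoint], swap_axes: bool = False) -> SlopeCurve:
    """Per-decay-time origin slopes from measure points.

    Points are grouped by decay time; within each group
    ``x = mean_interval`` and ``y = mean_n_contributing`` (reversed when
    ``swap_axes``). Groups whose slope is undefined (all intervals zero)
    are skipped with a warning.
    """
    groups: dict[float, list] = {}
    for p in measures:
        xy = (p.mean_interval, p.mean_n_contributing)
        if swap_axes:
            xy = xy[::-1]
        groups.setdefault(p.decay_time, []).append(xy)
    decay_times, slopes, n_points = [], [], []
    for t in sorted(groups):
        try:
            s = origin_fit(groups[t])
        except ValidationError:
            warnings.warn(f"decay time {t} ms: all x values zero, slope "
                          "undefined; group skipped", stacklevel=2)
            continue
        decay_times.append(t)
        slopes.append(s)
        n_points.append(len(groups[t]))
    return SlopeCurve(np.array(decay_times), np.array(slopes),
                      np.array(n_points))


def powerlaw_fit(curve: SlopeCurve, n_starts: int = 5) -> PowerlawFit:
    """Offset powerlaw ``a * t**b + c`` by nonlinear least squares.

    Initialization: ``c0`` slightly below the minimum slope, then ``a0`` and
    ``b0`` from a log-log regression of the offset-subtracted slopes.
    ``n_starts`` perturbed restarts are tried and the best residual kept;
    the perturbations come from a fixed-seed generator, so the fit is
    deterministic given the curve.

    Raises
    ------
    FitError
        If no start converges (diagnostics attached).
    ValidationError
        If fewer than 4 decay values are available.
    """
    t = curve.decay_times
    s = curve.slopes
    if t.size < 4:
        raise ValidationError("powerlaw fit needs >= 4 decay values")
    span = float(s.max() - s.min()) or 1.0
    c0 = float(s.min()) - 1e-3 * span
    resid0 = s - c0
    slope_ll, intercept_ll = np.polyfit(np.log(t), np.log(resid0), 1)
    b0, a0 = float(slope_ll), float(np.exp(intercept_ll))

    def residuals(theta):
        a, b, c = theta
        return a * t**b + c - s

    rng = np.random.default_rng(0)
    starts = [np.array([a0, b0, c0])]
    for _ in range(n_starts - 1):
        starts.append(np.array([a0, b0, c0])
                      * (1.0 + 0.2 * rng.standard_normal(3))
                      + np.array([0.0, 0.0, 0.01 * span * rng.standard_normal()]))
    best = None
    trace = []
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, method="lm", xtol=1e-14,
                                ftol=1e-14, max_nfev=10000)
        except Exception as exc:  # pragma: no cover - lm rarely raises
            trace.append({"start": list(theta0), "error": str(exc)})
            continue
        ssr = float(np.sum(res.fun**2))
        trace.append({"start": [float(v) for v in theta0], "ssr": ssr,
                      "success": bool(res.success)})
        if res.success and (best is None or ssr < best[1]):
            best = (res.x, ssr)
    if best is None:
        raise FitError("powerlaw fit failed to converge from all starts",
                       diagnostics={"trace": trace})
    (a, b, c), ssr = best
    return PowerlawFit(a=float(a), b=float(b), c=float(c), residual=ssr,
                       init_trace=trace)
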
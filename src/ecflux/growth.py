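"""Growth-curve metrics: doubling time, lag phase, final OD.

Doubling time is estimated by nonlinear least squares of
``OD = A * exp(mu * t)`` over an automatically selected exponential
window; the lag phase is the time for the culture to rise from the
inoculation density (OD600 0.1) to 0.25, found by linear interpolation
of the first crossing; final OD is the curve read off (interpolated) at
a requested time.

Window rule: candidate windows are contiguous runs of at least five
points with OD between 0.15 and half the curve maximum.  Among maximal
runs whose log-linear fit reaches R^2 >= 0.995 the one with the highest
fitted growth rate wins; if no maximal run passes (multi-phase or
saturating curves) the longest passing sub-window is used instead.
These window parameters are exposed as keyword arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class NoExponentialPhaseError(ValueError):
    """No window satisfies the exponential-phase criteria."""


class ThresholdNotReachedError(ValueError):
    """The lag-phase OD threshold is never crossed."""


@dataclass
class GrowthCurve:
    """A time (minutes) vs OD600 series."""

    time: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.shape != self.od.shape or self.time.ndim != 1:
            raise ValueError("time and od must be 1-d arrays of equal length")
        if len(self.time) < 5:
            raise ValueError("a growth curve needs at least 5 points")
        if (np.diff(self.time) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("OD readings must be >= 0")

    @classmethod
    def read_csv(cls, path, label: str | None = None) -> "GrowthCurve":
        frame = pd.read_csv(path)
        if not {"time_min", "od600"} <= set(frame.columns):
            raise ValueError("growth curve CSV needs columns 'time_min' and 'od600'")
        return cls(frame["time_min"].values, frame["od600"].values, label or str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "od600": self.od}).to_csv(
            path, index=False, float_format="%.6g"
        )


@dataclass
class GrowthMetrics:
    doubling_time_min: float
    lag_min: float | None = None
    final_od: float | None = None
    window: tuple[int, int] = (0, 0)  # [start, end) indices of the fit window
    r2: float = float("nan")


def _loglinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through log(OD); returns (mu, intercept, r2)."""
    ly = np.log(y)
    mu, b = np.polyfit(t, ly, 1)
    resid = ly - (mu * t + b)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(mu), float(b), r2


def _runs(mask: np.ndarray):
    run = []
    for i, ok in enumerate(mask):
        if ok:
            run.append(i)
        elif run:
            yield run[0], run[-1] + 1
            run = []
    if run:
        yield run[0], run[-1] + 1


def fit_doubling_time(
    curve: GrowthCurve,
    od_floor: float = 0.15,
    max_fraction: float = 0.5,
    min_points: int = 5,
    min_r2: float = 0.995,
) -> GrowthMetrics:
    """Doubling time (minutes) from the exponential phase of a curve."""
    od_cap = max_fraction * float(curve.od.max())
    mask = (curve.od >= od_floor) & (curve.od <= od_cap) & (curve.od > 0)
    candidates = []  # (mu, length, window, r2)
    maximal = [(a, b) for a, b in _runs(mask) if b - a >= min_points]
    for a, b in maximal:
        mu, _, r2 = _loglinear(curve.time[a:b], curve.od[a:b])
        if mu > 0 and r2 >= min_r2:
            candidates.append((mu, b - a, (a, b), r2))
    if candidates:
        mu0, _, (a, b), r2 = max(candidates, key=lambda c: c[0])
    else:
        # saturating / multi-phase curves: longest passing sub-window
        sub = []
        for ra, rb in maximal:
            for a in range(ra, rb - min_points + 1):
                for b in range(a + min_points, rb + 1):
                    mu, _, r2 = _loglinear(curve.time[a:b], curve.od[a:b])
                    if mu > 0 and r2 >= min_r2:
                        sub.append((b - a, mu, (a, b), r2))
        if not sub:
            n_band = int(mask.sum())
            raise NoExponentialPhaseError(
                "no exponential phase detected: "
                f"{n_band} points in the OD band [{od_floor}, {od_cap:.3g}], "
                f"no window of >= {min_points} points with R^2 >= {min_r2} "
                "and positive growth"
            )
        _, mu0, (a, b), r2 = max(sub, key=lambda c: (c[0], c[1]))
    t, y = curve.time[a:b], curve.od[a:b]
    amp0 = float(np.exp(np.log(y[0]) - mu0 * t[0]))
    (amp, mu), _ = curve_fit(
        lambda tt, aa, mm: aa * np.exp(mm * tt), t, y, p0=(amp0, mu0), maxfev=10000
    )
    if mu <= 0:  # pragma: no cover - guarded by window selection
        raise NoExponentialPhaseError("nonlinear fit collapsed to non-positive rate")
    return GrowthMetrics(
        doubling_time_min=math.log(2.0) / float(mu), window=(int(a), int(b)), r2=r2
    )


def lag_phase(
    curve: GrowthCurve, od_start: float = 0.1, od_threshold: float = 0.25
) -> float:
    """Minutes until the culture first reaches ``od_threshold``.

    Operationalizes the lag definition "time from inoculation at OD
    0.1 to reaching OD 0.25"; the crossing is located by linear
    interpolation between adjacent samples.
    """
    above = np.nonzero(curve.od >= od_threshold)[0]
    if len(above) == 0:
        raise ThresholdNotReachedError(
            f"OD threshold {od_threshold} never reached (max OD {curve.od.max():.4g})"
        )
    i = int(above[0])
    if i == 0:
        return 0.0
    t0, t1 = curve.time[i - 1], curve.time[i]
    y0, y1 = curve.od[i - 1], curve.od[i]
    return float(t0 + (od_threshold - y0) * (t1 - t0) / (y1 - y0))


def final_od(curve: GrowthCurve, at_minutes: float) -> float:
    """OD read off the curve at a requested time (linear interpolation)."""
    if at_minutes < curve.time[0] or at_minutes > curve.time[-1]:
        warnings.warn(
            f"requested time {at_minutes} min outside curve range "
            f"[{curve.time[0]}, {curve.time[-1]}]; using nearest endpoint",
            stacklevel=2,
        )
    return float(np.interp(at_minutes, curve.time, curve.od))


def percent_change(reference: float, test: float, round_to_int: bool = False) -> float:
    """``100 * (test - reference) / reference``, optionally integer-rounded."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    pct = 100.0 * (test - reference) / reference
    return float(round(pct)) if round_to_int else pct


def compute_growth_metrics(
    curve: GrowthCurve, final_at_minutes: float | None = None, **fit_kwargs
) -> GrowthMetrics:
    """Doubling time, lag and final OD for one curve in a single call."""
    metrics = fit_doubling_time(curve, **fit_kwargs)
    metrics.lag_min = lag_phase(curve)
    at = curve.time[-1] if final_at_minutes is None else final_at_minutes
    metrics.final_od = final_od(curve, at)
    return metrics
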
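"""Kinetic readouts: log-linear degradation rate, AUC, FRAP normalization.

The degradation rate of the aggregate pool is the negative slope of the
natural log of the white-puncta fraction against time (ordinary least
squares, matching a spreadsheet SLOPE on log values); aggregate formation
time courses are summarised by their trapezoidal area under the curve.
FRAP traces are normalized to the mean pre-bleach intensity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PixelCalibration
from .puncta import PunctaSet

logger = logging.getLogger("aggrequant")


@dataclass
class TimeSeries:
    """A sampled scalar against time with units attached."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = ""
    time_unit: str = "h"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            f"time_{self.time_unit}": self.times,
            self.label or "value": self.values,
        })


@dataclass
class RateEstimate:
    """A decay rate with the fit window and goodness it came from."""

    rate: float                 # per time unit, positive under decay
    window: tuple[int, int]     # first/last series index used (inclusive)
    r_squared: float
    n_used: int
    n_floored: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rate": self.rate, "window_start": self.window[0],
            "window_stop": self.window[1], "r_squared": self.r_squared,
            "n_used": self.n_used, "n_floored": self.n_floored,
        }])


def degradation_rate(series: TimeSeries,
                     window: tuple[int, int] | None = None,
                     log_floor: float | None = None) -> RateEstimate:
    """Degradation rate from log-linear decay.

    OLS slope of ln(value) against time over the fit window, multiplied
    by −1.  Values at or below ``log_floor`` are excluded (count logged).

    The default window runs from the first sample below 95% of the series
    maximum (decay onset) to the last sample above the floor; the default
    floor is 10⁻³ of the series maximum.  The estimate is scale-invariant
    and exact on noiseless exponentials.
    """
    v = series.values
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("series has no positive values to fit")
    if log_floor is None:
        log_floor = 1e-3 * vmax
    if window is None:
        below = np.nonzero(v < 0.95 * vmax)[0]
        start = int(below[0]) if len(below) else 0
        above = np.nonzero(v > log_floor)[0]
        stop = int(above[-1]) if len(above) else len(v) - 1
    else:
        start, stop = window
        if not 0 <= start <= stop < len(v):
            raise ValueError(f"window {window} out of range")
    t = series.times[start:stop + 1]
    vv = v[start:stop + 1]
    usable = vv > log_floor
    # count every excluded value from the decay onset on, including the
    # tail the automatic window already clipped
    n_floored = int((v[start:] <= log_floor).sum()) if window is None \
        else int((~usable).sum())
    if n_floored:
        logger.info("degradation_rate: excluded %d values <= floor %.3g",
                    n_floored, log_floor)
    if (vv[usable] <= 0).any():
        raise ValueError("non-positive values survive the log floor")
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable points for the log-linear fit")
    x, y = t[usable], np.log(vv[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
    return RateEstimate(rate=-slope, window=(start, stop), r_squared=float(r2),
                        n_used=int(usable.sum()), n_floored=n_floored)


def auc(series: TimeSeries) -> float:
    """Trapezoidal area under the curve over the observed time range."""
    if len(series) < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(series.values, series.times))


def frap_normalize(trace: TimeSeries, n_prebleach: int) -> TimeSeries:
    """Normalize a FRAP trace to its mean pre-bleach intensity."""
    if not 1 <= n_prebleach < len(trace):
        raise ValueError("n_prebleach must be >= 1 and < trace length")
    baseline = trace.values[:n_prebleach].mean()
    if baseline <= 0:
        raise ValueError("pre-bleach mean must be positive")
    return TimeSeries(trace.times, trace.values / baseline,
                      label=f"{trace.label or 'intensity'}_normalized",
                      unit="fraction of pre-bleach",
                      time_unit=trace.time_unit)


def puncta_count_timeseries(puncta_sets: Sequence[PunctaSet],
                            calibration: PixelCalibration,
                            label: str = "puncta_count") -> TimeSeries:
    """Object count per frame with times from the frame interval."""
    frames = [ps.frame for ps in puncta_sets]
    if frames != sorted(frames):
        raise ValueError("puncta sets must be ordered by frame")
    counts = np.array([len(ps) for ps in puncta_sets], dtype=float)
    times = np.asarray(frames, dtype=float) * calibration.frame_interval
    return TimeSeries(times, counts, label=label, unit="count",
                      time_unit=calibration.time_unit)
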
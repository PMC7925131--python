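"""Maximum specific growth rates from OD600 time series.

The estimator is deliberately model-free: blank the curve, smooth it
(moving median then moving mean), and take the maximum finite-difference
derivative of ln(OD).  For exponential growth this is the specific
growth rate r; for logistic growth it is r*(1 - OD0/K), attained at the
start of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import math

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

#: OD values at or below this floor after blanking are masked before the
#: log transform (they are reader noise, not signal)
OD_FLOOR = 0.005

DEFAULT_SMOOTHING_WINDOW = 5


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series with its blank and smoothing metadata."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray
    blank: float = 0.0
    smoothed: bool = False
    meta: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if t.ndim != 1 or t.shape != od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)):
            raise ValueError("od values must be finite")

    def __len__(self) -> int:
        return len(self.times)


def preprocess_curve(
    raw: GrowthCurve,
    blank: float | None = None,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    od_floor: float = OD_FLOOR,
) -> GrowthCurve:
    """Blank and smooth an OD600 curve.

    The blank (well/medium offset) is subtracted, then a moving median
    followed by a moving mean of the same odd window is applied —
    the median knocks out single-read spikes, the mean suppresses
    reader noise.  Edges use nearest-value padding, so a constant series
    is a fixed point of the smoother.

    Raises
    ------
    ValueError
        for an even or too-small window, a negative blank, or a curve
        that is entirely at or below the OD floor after blanking
        ("no growth signal").
    """
    if blank is None:
        blank = raw.blank
    if blank < 0:
        raise ValueError("blank must be >= 0")
    if window < 3 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 3")

    od = raw.od - blank
    od = median_filter(od, size=window, mode="nearest")
    od = uniform_filter1d(od, size=window, mode="nearest")
    if np.all(od <= od_floor):
        raise ValueError(
            f"no growth signal: all points <= {od_floor} OD after blanking"
        )
    return GrowthCurve(
        times=raw.times, od=od, blank=0.0, smoothed=True, meta=raw.meta
    )


def max_growth_rate(curve: GrowthCurve, od_floor: float = OD_FLOOR) -> float:
    """Maximum derivative of ln(OD) over the curve, in 1/min.

    Points at or below the OD floor are masked; the derivative uses
    central differences on interior points and one-sided differences at
    the ends of the usable stretch.  The input should already be blanked
    (and normally smoothed) via :func:`preprocess_curve`.

    Invariant: multiplying the whole OD series by a positive constant
    leaves the estimate unchanged (it is a log-derivative).
    """
    usable = curve.od > od_floor
    if int(usable.sum()) < 3:
        raise ValueError("need at least 3 points above the OD floor")
    t = curve.times[usable]
    ln_od = np.log(curve.od[usable])
    deriv = np.gradient(ln_od, t)
    return float(np.max(deriv))


def doubling_time(rate: float) -> float:
    """Doubling time ln(2)/rate, in minutes for a rate in 1/min."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / rate


def growth_rates_from_table(
    df: pd.DataFrame,
    blank: float = 0.0,
    window: int = DEFAULT_SMOOTHING_WINDOW,
) -> pd.DataFrame:
    """Per-sample max growth rate from a long-format (sample, time_min, od) table."""
    out = []
    for sample, grp in df.groupby("sample"):
        grp = grp.sort_values("time_min")
        curve = GrowthCurve(
            times=grp["time_min"].to_numpy(dtype=float),
            od=grp["od"].to_numpy(dtype=float),
            blank=blank,
            meta=str(sample),
        )
        rate = max_growth_rate(preprocess_curve(curve, window=window))
        out.append(
            {
                "sample": sample,
                "max_growth_rate_per_min": rate,
                "doubling_time_min": doubling_time(rate),
            }
        )
    return pd.DataFrame(out)
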
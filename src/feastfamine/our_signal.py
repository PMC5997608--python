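"""OUR signal processing for the dual-DO respirometer loop.

The oxygen uptake rate is measured from two DO probes on a recirculating
reaction tank: OUR = (DO_in - DO_out) / residence time, sampled on a
uniform 0.5-min grid.  Its discrete derivative drives the feed-on-demand
controller; a sustained return of OUR to the endogenous baseline after
budget exhaustion marks the end of the feast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OURSeries",
    "our_from_dual_do",
    "smooth_median",
    "d_our_dt",
    "detect_feast_end",
]

DEFAULT_DT_MIN = 0.5


@dataclass
class OURSeries:
    """Uniformly sampled OUR trace (mg O2/L/min) on a Delta-t grid."""

    t_min: np.ndarray
    values: np.ndarray
    provenance: str = "simulated"
    dt_min: float = field(init=False)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_min.shape != self.values.shape or self.t_min.ndim != 1:
            raise ValueError("t_min and values must be 1-D arrays of equal length")
        if len(self.t_min) >= 2:
            steps = np.diff(self.t_min)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("OURSeries requires exactly uniform spacing")
            self.dt_min = float(steps[0])
        else:
            self.dt_min = DEFAULT_DT_MIN
        self.values = np.clip(self.values, 0.0, None)

    def __len__(self) -> int:
        return len(self.t_min)

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "OURSeries":
        """Read a two-column (t_min, value) CSV, '#' comment lines allowed."""
        df = pd.read_csv(path, comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), provenance)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_min": self.t_min, "our_mg_l_min": self.values}).to_csv(
            path, index=False
        )


def our_from_dual_do(do_in, do_out, residence_time_min: float):
    """OUR (mg O2/L/min) from paired DO readings across the reaction tank.

    The difference of the two DO values is divided by the hydraulic
    residence time V_reaction/flow of the unaerated tank; negative values
    (sensor noise) clip to zero.  Accepts scalars or arrays.
    """
    if residence_time_min <= 0:
        raise ValueError("residence time must be positive")
    our = (np.asarray(do_in, dtype=float) - np.asarray(do_out, dtype=float)) / residence_time_min
    return np.clip(our, 0.0, None) if our.ndim else float(max(our, 0.0))


def smooth_median(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving-median smoothing with edge passthrough."""
    values = np.asarray(values, dtype=float)
    if window <= 1 or len(values) < window:
        return values.copy()
    half = window // 2
    out = values.copy()
    for i in range(half, len(values) - half):
        out[i] = np.median(values[i - half:i + half + 1])
    return out


def d_our_dt(series: OURSeries, n: int | None = None, smooth_window: int = 3):
    """Discrete derivative (OUR_{n+1} - OUR_n)/Delta-t, mg O2/L/min^2.

    Optionally moving-median pre-smoothed.  With ``n`` given, returns the
    single signed rate at that index; otherwise the full length-(N-1)
    array.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples to difference")
    smoothed = smooth_median(series.values, smooth_window)
    deriv = np.diff(smoothed) / series.dt_min
    if n is None:
        return deriv
    if not 0 <= n < len(deriv):
        raise IndexError(f"index {n} out of range for derivative of length {len(deriv)}")
    return float(deriv[n])


def detect_feast_end(series: OURSeries, baseline: float, tol: float = 0.1,
                     k: int = 4, floor: float = 0.05,
                     start_min: float = 0.0) -> float:
    """First time OUR returns to the endogenous baseline, sustained.

    ``baseline`` is the pre-feed endogenous OUR (mg O2/L/min); the feast is
    declared over at the first sample >= ``start_min`` from which OUR stays
    at or below ``max(baseline*(1+tol), floor)`` for ``k`` consecutive
    samples.  ``floor`` keeps the test meaningful when the baseline is
    (near) zero.  If never satisfied, the final timestamp is returned with
    a warning.
    """
    if len(series) == 0:
        raise ValueError("empty OUR series")
    threshold = max(baseline * (1.0 + tol), floor)
    below = series.values <= threshold
    eligible = series.t_min >= start_min
    run = 0
    for i in range(len(series)):
        if eligible[i] and below[i]:
            run += 1
            if run >= k:
                return float(series.t_min[i - k + 1])
        else:
            run = 0
    warnings.warn("OUR never returned to baseline; returning end of series")
    return float(series.t_min[-1])
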
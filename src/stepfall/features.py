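"""Window extrema and feature extraction for steps and falls.

All windows are addressed in seconds; a window ``[start, start + duration]``
covers every sample whose time falls inside it (both endpoints inclusive).
Ties between equal extreme values are broken by the earliest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import AccelSeries, OrientedSeries

__all__ = [
    "Extremum",
    "StepFeatures",
    "FallFeatures",
    "FallClassFeatures",
    "window_extrema",
    "step_features",
    "fall_features",
    "fall_class_features",
]


@dataclass(frozen=True)
class Extremum:
    index: int  # absolute sample index in the trace
    time: float  # seconds
    value: float
    kind: str  # "max" | "min"


@dataclass(frozen=True)
class StepFeatures:
    """f1: vertical amplitude range (g); f2: longitudinal max-minus-min
    time lag, signed, seconds."""

    f1: float
    f2: float
    window_start: float = 0.0


@dataclass(frozen=True)
class FallFeatures:
    """f1: |G| amplitude range (g); f2: elapsed time between the |G|
    minimum and maximum, milliseconds (non-negative)."""

    f1: float
    f2: float
    window_start: float = 0.0


@dataclass(frozen=True)
class FallClassFeatures:
    """Raw device-axis accelerations (g) at the |G| impact peak."""

    f1: float
    f2: float
    f3: float


def _window_indices(
    n: int, fs: float, t0: float, start: float, duration: float
) -> tuple[int, int]:
    """Inclusive [i0, i1) index range of the window; validates extent."""
    eps = 1e-9
    i0 = int(np.ceil((start - t0) * fs - eps))
    i1 = int(np.floor((start + duration - t0) * fs + eps)) + 1
    if i0 < 0 or i1 > n:
        raise ValueError(
            f"window [{start}, {start + duration}] s outside signal extent "
            f"[{t0}, {t0 + (n - 1) / fs}] s"
        )
    if i1 - i0 < 2:
        raise ValueError("window must contain at least 2 samples")
    return i0, i1


def window_extrema(
    trace: np.ndarray,
    fs: float,
    t0: float,
    start: float,
    duration: float,
) -> tuple[Extremum, Extremum]:
    """Global maximum and minimum of a scalar trace within a time window.

    Returns ``(max, min)`` extrema; ties go to the earliest index.
    """
    trace = np.asarray(trace, dtype=float)
    i0, i1 = _window_indices(trace.shape[0], fs, t0, start, duration)
    seg = trace[i0:i1]
    imax = i0 + int(np.argmax(seg))
    imin = i0 + int(np.argmin(seg))
    mk = Extremum(index=imax, time=t0 + imax / fs, value=float(trace[imax]), kind="max")
    mn = Extremum(index=imin, time=t0 + imin / fs, value=float(trace[imin]), kind="min")
    return mk, mn


def step_features(
    oriented: OrientedSeries, start: float, duration: float
) -> StepFeatures:
    """Step features of a window: vertical range and longitudinal time lag."""
    vmax, vmin = window_extrema(
        oriented.vertical, oriented.fs, oriented.t0, start, duration
    )
    lmax, lmin = window_extrema(
        oriented.longitudinal, oriented.fs, oriented.t0, start, duration
    )
    return StepFeatures(
        f1=vmax.value - vmin.value,
        f2=lmax.time - lmin.time,
        window_start=start,
    )


def fall_features(
    oriented: OrientedSeries, start: float, duration: float
) -> FallFeatures:
    """Fall features of a window: |G| range (g) and min-to-max lag (ms)."""
    gmax, gmin = window_extrema(
        oriented.magnitude, oriented.fs, oriented.t0, start, duration
    )
    return FallFeatures(
        f1=gmax.value - gmin.value,
        f2=abs(gmax.time - gmin.time) * 1000.0,
        window_start=start,
    )


def fall_class_features(
    series: AccelSeries,
    oriented: OrientedSeries,
    start: float,
    duration: float,
) -> FallClassFeatures:
    """Raw axis triple at the sample where |G| peaks inside the window."""
    gmax, _ = window_extrema(
        oriented.magnitude, oriented.fs, oriented.t0, start, duration
    )
    ax, ay, az = series.data[gmax.index]
    return FallClassFeatures(f1=float(ax), f2=float(ay), f3=float(az))
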
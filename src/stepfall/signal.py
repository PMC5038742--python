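"""Accelerometer stream representation and orientation handling.

An :class:`AccelSeries` is a uniformly sampled tri-axial acceleration
stream in g units.  The processing chain estimates the quasi-static
gravity vector with a centred moving average, projects each sample
against it to obtain the dynamic vertical component, extracts a
longitudinal (movement-direction) component from the gravity-orthogonal
residual, and can rescale axis amplitudes between torso sensor
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import LOCATION_STD

__all__ = [
    "AccelSeries",
    "GravitySeries",
    "OrientedSeries",
    "LocationCalibration",
    "moving_average",
    "estimate_gravity",
    "project_components",
    "compensate_location",
    "default_calibration",
]

_LOCATIONS = ("lower_torso", "upper_torso")


@dataclass(frozen=True)
class AccelSeries:
    """Uniformly sampled tri-axial acceleration, in g.

    Parameters
    ----------
    data:
        Array of shape ``(n, 3)`` holding ``(ax, ay, az)`` triples.
    fs:
        Sampling rate in Hz; must be positive.
    t0:
        Time of the first sample, seconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError(f"expected (n, 3) samples, got shape {data.shape}")
        if data.shape[0] < 1:
            raise ValueError("series must contain at least one sample")
        if not np.isfinite(data).all():
            raise ValueError("series contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "data", data)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


@dataclass(frozen=True)
class GravitySeries:
    """Per-sample gravity estimate (g), from a centred moving average."""

    data: np.ndarray
    fs: float
    t0: float = 0.0
    window_s: float = 2.0

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class OrientedSeries:
    """Gravity-aligned dynamic components of an acceleration stream.

    ``vertical`` is the component along gravity with the static 1 g
    magnitude removed; ``longitudinal`` is the projection of the
    gravity-orthogonal residual on the dominant horizontal direction;
    ``magnitude`` is the raw vector norm |G|.
    """

    vertical: np.ndarray
    longitudinal: np.ndarray
    magnitude: np.ndarray
    fs: float
    t0: float = 0.0

    def __len__(self) -> int:
        return self.vertical.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (len(self) - 1) / self.fs


@dataclass(frozen=True)
class LocationCalibration:
    """Per-axis acceleration standard deviations (g) by sensor location."""

    stds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(LOCATION_STD)
    )

    def __post_init__(self) -> None:
        for loc, triple in self.stds.items():
            if len(triple) != 3:
                raise ValueError(f"calibration for {loc!r} must have 3 axes")
            if any(not (s > 0) for s in triple):
                raise ValueError(f"calibration stds for {loc!r} must be > 0")

    def ratios(self, from_loc: str, to_loc: str) -> np.ndarray:
        for loc in (from_loc, to_loc):
            if loc not in self.stds:
                raise KeyError(f"no calibration entry for location {loc!r}")
        src = np.asarray(self.stds[from_loc], dtype=float)
        dst = np.asarray(self.stds[to_loc], dtype=float)
        return dst / src


def default_calibration() -> LocationCalibration:
    return LocationCalibration()


def moving_average(data: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centred moving average over ``±window_s/2``, truncated at edges.

    Works on 1-D traces or (n, k) arrays (averaged along axis 0).
    """
    if not window_s > 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    n = data.shape[0]
    # samples within +-window_s/2: half-width in whole sample counts
    half = int(np.floor(window_s / 2 * fs + 1e-9))
    csum = np.cumsum(np.vstack([np.zeros((1, data.shape[1])), data]), axis=0)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    out = (csum[hi] - csum[lo]) / (hi - lo).astype(float)[:, None]
    return out[:, 0] if squeeze else out


def estimate_gravity(series: AccelSeries, window_s: float = 2.0) -> GravitySeries:
    """Estimate per-sample gravity by a centred moving average.

    Each output sample is the mean of all input samples within
    ``±window_s / 2`` of its time; the window is truncated at the series
    edges so every output is an average of at least one sample.
    """
    if len(series) < 1:
        raise ValueError("series must be non-empty")
    return GravitySeries(
        data=moving_average(series.data, series.fs, window_s),
        fs=series.fs,
        t0=series.t0,
        window_s=window_s,
    )


def project_components(series: AccelSeries, gravity: GravitySeries) -> OrientedSeries:
    """Split samples into vertical / longitudinal dynamic components.

    vertical[k] is the dot product of sample k with the unit gravity
    estimate minus the gravity magnitude (so a motionless stream reads
    zero).  The gravity-orthogonal residual is projected on its first
    principal axis over the whole series to obtain the longitudinal
    trace; the axis sign is chosen so the mean cubed longitudinal value
    is non-negative.
    """
    if len(series) != len(gravity):
        raise ValueError(
            f"series ({len(series)}) and gravity ({len(gravity)}) lengths differ"
        )
    g = np.asarray(gravity.data, dtype=float)
    gnorm = np.linalg.norm(g, axis=1)
    if np.any(gnorm < 1e-12):
        k = int(np.argmax(gnorm < 1e-12))
        raise ValueError(
            f"degenerate orientation: gravity estimate at sample {k} has zero norm"
        )
    unit = g / gnorm[:, None]
    proj = np.einsum("ij,ij->i", series.data, unit)
    vertical = proj - gnorm
    residual = series.data - proj[:, None] * unit

    # dominant horizontal direction: first right-singular vector of the
    # residual cloud (uncentred; residuals are near zero-mean dynamics)
    _, svals, vt = np.linalg.svd(residual, full_matrices=False)
    axis = vt[0]
    longitudinal = residual @ axis
    if np.mean(longitudinal**3) < 0:
        longitudinal = -longitudinal

    magnitude = np.linalg.norm(series.data, axis=1)
    return OrientedSeries(
        vertical=vertical,
        longitudinal=longitudinal,
        magnitude=magnitude,
        fs=series.fs,
        t0=series.t0,
    )


def orient(series: AccelSeries, window_s: float = 2.0) -> OrientedSeries:
    """Convenience: gravity estimation followed by projection."""
    return project_components(series, estimate_gravity(series, window_s))


def compensate_location(
    series: AccelSeries,
    cal: LocationCalibration,
    from_loc: str,
    to_loc: str,
) -> AccelSeries:
    """Rescale per-axis amplitudes from one torso location to another.

    Each axis is scaled about its own series mean by the ratio of the
    calibration standard deviations at the two locations.
    """
    if from_loc == to_loc:
        return AccelSeries(data=series.data.copy(), fs=series.fs, t0=series.t0)
    ratios = cal.ratios(from_loc, to_loc)
    means = series.data.mean(axis=0)
    scaled = means + (series.data - means) * ratios
    return AccelSeries(data=scaled, fs=series.fs, t0=series.t0)
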
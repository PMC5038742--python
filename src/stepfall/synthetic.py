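"""Seeded generators of labelled accelerometer traces.

Walks, falls and null activities are built so that the features
extracted by the detection pipeline follow the shipped model
distributions: per-step (f1, f2) targets are drawn from the per-cadence
Gaussians, fall profiles realise (f1, f2) draws from the fall model and
impact-axis triples from the per-class Gaussians.  Waveforms are
raised-cosine pulses (steps) and a dip-then-spike magnitude profile
(falls); every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import params
from .signal import AccelSeries, LocationCalibration, compensate_location

__all__ = [
    "WalkSpec",
    "FallSpec",
    "WalkTruth",
    "FallTruth",
    "synth_walk",
    "synth_fall",
    "synth_null",
    "draw_features",
    "interp_cadence_params",
]

_MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class WalkSpec:
    cadence: float = 80.0  # steps/min
    n_steps: int = 20
    fs: float = 50.0
    noise_sd: float = 0.005  # g
    location: str = "lower_torso"
    seed: int = 0
    lead_in: float = 1.5  # quiet context before the first step (s)
    lead_out: float = 1.5

    def __post_init__(self) -> None:
        if not self.cadence > 0:
            raise ValueError("cadence must be positive")
        if self.n_steps < 1:
            raise ValueError("need at least one step")
        if self.fs < 20:
            raise ValueError("sampling rate must be at least 20 Hz")


@dataclass(frozen=True)
class FallSpec:
    class_label: str = "c1"
    fs: float = 50.0
    pre: float = 2.0  # context before the fall (s)
    post: float = 2.0
    seed: int = 0
    context: str = "quiet"  # "quiet" | "walking"
    impact_scale: float = 1.0  # scales the impact amplitude (1 = calibrated)

    def __post_init__(self) -> None:
        if self.class_label not in params.FALL_CLASS_LABELS:
            raise ValueError(f"unknown fall class {self.class_label!r}")
        if self.context not in ("quiet", "walking"):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class WalkTruth:
    """Ground truth for a synthetic walk: step times and drawn targets."""

    step_times: np.ndarray  # vertical-peak time of each step (s)
    f1_targets: np.ndarray  # drawn vertical amplitude per step (g)
    f2_targets: np.ndarray  # drawn longitudinal time lag per step (s)
    cadence: float = 80.0


@dataclass(frozen=True)
class FallTruth:
    time: float  # |G| impact-peak time (s)
    class_label: str
    f1: float  # realised |G| range (g)
    f2: float  # realised min-to-max lag (ms)
    impact_triple: tuple[float, float, float]  # raw axes at the peak (g)


def interp_cadence_params(cadence: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """(lam, sigma) for f1 and f2 at a cadence, linear between trained points."""
    grid = sorted(params.STEP_F1)
    c = float(np.clip(cadence, grid[0], grid[-1]))

    def interp(table: dict[int, tuple[float, float]]) -> tuple[float, float]:
        lo = max(g for g in grid if g <= c)
        hi = min(g for g in grid if g >= c)
        if lo == hi:
            return table[lo]
        w = (c - lo) / (hi - lo)
        return (
            table[lo][0] * (1 - w) + table[hi][0] * w,
            table[lo][1] * (1 - w) + table[hi][1] * w,
        )

    return interp(params.STEP_F1), interp(params.STEP_F2)


def draw_features(lam: float, sigma: float, n: int, seed: int) -> np.ndarray:
    """n seeded iid Gaussian feature draws."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(lam, sigma, size=n)


def _lobe(t: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    """Raised-cosine lobe: peak ``height`` at ``center``, support ``width``."""
    s = (t - center) / width
    out = np.zeros_like(t)
    mask = np.abs(s) < 0.5
    out[mask] = height * 0.5 * (1.0 + np.cos(2 * np.pi * s[mask]))
    return out


def _draw_step_targets(
    rng: np.random.Generator, cadence: float, fs: float, interval: float
) -> tuple[float, float]:
    """One feasible (f1*, f2*) pair for a step; resamples infeasible draws."""
    (l1, s1), (l2, s2) = interp_cadence_params(cadence)
    for _ in range(_MAX_ATTEMPTS):
        f1 = rng.normal(l1, s1)
        f2 = rng.normal(l2, s2)
        if f1 < 0.10:  # below the noise floor the step is unobservable
            continue
        if not (2.0 / fs <= abs(f2) <= 0.35 * interval):
            continue
        return float(f1), float(f2)
    raise RuntimeError(
        f"could not draw feasible step features at cadence {cadence} after "
        f"{_MAX_ATTEMPTS} attempts"
    )


def synth_walk(spec: WalkSpec) -> tuple[AccelSeries, WalkTruth]:
    """Generate a walking trace with per-step feature targets.

    The vertical trace carries, per step, a positive raised-cosine lobe
    at the step time and an equal negative lobe 0.3 step-intervals
    later (max - min equals the drawn f1).  The longitudinal trace is a
    sine pulse whose minimum and maximum are separated by the drawn f2,
    with the positive half amplified for positive skewness.  Gravity sits
    on the z axis; the longitudinal pulse rides on y.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    interval = 60.0 / spec.cadence

    # jittered, grid-snapped step times
    gaps = interval * (1.0 + rng.uniform(-0.03, 0.03, size=spec.n_steps))
    raw_times = spec.lead_in + np.cumsum(gaps) - gaps[0]
    step_times = np.round(raw_times * fs) / fs

    duration = spec.lead_in + spec.n_steps * interval + spec.lead_out
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    f1s = np.empty(spec.n_steps)
    f2s = np.empty(spec.n_steps)
    for k in range(spec.n_steps):
        f1s[k], f2s[k] = _draw_step_targets(rng, spec.cadence, fs, interval)

    longitudinal = np.zeros(n)
    for ts, f1, f2 in zip(step_times, f1s, f2s):
        # longitudinal: min lobe at ts - h, max lobe at ts + h (h = f2/2,
        # snapped to the grid); the taller-but-narrower positive lobe has
        # the same area as the negative one, so the pulse is zero-mean
        # (gravity estimate unbiased) with positive skewness (fixes the
        # principal-axis sign)
        h = np.sign(f2) * max(1, round(abs(f2) * fs / 2.0)) / fs
        amp = max(0.1, 0.4 * f1)
        longitudinal += _lobe(t, ts + h, 0.72 * abs(2 * h), 1.25 * amp)
        longitudinal -= _lobe(t, ts - h, 0.90 * abs(2 * h), amp)

    lobe_w = max(0.12 * interval, 3.0 / fs)

    def build_vertical(amps: np.ndarray) -> np.ndarray:
        v = np.zeros(n)
        for ts, a in zip(step_times, amps):
            neg_center = np.round((ts + 0.3 * interval) * fs) / fs
            v += _lobe(t, ts, lobe_w, a / 2.0)
            v -= _lobe(t, neg_center, lobe_w, a / 2.0)
        return v

    # closed-loop amplitude calibration: the gravity moving average
    # absorbs ~1 % of each pulse, so iterate until the features the
    # pipeline extracts equal the drawn targets
    from .features import step_features  # local import avoids a cycle
    from .signal import estimate_gravity, project_components

    amps = f1s.copy()
    for _ in range(3):
        data = np.zeros((n, 3))
        data[:, 1] = longitudinal
        data[:, 2] = 1.0 + build_vertical(amps)
        clean = AccelSeries(data=data, fs=fs, t0=0.0)
        oriented = project_components(clean, estimate_gravity(clean))
        measured = np.array(
            [
                step_features(
                    oriented, ts - 0.375 * interval, 0.875 * interval
                ).f1
                for ts in step_times
            ]
        )
        amps = np.maximum(amps + (f1s - measured), 0.02)

    data = np.zeros((n, 3))
    data[:, 1] = longitudinal
    data[:, 2] = 1.0 + build_vertical(amps)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    series = AccelSeries(data=data, fs=fs, t0=0.0)
    if spec.location != "lower_torso":
        series = compensate_location(
            series, LocationCalibration(), "lower_torso", spec.location
        )
    truth = WalkTruth(
        step_times=step_times, f1_targets=f1s, f2_targets=f2s, cadence=spec.cadence
    )
    return series, truth


def _truncated_normal(
    rng: np.random.Generator, lam: float, sigma: float, k_sigma: float
) -> float:
    """Gaussian draw rejected outside ``lam +- k_sigma * sigma``."""
    for _ in range(_MAX_ATTEMPTS):
        x = rng.normal(lam, sigma)
        if abs(x - lam) <= k_sigma * sigma:
            return float(x)
    return lam


def _cos_ramp(n: int, a: float, b: float) -> np.ndarray:
    """Monotone raised-cosine ramp over n+1 samples from a to b."""
    s = np.arange(n + 1) / n
    return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * s))


def synth_fall(spec: FallSpec) -> tuple[AccelSeries, FallTruth]:
    """Generate a fall trace: free-fall dip then impact spike.

    The |G| profile descends from 1 g to a dip minimum, rises to the
    impact peak over the drawn min-to-max lag, and decays back to rest.
    The impact-axis triple is drawn from the requested class Gaussians
    (truncated at +-0.5 sigma) and sets the peak magnitude, so the raw
    sample at the peak equals the drawn triple exactly.  The |G| range
    is the Table-calibrated draw (truncated +-1 sigma) where the dip
    floor permits.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs

    # class triple at +-0.5 sigma -> impact peak magnitude
    trio = np.array(
        [
            _truncated_normal(rng, lam, sig, 0.5)
            for lam, sig in (
                params.FALL_CLASS[spec.class_label][k] for k in ("f1", "f2", "f3")
            )
        ]
    )
    trio *= spec.impact_scale
    g_max = float(np.linalg.norm(trio))
    u_impact = trio / g_max

    f1_draw = _truncated_normal(rng, *params.FALL_F1, 1.0) * spec.impact_scale
    # the dip must descend below the 1 g rest baseline to read as free fall
    g_min = min(0.9, max(0.05, g_max - f1_draw))
    f2_draw = _truncated_normal(rng, *params.FALL_F2, 1.0)  # ms
    n_rise = max(2, round(f2_draw * fs / 1000.0))
    f2_real = n_rise / fs * 1000.0

    n_desc = max(2, int(round(0.25 * fs)))
    n_decay = max(2, int(round(0.35 * fs)))

    # magnitude profile of the fall core (1 s of quiet on each side);
    # g_min lands exactly at i_min and g_max at i_max
    n_quiet = int(round(1.0 * fs))
    mag = np.concatenate(
        [
            np.ones(n_quiet),
            _cos_ramp(n_desc, 1.0, g_min),
            _cos_ramp(n_rise, g_min, g_max)[1:],
            _cos_ramp(n_decay, g_max, 1.0)[1:],
            np.ones(n_quiet),
        ]
    )
    i_min = n_quiet + n_desc
    i_max = i_min + n_rise

    # direction: vertical at rest, rotating into the impact direction
    up = np.array([0.0, 0.0, 1.0])
    core = np.empty((mag.shape[0], 3))
    core[:] = up
    for j in range(1, n_rise + 1):  # blend during the rise
        w = j / n_rise
        v = (1 - w) * up + w * u_impact
        core[i_min + j] = v / np.linalg.norm(v)
    for j in range(1, n_decay):  # blend back during the decay
        w = j / n_decay
        v = (1 - w) * u_impact + w * up
        core[i_max + j] = v / np.linalg.norm(v)
    core *= mag[:, None]

    # context around the core
    if spec.context == "walking":
        pre_steps = max(1, int(math.ceil(spec.pre / 0.75)))
        post_steps = max(1, int(math.ceil(spec.post / 0.75)))
        pre_s, _ = synth_walk(
            WalkSpec(cadence=80, n_steps=pre_steps, fs=fs, seed=spec.seed + 1,
                     lead_in=0.5, lead_out=0.5)
        )
        post_s, _ = synth_walk(
            WalkSpec(cadence=80, n_steps=post_steps, fs=fs, seed=spec.seed + 2,
                     lead_in=0.5, lead_out=0.5)
        )
        pre_data, post_data = pre_s.data, post_s.data
    else:
        pre_n = int(round(spec.pre * fs))
        post_n = int(round(spec.post * fs))
        pre_data = np.tile(up, (pre_n, 1))
        post_data = np.tile(up, (post_n, 1))

    data = np.vstack([pre_data, core, post_data])
    series = AccelSeries(data=data, fs=fs, t0=0.0)
    t_peak = (pre_data.shape[0] + i_max) / fs
    truth = FallTruth(
        time=t_peak,
        class_label=spec.class_label,
        f1=g_max - g_min,
        f2=f2_real,
        impact_triple=tuple(trio),
    )
    return series, truth


def synth_null(
    archetype: str, duration: float, fs: float = 50.0, seed: int = 0
) -> AccelSeries:
    """Quiet non-walking activity: gravity baseline plus noise.

    sitting/standing use low-amplitude AR(1)-coloured noise (std at most
    0.02 g); "noise" is broadband white noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    levels = {"sitting": 0.005, "standing": 0.01, "noise": 0.05}
    if archetype not in levels:
        raise ValueError(f"unknown archetype {archetype!r}")
    sd = levels[archetype]

    if archetype == "noise":
        noise = rng.normal(0.0, sd, size=(n, 3))
    else:
        a = 0.9  # AR(1) coefficient; innovations scaled to stationary sd
        eps = rng.normal(0.0, sd * math.sqrt(1 - a * a), size=(n, 3))
        noise = np.empty((n, 3))
        noise[0] = eps[0]
        for k in range(1, n):
            noise[k] = a * noise[k - 1] + eps[k]

    data = noise + np.array([0.0, 0.0, 1.0])
    return AccelSeries(data=data, fs=fs, t0=0.0)
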
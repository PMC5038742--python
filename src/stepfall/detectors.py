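"""Detection of steps and falls over full recordings.

Steps: every local maximum of the vertical acceleration (spaced by the
refractory period) is a candidate anchor.  Each candidate is scored
with the cadence posterior, extracting features from a window centred
on the anchor: the null class reads a ``delta_max`` window while each
cadence class reads a window matching its movement duration
(60/cadence seconds), mirroring the per-speed execution duration the
window length is derived from.  Candidates whose step probability
exceeds ``theta`` become events, anchored at the vertical maximum
(heel-strike proxy); any anchors closer than the refractory period are
merged keeping the most probable.  A periodic post-correction pass
inserts single missed steps into gaps close to twice the local
inter-step interval.

Falls: windows of ``fall_window`` seconds are scored with the fall
kernel product; supra-threshold windows are merged by the fall
refractory and each event is classified from the raw axis triple at its
|G| peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .features import fall_class_features, fall_features, step_features
from .model import (
    FallClassModel,
    FallModel,
    SpeedModelSet,
    classify_fall,
    fall_likelihood,
    posterior_from_loglik,
    step_probability,
)
from .signal import AccelSeries, OrientedSeries

__all__ = [
    "DetectionEvent",
    "DetectorConfig",
    "detect_steps",
    "correct_periodic",
    "detect_falls",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionEvent:
    kind: str  # "step" | "fall"
    time: float  # s
    score: float  # step probability or fall kernel score
    label: str | None = None  # fall class (falls) or cadence label (steps)
    extra: dict = field(default_factory=dict)
    inserted: bool = False


@dataclass(frozen=True)
class DetectorConfig:
    delta_max: float = 1.2  # step window length (s)
    hop: float = 0.1  # window stride (s)
    theta: float = 0.5  # step decision threshold
    refractory: float = 0.3  # min inter-step gap (s)
    fall_window: float = 2.5  # fall window length (s)
    fall_refractory: float = 2.0  # min inter-fall gap (s)

    def __post_init__(self) -> None:
        if self.hop > self.delta_max:
            raise ValueError("hop must not exceed delta_max")
        if not self.refractory > 0:
            raise ValueError("refractory must be positive")


def _window_starts(t0: float, t_end: float, length: float, hop: float) -> np.ndarray:
    n = int(np.floor((t_end - t0 - length) / hop + 1e-9)) + 1
    if n < 1:
        return np.empty(0)
    return t0 + hop * np.arange(n)


def _merge_candidates(
    candidates: list[DetectionEvent], refractory: float
) -> list[DetectionEvent]:
    """Cluster candidates whose anchor times fall within the refractory
    period of each other; keep the highest-scoring member per cluster."""
    if not candidates:
        return []
    candidates = sorted(candidates, key=lambda e: e.time)
    merged: list[DetectionEvent] = []
    cluster = [candidates[0]]
    for ev in candidates[1:]:
        if ev.time - cluster[-1].time < refractory:
            cluster.append(ev)
        else:
            merged.append(max(cluster, key=lambda e: e.score))
            cluster = [ev]
    merged.append(max(cluster, key=lambda e: e.score))
    return merged


def _centred_features(
    oriented: OrientedSeries, anchor: float, duration: float
):
    """Step features of a window centred at the anchor, shifted to stay
    inside the recording extent."""
    start = anchor - duration / 2.0
    start = min(max(start, oriented.t0), oriented.t_end - duration)
    return step_features(oriented, start, duration)


def detect_steps(
    oriented: OrientedSeries,
    m: SpeedModelSet,
    cfg: DetectorConfig | None = None,
) -> list[DetectionEvent]:
    """Detect step events over a full oriented recording."""
    cfg = cfg or DetectorConfig()
    if oriented.t_end - oriented.t0 < cfg.delta_max:
        warnings.warn("recording shorter than the analysis window; no events")
        return []

    # candidate anchors: vertical local maxima spaced by the refractory
    dist = max(1, int(np.ceil(cfg.refractory * oriented.fs)))
    peaks, _ = find_peaks(oriented.vertical, distance=dist)

    cadences = m.cadences
    shortest = 60.0 / max(cadences)
    candidates: list[DetectionEvent] = []
    for k in peaks:
        anchor = oriented.t0 + k / oriented.fs
        loglik = np.empty(len(m.speeds) + 1)
        fnull = _centred_features(oriented, anchor, cfg.delta_max)
        # the null class competes on every window it could explain
        null_ll = m.null.f1.logpdf(fnull.f1) + m.null.f2.logpdf(fnull.f2)
        f_short = None
        for i, sg in enumerate(m.speeds, start=1):
            f = _centred_features(oriented, anchor, 60.0 / sg.mu_label)
            loglik[i] = sg.f1.logpdf(f.f1) + sg.f2.logpdf(f.f2)
            null_ll = max(null_ll, m.null.f1.logpdf(f.f1) + m.null.f2.logpdf(f.f2))
            if 60.0 / sg.mu_label == shortest:
                f_short = f
        loglik[0] = null_ll
        # peak consistency: a heel-strike anchor sits near the top of its
        # window's range; rebound/noise maxima between steps do not
        if f_short is not None and oriented.vertical[k] < 0.3 * f_short.f1:
            continue
        post = posterior_from_loglik(loglik, m.prior)
        p = step_probability(post)
        log.debug("anchor %.2f s: f1=%.4f p(step)=%.4f", anchor, fnull.f1, p)
        if p > cfg.theta:
            label = str(cadences[int(np.argmax(post[1:]))])
            candidates.append(
                DetectionEvent(
                    kind="step",
                    time=anchor,
                    score=p,
                    label=label,
                    extra={"posterior": post},
                )
            )
    return _merge_candidates(candidates, cfg.refractory)


def correct_periodic(
    events: list[DetectionEvent], tolerance: float = 0.2
) -> list[DetectionEvent]:
    """Insert single missed steps into near-double inter-event gaps.

    Events are split into runs at gaps larger than 3x the median
    interval; within a run, a gap within ``+-tolerance`` of twice the
    median of the other intervals receives one inserted event at its
    midpoint.  Original events are never altered or removed.
    """
    if len(events) < 3:
        return list(events)
    events = sorted(events, key=lambda e: e.time)
    times = np.array([e.time for e in events])
    gaps = np.diff(times)
    med_all = float(np.median(gaps))

    # split into runs of near-contiguous events
    breaks = np.nonzero(gaps > 3.0 * med_all)[0]
    run_bounds = np.concatenate([[0], breaks + 1, [len(events)]])

    out = list(events)
    for r0, r1 in zip(run_bounds[:-1], run_bounds[1:]):
        run_gaps = gaps[r0 : r1 - 1]
        if run_gaps.size < 2:
            continue
        for j, gap in enumerate(run_gaps):
            others = np.delete(run_gaps, j)
            med = float(np.median(others))
            if abs(gap - 2.0 * med) <= tolerance * 2.0 * med:
                mid = times[r0 + j] + gap / 2.0
                ref = out[0]
                out.append(
                    DetectionEvent(
                        kind=ref.kind,
                        time=mid,
                        score=0.0,
                        label=None,
                        inserted=True,
                    )
                )
    return sorted(out, key=lambda e: e.time)


def detect_falls(
    series: AccelSeries,
    oriented: OrientedSeries,
    fm: FallModel,
    fcm: FallClassModel,
    cfg: DetectorConfig | None = None,
) -> list[DetectionEvent]:
    """Detect and classify fall events over a full recording."""
    cfg = cfg or DetectorConfig()
    starts = _window_starts(oriented.t0, oriented.t_end, cfg.fall_window, cfg.hop)
    if starts.size == 0:
        warnings.warn("recording shorter than the fall window; no events")
        return []

    candidates: list[DetectionEvent] = []
    for start in starts:
        f = fall_features(oriented, start, cfg.fall_window)
        score, is_fall = fall_likelihood(f, fm)
        if is_fall:
            i0 = int(np.ceil((start - oriented.t0) * oriented.fs - 1e-9))
            i1 = int(
                np.floor((start + cfg.fall_window - oriented.t0) * oriented.fs + 1e-9)
            ) + 1
            k = i0 + int(np.argmax(oriented.magnitude[i0:i1]))
            anchor = oriented.t0 + k / oriented.fs
            candidates.append(
                DetectionEvent(kind="fall", time=anchor, score=score)
            )

    merged = _merge_candidates(candidates, cfg.fall_refractory)

    # classify each event from the axis triple at its |G| peak
    out: list[DetectionEvent] = []
    for ev in merged:
        half = cfg.fall_window / 2.0
        start = max(oriented.t0, ev.time - half)
        start = min(start, oriented.t_end - cfg.fall_window)
        fcf = fall_class_features(series, oriented, start, cfg.fall_window)
        label, scores = classify_fall(fcf, fcm)
        out.append(replace(ev, label=label, extra={"class_scores": scores}))
    return out
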
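"""CSV time-series / event I/O and JSON model serialization.

Time series use the header ``t,ax,ay,az`` (seconds / g); events use
``kind,time_s,score,label,inserted``; ground truth uses
``kind,time_s,label``.  Models are stored as a single versioned JSON
document holding the cadence Gaussians, the null model, the prior, the
fall and fall-class parameters and the location calibration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detectors import DetectionEvent
from .model import (
    FallClassModel,
    FallModel,
    GaussianParams,
    NullFeature,
    NullModel,
    SpeedGaussian,
    SpeedModelSet,
)
from .params import STANDARD_GRAVITY
from .signal import AccelSeries, LocationCalibration

__all__ = [
    "read_series",
    "write_series",
    "read_events",
    "write_events",
    "read_truth",
    "write_truth",
    "save_model",
    "load_model",
    "ModelBundle",
    "SCHEMA",
]

SCHEMA = "stepfall-model/1"
SERIES_COLUMNS = ["t", "ax", "ay", "az"]


class ParseError(ValueError):
    pass


def read_series(
    path: str | Path,
    units: str = "g",
    fs_override: float | None = None,
) -> AccelSeries:
    """Read a ``t,ax,ay,az`` CSV into a validated uniform series.

    Non-uniform timestamps are linearly resampled onto a uniform grid at
    ``fs_override`` (or the median rate).  ``units="m/s^2"`` converts to
    g on read.
    """
    path = Path(path)
    if units not in ("g", "m/s^2", "m/s2"):
        raise ValueError(f"units must be 'g' or 'm/s^2', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; header must be t,ax,ay,az")

    for col in SERIES_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric or missing {col} at line {bad[0] + 2}")

    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            raise ParseError(
                f"{path}: time column not strictly increasing at line {k + 3}"
            )
    data = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if units != "g":
        data = data / STANDARD_GRAVITY

    if len(t) == 1:
        return AccelSeries(data=data, fs=fs_override or 1.0, t0=float(t[0]))

    dt = np.diff(t)
    fs_est = 1.0 / float(np.median(dt))
    fs = fs_override or fs_est
    uniform = np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) and (
        fs_override is None or np.isclose(fs, fs_est, rtol=1e-6)
    )
    if uniform:
        return AccelSeries(data=data, fs=fs, t0=float(t[0]))

    grid = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    grid = grid[grid <= t[-1] + 1e-12]
    resampled = np.column_stack(
        [np.interp(grid, t, data[:, j]) for j in range(3)]
    )
    return AccelSeries(data=resampled, fs=fs, t0=float(grid[0]))


def write_series(series: AccelSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t": series.times,
            "ax": series.data[:, 0],
            "ay": series.data[:, 1],
            "az": series.data[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_events(events: list[DetectionEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "time_s": [e.time for e in events],
            "score": [e.score for e in events],
            "label": [e.label if e.label is not None else "" for e in events],
            "inserted": [int(e.inserted) for e in events],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_events(path: str | Path) -> list[DetectionEvent]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        label = str(row.label) if str(row.label) else None
        out.append(
            DetectionEvent(
                kind=row.kind,
                time=float(row.time_s),
                score=float(row.score),
                label=label,
                inserted=bool(int(row.inserted)),
            )
        )
    return out


def write_truth(rows: list[tuple[str, float, str]], path: str | Path) -> None:
    """Ground-truth sidecar: rows of (kind, time_s, label)."""
    df = pd.DataFrame(rows, columns=["kind", "time_s", "label"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_truth(path: str | Path) -> list[tuple[str, float, str]]:
    df = pd.read_csv(path, keep_default_na=False)
    return [(str(r.kind), float(r.time_s), str(r.label)) for r in df.itertuples(index=False)]


class ModelBundle:
    """All trained parameters in one deployable artifact."""

    def __init__(
        self,
        steps: SpeedModelSet,
        fall: FallModel,
        fall_classes: FallClassModel,
        calibration: LocationCalibration | None = None,
    ) -> None:
        self.steps = steps
        self.fall = fall
        self.fall_classes = fall_classes
        self.calibration = calibration or LocationCalibration()


def _gauss_to_json(g: GaussianParams) -> list[float]:
    return [g.lam, g.sigma]


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    m = bundle.steps
    doc = {
        "schema": SCHEMA,
        "units": {
            "step_f1": "g",
            "step_f2": "s",
            "fall_f1": "g",
            "fall_f2": "ms",
            "fall_class": "g",
        },
        "delta_max_s": m.delta_max,
        "speeds": [
            {
                "cadence_spm": s.mu_label,
                "f1": _gauss_to_json(s.f1),
                "f2": _gauss_to_json(s.f2),
            }
            for s in m.speeds
        ],
        "prior": list(map(float, m.prior)),
        "null": {
            name: {
                "lam01": nf.lam01,
                "mu01": nf.mu01,
                "lam02": nf.lam02,
                "mu02": nf.mu02,
            }
            for name, nf in (("f1", m.null.f1), ("f2", m.null.f2))
        },
        "fall": {
            "f1": _gauss_to_json(bundle.fall.f1),
            "f2": _gauss_to_json(bundle.fall.f2),
            "tau2": bundle.fall.tau2,
        },
        "fall_classes": {
            label: [_gauss_to_json(g) for g in trio]
            for label, trio in bundle.fall_classes.classes.items()
        },
        "fall_class_thresholds": bundle.fall_classes.thresholds,
        "calibration": {
            loc: list(map(float, stds))
            for loc, stds in bundle.calibration.stds.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> ModelBundle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    doc = json.loads(path.read_text())
    schema = doc.get("schema")
    if schema != SCHEMA:
        raise ValueError(f"unsupported model schema: expected {SCHEMA!r}, found {schema!r}")

    speeds = tuple(
        SpeedGaussian(
            mu_label=float(s["cadence_spm"]),
            f1=GaussianParams(*s["f1"]),
            f2=GaussianParams(*s["f2"]),
        )
        for s in doc["speeds"]
    )
    null = NullModel(
        f1=NullFeature(**doc["null"]["f1"]),
        f2=NullFeature(**doc["null"]["f2"]),
    )
    steps = SpeedModelSet(
        speeds=speeds,
        null=null,
        prior=np.asarray(doc["prior"], dtype=float),
        delta_max=float(doc["delta_max_s"]),
    )
    fall = FallModel(
        f1=GaussianParams(*doc["fall"]["f1"]),
        f2=GaussianParams(*doc["fall"]["f2"]),
        tau2=float(doc["fall"]["tau2"]),
    )
    fall_classes = FallClassModel(
        classes={
            label: tuple(GaussianParams(*g) for g in trio)
            for label, trio in doc["fall_classes"].items()
        },
        thresholds=doc.get("fall_class_thresholds"),
    )
    calibration = LocationCalibration(
        stds={loc: tuple(v) for loc, v in doc["calibration"].items()}
    )
    return ModelBundle(steps, fall, fall_classes, calibration)
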
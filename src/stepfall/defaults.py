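"""Assembly of the shipped default model set.

The cadence Gaussians, fall model and fall-class model come straight
from the calibration constants; the null-class model is fitted, once and
deterministically, on step features extracted from synthetic non-walking
traces (sitting / standing / broadband-noise archetypes).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .features import step_features
from .model import (
    FallClassModel,
    FallModel,
    NullModel,
    SpeedModelSet,
    default_speed_gaussians,
    fit_null,
)
from .params import DEFAULT_DELTA_MAX
from .signal import orient
from .synthetic import synth_null

__all__ = ["default_model_set", "default_fall_model", "default_fall_class_model"]

_NULL_FIT_SEED = 20160901


def _null_feature_samples(fs: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Step features from sliding windows over synthetic null activities."""
    f1s: list[float] = []
    f2s: list[float] = []
    for i, archetype in enumerate(("sitting", "standing")):
        series = synth_null(archetype, duration=60.0, fs=fs, seed=_NULL_FIT_SEED + i)
        oriented = orient(series)
        start = oriented.t0
        while start + DEFAULT_DELTA_MAX <= oriented.t_end:
            f = step_features(oriented, start, DEFAULT_DELTA_MAX)
            f1s.append(f.f1)
            f2s.append(f.f2)
            start += 0.3
    return np.asarray(f1s), np.asarray(f2s)


@lru_cache(maxsize=1)
def default_model_set() -> SpeedModelSet:
    """Shipped cadence model: table Gaussians, fitted null model, and a
    null-weighted prior (0.4 null, 0.2 per cadence) so decisions at the
    noise floor favour the null class."""
    f1s, f2s = _null_feature_samples()
    null = NullModel(f1=fit_null(f1s), f2=fit_null(f2s))
    speeds = default_speed_gaussians()
    prior = np.concatenate([[0.4], np.full(len(speeds), 0.6 / len(speeds))])
    return SpeedModelSet(speeds=speeds, null=null, prior=prior,
                         delta_max=DEFAULT_DELTA_MAX)


def default_fall_model() -> FallModel:
    return FallModel()


def default_fall_class_model() -> FallClassModel:
    return FallClassModel()
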
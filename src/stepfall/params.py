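"""Default trained model parameters.

These constants are the shipped calibration of the detector: per-cadence
Gaussian parameters for the two step features, Gaussian parameters for the
fall-detection features, per-class Gaussian parameters for the three
fall-classification features, and per-axis amplitude standard deviations
measured at two torso locations.

Units: step f1 and all fall-class features in g; step f2 in seconds;
fall f1 in g; fall f2 in milliseconds.
"""

from __future__ import annotations

# cadence (steps/min) -> (mean, std) of step feature f1 (vertical amplitude, g)
STEP_F1: dict[int, tuple[float, float]] = {
    60: (0.4846, 0.2023),
    80: (0.6760, 0.2922),
    100: (0.8141, 0.3581),
}

# cadence (steps/min) -> (mean, std) of step feature f2 (max/min time lag, s)
STEP_F2: dict[int, tuple[float, float]] = {
    60: (0.1440, 0.0826),
    80: (0.1188, 0.0715),
    100: (0.0688, 0.0370),
}

# fall-detection features: f1 = |G| range (g), f2 = min-to-max time (ms)
FALL_F1: tuple[float, float] = (7.8549, 2.5692)
FALL_F2: tuple[float, float] = (136.27, 81.36)

# fall classes
C1 = "c1"  # frontal fall when walking
C2 = "c2"  # frontal fall when sitting
C3 = "c3"  # other fall
FALL_CLASS_LABELS: tuple[str, ...] = (C1, C2, C3)

# class -> feature -> (mean, std); features are the raw device-axis
# accelerations (g) sampled at the |G| impact peak
FALL_CLASS: dict[str, dict[str, tuple[float, float]]] = {
    C1: {"f1": (5.2423, 2.0798), "f2": (1.9998, 1.0555), "f3": (-1.8940, 0.2080)},
    C2: {"f1": (5.1299, 2.0878), "f2": (-0.8582, 3.8089), "f3": (-3.9783, 0.1520)},
    C3: {"f1": (7.1742, 1.4663), "f2": (1.4240, 4.1176), "f3": (0.0463, 3.8780)},
}

# per-axis acceleration standard deviations (g) while walking, by sensor
# location; the x axis was not characterised, so it is given equal values
# at both locations (compensation ratio 1).
LOCATION_STD: dict[str, tuple[float, float, float]] = {
    "lower_torso": (0.0812, 0.0794, 0.0830),
    "upper_torso": (0.0812, 0.0848, 0.0862),
}

DEFAULT_TAU2 = 0.1  # fall-detection threshold on the kernel product
DEFAULT_DELTA_MAX = 1.2  # analysis window length (s)
STANDARD_GRAVITY = 9.80665  # m/s^2 per g
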
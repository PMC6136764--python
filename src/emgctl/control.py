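"""Proportional velocity control from classifier output and effort.

The decoded class sets the 2-D movement direction (horizontal position,
orientation); contraction effort sets the speed magnitude through

    V = G * (X/Y - TH) / (1 - TH),   clipped to [0, G]

where X is the current MAV of the EMG averaged over all channels, Y is
the maximum of the same quantity over all training windows of the
decoded class, TH = 0.2 suppresses small unintended movements, and
G = 0.6 units/s is the speed gain.  Sub-threshold effort gives V = 0.

For right-handed users extension/flexion move the cursor right/left and
pronation/supination rotate it counterclockwise/clockwise; combined
classes move along the normalized diagonal so the speed magnitude still
equals V.  Left-handed users see both axes reversed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motions import MotionClass

DEFAULT_TH = 0.2
DEFAULT_GAIN = 0.6  # units per second

_PRIMITIVE_DIRS = {
    MotionClass.EXTENSION: np.array([1.0, 0.0]),
    MotionClass.FLEXION: np.array([-1.0, 0.0]),
    MotionClass.PRONATION: np.array([0.0, 1.0]),   # counterclockwise
    MotionClass.SUPINATION: np.array([0.0, -1.0]),  # clockwise
}


@dataclass
class ControlConfig:
    """Velocity-control parameters plus the per-class effort ceiling."""

    th: float = DEFAULT_TH
    gain: float = DEFAULT_GAIN
    y_per_class: dict[MotionClass, float] = field(default_factory=dict)
    handedness: str = "right"
    per_axis_speed: bool = False  # alternative: V on each axis instead of |v| = V

    def __post_init__(self) -> None:
        if not 0 <= self.th < 1:
            raise ValueError("TH must be in [0, 1)")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        self.y_per_class = {MotionClass(k): float(v) for k, v in self.y_per_class.items()}
        if any(v <= 0 for v in self.y_per_class.values()):
            raise ValueError("Y must be positive for every class")


def effort_speed(x: float, y: float, cfg: ControlConfig) -> float:
    """Speed magnitude from current effort X against class ceiling Y."""
    if y <= 0:
        raise ValueError("class maximum MAV Y must be positive")
    if x <= cfg.th * y:
        return 0.0  # exact zero below threshold: no sub-threshold drift
    v = cfg.gain * (x / y - cfg.th) / (1.0 - cfg.th)
    return float(np.clip(v, 0.0, cfg.gain))


def class_to_direction(cls: MotionClass, handedness: str = "right") -> np.ndarray:
    """Unit direction (dx, dtheta) for a class; (0, 0) for rest."""
    cls = MotionClass(cls)
    d = np.zeros(2)
    for p in cls.primitives:
        d = d + _PRIMITIVE_DIRS[p]
    norm = np.linalg.norm(d)
    if norm > 0:
        d = d / norm
    if handedness == "left":
        d = -d
    return d


def command(predicted_class: MotionClass, current_mav: float,
            cfg: ControlConfig) -> np.ndarray:
    """Velocity command (units/s, units/s) for one control tick.

    ``current_mav`` is the channel-averaged MAV of the most recent
    window; the class ceiling Y comes from ``cfg.y_per_class``.
    """
    cls = MotionClass(predicted_class)
    direction = class_to_direction(cls, cfg.handedness)
    if cls is MotionClass.NO_MOTION:
        return np.zeros(2)
    if cls not in cfg.y_per_class:
        raise KeyError(f"no Y ceiling recorded for class {cls.value}")
    v = effort_speed(current_mav, cfg.y_per_class[cls], cfg)
    if cfg.per_axis_speed:
        return v * np.sign(direction)
    return v * direction


def channel_averaged_mav(window: np.ndarray) -> float:
    """MAV per channel, averaged over all channels."""
    return float(np.mean(np.abs(window)))


def fit_y_per_class(windows: np.ndarray, labels) -> dict[MotionClass, float]:
    """Per-class maximum channel-averaged MAV over the training windows.

    Computed on the post-intensity-filter training set -- the same data
    the classifier saw.
    """
    mavs = np.mean(np.abs(np.asarray(windows)), axis=(1, 2))
    out: dict[MotionClass, float] = {}
    for m, lab in zip(mavs, labels):
        cls = MotionClass(lab)
        if cls is MotionClass.NO_MOTION:
            continue
        out[cls] = max(out.get(cls, 0.0), float(m))
    return out


def control_config_from_training(windows: np.ndarray, labels,
                                 th: float = DEFAULT_TH, gain: float = DEFAULT_GAIN,
                                 handedness: str = "right") -> ControlConfig:
    return ControlConfig(th=th, gain=gain, handedness=handedness,
                         y_per_class=fit_y_per_class(windows, labels))
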
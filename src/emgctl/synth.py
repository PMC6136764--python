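"""Seeded synthetic surface-EMG generator.

Surface EMG is modeled as amplitude-modulated band-limited Gaussian
noise: each channel carries an independent Gaussian carrier band-passed
to 20-450 Hz (the bulk of the surface-EMG spectrum) whose instantaneous
standard deviation is

    sigma_ch(t) = noise_floor + intensity(t) * gain[ch, class]

with class gains laid out spatially around the 8-electrode forearm ring:
each primitive motion dominates two adjacent channels, with a small
cross-talk floor on the rest, and combined motions superpose the gains
of their two primitives.  This is the standard first-order surrogate for
surface EMG; the downstream pipeline assumes only stochastic signals
with class-dependent spatial amplitude structure, which this provides.

All randomness flows from one explicit seed, split into independent
per-trial child streams via :class:`numpy.random.SeedSequence`, so a
session is exactly reproducible and its trials are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import DEFAULT_FS, N_CHANNELS, EmgRecording
from .motions import ACTIVE_CLASSES, PRIMITIVE_CLASSES, MotionClass
from .preprocess import IntensityProfile, make_intensity_profile

NO_MOTION_TRIAL_S = 30.0


def default_gains(n_channels: int = N_CHANNELS, dominant: float = 1.0,
                  crosstalk: float = 0.05) -> np.ndarray:
    """(n_channels x 4) activation gains for the primitive motions.

    Primitive k dominates channels 2k and 2k+1 of the ring; every other
    channel picks up a small cross-talk gain.
    """
    g = np.full((n_channels, len(PRIMITIVE_CLASSES)), crosstalk)
    for k in range(len(PRIMITIVE_CLASSES)):
        g[(2 * k) % n_channels, k] = dominant
        g[(2 * k + 1) % n_channels, k] = dominant
    return g


@dataclass
class SynthConfig:
    """Generator configuration.

    Parameters
    ----------
    gains : ndarray (n_channels, 4)
        Channel gain per primitive motion, in the order flexion,
        extension, pronation, supination.
    noise_floor : float
        Baseline (rest) signal scale, in the same arbitrary units.
    band : (low, high) Hz
        Spectral support of the carrier noise.
    fs : float
        Sampling rate, Hz.
    gain_jitter : float
        Relative s.d. of per-session multiplicative gain noise
        (inter-session/electrode-shift variability); 0 disables.
    """

    gains: np.ndarray = field(default_factory=default_gains)
    noise_floor: float = 0.05
    band: tuple[float, float] = (20.0, 450.0)
    fs: float = DEFAULT_FS
    gain_jitter: float = 0.0

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.ndim != 2 or self.gains.shape[1] != len(PRIMITIVE_CLASSES):
            raise ValueError("gains must be (n_channels, 4)")
        if np.any(self.gains < 0):
            raise ValueError("gains must be non-negative")
        if not 0 < self.band[0] < self.band[1] < self.fs / 2:
            raise ValueError("band must lie inside (0, fs/2)")

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    def class_gains(self, cls: MotionClass) -> np.ndarray:
        """Per-channel gain for a class: sum of its primitives' columns."""
        cls = MotionClass(cls)
        g = np.zeros(self.n_channels)
        for p in cls.primitives:
            g += self.gains[:, PRIMITIVE_CLASSES.index(p)]
        return g


def _carrier(n_channels: int, n_samples: int, band: tuple[float, float],
             fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_segment(cls: MotionClass, intensity: float | np.ndarray,
                     duration_s: float, cfg: SynthConfig,
                     seed: int | np.random.SeedSequence) -> EmgRecording:
    """One constant- or profiled-intensity EMG segment for a class.

    ``intensity`` is a contraction fraction in [0, 1]; it may be a
    per-sample vector (an envelope) of length ``duration_s * fs``.
    Identical ``(cls, intensity, duration_s, cfg, seed)`` give
    bit-identical output.
    """
    cls = MotionClass(cls)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0) or np.any(intensity > 1):
        raise ValueError("intensity must lie in [0, 1]")
    n = int(round(duration_s * cfg.fs))
    rng = np.random.default_rng(seed)
    x = _carrier(cfg.n_channels, n, cfg.band, cfg.fs, rng)
    env = cfg.noise_floor + np.outer(cfg.class_gains(cls),
                                     np.broadcast_to(intensity, (n,)))
    return EmgRecording(samples=x * env, fs=cfg.fs, motion_class=cls)


def generate_trial(cls: MotionClass, cfg: SynthConfig,
                   seed: int | np.random.SeedSequence,
                   profile: IntensityProfile | None = None,
                   trial_id: str = "") -> EmgRecording:
    """One training trial: 30 s rest, or the 4-cycle trapezoid for active classes."""
    cls = MotionClass(cls)
    if cls is MotionClass.NO_MOTION:
        rec = generate_segment(cls, 0.0, NO_MOTION_TRIAL_S, cfg, seed)
    else:
        if profile is None:
            profile = make_intensity_profile()
        t = np.arange(int(round(profile.total_s * cfg.fs))) / cfg.fs
        rec = generate_segment(cls, profile(t), profile.total_s, cfg, seed)
    rec.trial_id = trial_id
    return rec


def generate_training_session(cfg: SynthConfig | None = None, seed: int = 0,
                              profile: IntensityProfile | None = None,
                              ) -> list[EmgRecording]:
    """The 9-trial training protocol: one rest trial plus the 8 motions.

    Trial 1 is 30 s of rest; trials 2-9 each run the trapezoid profile
    (48 s at the default 4 x 12 s).  Per-trial seeds are spawned from
    ``seed``; optional per-session gain jitter is drawn first.
    """
    if cfg is None:
        cfg = SynthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ACTIVE_CLASSES) + 2)
    if cfg.gain_jitter > 0:
        jit_rng = np.random.default_rng(children[0])
        factor = 1.0 + cfg.gain_jitter * jit_rng.standard_normal(cfg.gains.shape)
        cfg = SynthConfig(gains=np.clip(cfg.gains * factor, 0, None),
                          noise_floor=cfg.noise_floor, band=cfg.band, fs=cfg.fs)
    recs = [generate_trial(MotionClass.NO_MOTION, cfg, children[1],
                           trial_id="trial_00_no_motion")]
    for i, cls in enumerate(ACTIVE_CLASSES):
        recs.append(generate_trial(cls, cfg, children[i + 2], profile=profile,
                                   trial_id=f"trial_{i + 1:02d}_{cls.value}"))
    return recs
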
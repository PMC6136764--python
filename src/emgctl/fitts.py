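"""Headless Fitts'-law target-acquisition test bench.

Targets span the 8 active motion classes crossed with six
distance/width difficulty levels (48 targets, presented in four
randomized trials of 12).  Difficulty uses the Shannon-Welford index

    ID = log2((W + D) / W**k),  k = 0.5

which separates the influence of distance and width and reduces to the
Shannon form at k = 1.

A trial runs a 30 ms control loop: a simulated user emits synthetic EMG
for its intended class and effort, the most recent 160 ms buffer is
causally filtered and decoded, and the resulting velocity command is
integrated into the 2-D cursor state (horizontal position,
orientation -- treated as two unbounded Cartesian coordinates).  A
target is acquired by keeping the cursor within a 2-D Euclidean
distance of W/2 of the goal continuously for a 1 s dwell (the dwell
timer resets on exit); a trial not acquired within 15 s -- dwell
included -- times out and counts as a failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .control import ControlConfig, channel_averaged_mav, class_to_direction, command, effort_speed
from .features import extract
from .motions import ACTIVE_CLASSES, MotionClass
from .preprocess import design_filters, window_sample_counts
from .synth import SynthConfig

DEFAULT_K = 0.5
TICK_S = 0.030
DWELL_S = 1.0
TIMEOUT_S = 15.0

#: the six (distance, width) difficulty levels of the test
DIFFICULTY_LEVELS = (
    (1.0, 0.10),
    (1.0, 0.15),
    (1.0, 0.25),
    (0.5, 0.10),
    (0.5, 0.15),
    (0.5, 0.25),
)


def shannon_welford_id(distance: float, width: float, k: float = DEFAULT_K) -> float:
    """Index of difficulty ID = log2((W + D) / W**k), in bits."""
    if distance <= 0 or width <= 0 or k <= 0:
        raise ValueError("distance, width and k must be positive")
    return float(np.log2((width + distance) / width ** k))


@dataclass(frozen=True)
class Target:
    cls: MotionClass
    distance: float
    width: float
    id_bits: float

    @classmethod
    def make(cls_, cls: MotionClass, distance: float, width: float,
             k: float = DEFAULT_K) -> "Target":
        return cls_(MotionClass(cls), distance, width,
                    shannon_welford_id(distance, width, k))


def make_target_set(k: float = DEFAULT_K, seed: int | None = None,
                    levels=DIFFICULTY_LEVELS) -> list[Target]:
    """All 8 classes x 6 difficulty levels, in seeded randomized order.

    The 48 targets are presented as four trials of 12; chunk the
    returned list in blocks of 12 to recover the trial structure.
    """
    targets = [Target.make(c, d, w, k) for c in ACTIVE_CLASSES for d, w in levels]
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(targets)
    return targets


@dataclass
class CursorState:
    x: float = 0.0
    theta: float = 0.0
    t: float = 0.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.theta])


def place_target(target: Target, start: CursorState,
                 handedness: str = "right") -> np.ndarray:
    """Goal point: start + D along the target class's direction."""
    return start.pos + target.distance * class_to_direction(target.cls, handedness)


# ---------------------------------------------------------------------------
# streaming synthetic EMG + causal preprocessing


class StreamingEmgSource:
    """Causal, chunked version of the synthetic-EMG generator.

    Emits the same amplitude-modulated band-limited noise model as the
    offline generator, but with a persistent causal band-limiting
    filter so chunk boundaries are seamless.  The carrier is scaled so
    its stationary variance is 1 (normalization from the filter's
    energy gain).
    """

    def __init__(self, cfg: SynthConfig, seed):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.sos = signal.butter(4, cfg.band, btype="bandpass", fs=cfg.fs, output="sos")
        w, h = signal.sosfreqz(self.sos, worN=2048, fs=cfg.fs)
        self.norm = 1.0 / np.sqrt(np.mean(np.abs(h) ** 2))
        self.zi = np.zeros((self.sos.shape[0], cfg.n_channels, 2))

    def emit(self, cls: MotionClass, effort: float, n_samples: int) -> np.ndarray:
        white = self.rng.standard_normal((self.cfg.n_channels, n_samples))
        carrier, self.zi = signal.sosfilt(self.sos, white, axis=1, zi=self.zi)
        env = self.cfg.noise_floor + np.clip(effort, 0, 1) * self.cfg.class_gains(cls)
        return carrier * self.norm * env[:, None]


class CausalPreprocessor:
    """Persistent-state causal band-pass + notch, matched to training filters."""

    def __init__(self, fs: float, n_channels: int):
        self.sos_bp, self.sos_notch = design_filters(fs)
        self.zi_bp = np.zeros((self.sos_bp.shape[0], n_channels, 2))
        self.zi_notch = np.zeros((self.sos_notch.shape[0], n_channels, 2))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        x, self.zi_bp = signal.sosfilt(self.sos_bp, chunk, axis=1, zi=self.zi_bp)
        x, self.zi_notch = signal.sosfilt(self.sos_notch, x, axis=1, zi=self.zi_notch)
        return x


# ---------------------------------------------------------------------------
# simulated users


@dataclass
class SimulatedUser:
    """Closed-loop stand-in for the human operator.

    Each tick the user looks at the cursor state from ``reaction_delay``
    ticks ago and picks the active class whose movement direction best
    aligns with the remaining error vector -- a combined class when both
    coordinates err beyond the dead zone, the dominant single motion
    otherwise -- with effort a saturating function of distance plus
    Gaussian noise.  Inside the target it relaxes to rest.
    """

    reaction_delay: int = 5  # ticks
    effort_noise: float = 0.1
    saturation_dist: float = 0.3  # units at which effort saturates to 1
    dead_zone: float = 0.05  # units; below this an axis is "close enough"
    bypass_decoder: bool = False
    handedness: str = "right"

    def intend(self, pos: np.ndarray, goal: np.ndarray, width: float,
               rng: np.random.Generator) -> tuple[MotionClass, float]:
        err = goal - pos
        dist = float(np.linalg.norm(err))
        if dist < width / 2:
            return MotionClass.NO_MOTION, 0.0
        candidates = []
        for c in ACTIVE_CLASSES:
            if c.is_combined and (abs(err[0]) <= self.dead_zone
                                  or abs(err[1]) <= self.dead_zone):
                continue
            candidates.append(c)
        dirs = np.array([class_to_direction(c, self.handedness) for c in candidates])
        cls = candidates[int(np.argmax(dirs @ (err / dist)))]
        effort = min(1.0, dist / self.saturation_dist)
        if self.effort_noise > 0:
            effort += self.effort_noise * rng.standard_normal()
        return cls, float(np.clip(effort, 0.0, 1.0))


def ideal_user(handedness: str = "right") -> SimulatedUser:
    """Noise-free, delay-free user that bypasses the decoder (kinematic bound)."""
    return SimulatedUser(reaction_delay=0, effort_noise=0.0, saturation_dist=1e-9,
                         dead_zone=0.0, bypass_decoder=True, handedness=handedness)


# ---------------------------------------------------------------------------
# trial execution


@dataclass
class TrialLog:
    """Tick-level record of one target-acquisition attempt."""

    target: Target
    goal: tuple[float, float]
    tick_s: float
    times: list[float] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    thetas: list[float] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)
    speeds: list[float] = field(default_factory=list)
    entries: int = 0
    first_entry_t: float | None = None
    acquired: bool = False
    acquisition_t: float | None = None
    movement_time: float | None = None  # trial start -> start of final dwell
    timed_out: bool = False

    def path(self) -> np.ndarray:
        return np.stack([self.xs, self.thetas], axis=1)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            head = {"target": {"cls": self.target.cls.value,
                               "distance": self.target.distance,
                               "width": self.target.width,
                               "id_bits": self.target.id_bits},
                    "goal": list(self.goal), "tick_s": self.tick_s,
                    "entries": self.entries, "first_entry_t": self.first_entry_t,
                    "acquired": self.acquired, "acquisition_t": self.acquisition_t,
                    "movement_time": self.movement_time, "timed_out": self.timed_out}
            fh.write(json.dumps(head) + "\n")
            for row in zip(self.times, self.xs, self.thetas, self.classes, self.speeds):
                fh.write(json.dumps(list(row)) + "\n")


def _decode(decoder, window: np.ndarray, fs: float) -> MotionClass:
    if decoder.kind == "svm":
        feats = extract(window, fs, decoder.dead_band)
        cls, _ = decoder.predict_with_scores(feats)
    else:
        cls, _ = decoder.predict_with_scores(window)
    return cls


def run_trial(target: Target, decoder, user: SimulatedUser, cfg: ControlConfig,
              synth_cfg: SynthConfig | None = None, seed=0,
              tick_s: float = TICK_S, dwell_s: float = DWELL_S,
              timeout_s: float = TIMEOUT_S,
              start: CursorState | None = None) -> TrialLog:
    """Run one closed-loop acquisition attempt.

    The EMG buffer is primed with one full window of rest signal before
    the loop starts, so the first predictions see a valid 160 ms
    window.  Timeout is a recorded outcome, not an error.
    """
    if synth_cfg is None:
        synth_cfg = SynthConfig()
    start = start or CursorState()
    goal = place_target(target, start, cfg.handedness)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    emg_seed, user_seed = ss.spawn(2)
    source = StreamingEmgSource(synth_cfg, emg_seed)
    prep = CausalPreprocessor(synth_cfg.fs, synth_cfg.n_channels)
    user_rng = np.random.default_rng(user_seed)

    win, _ = window_sample_counts(synth_cfg.fs)
    tick_n = int(round(tick_s * synth_cfg.fs))
    buffer = prep.process(source.emit(MotionClass.NO_MOTION, 0.0, win))

    log = TrialLog(target=target, goal=tuple(goal), tick_s=tick_s)
    pos = start.pos.astype(float)
    state_hist = [pos.copy()]
    in_target = False
    dwell_start: float | None = None
    t = 0.0
    n_ticks = int(np.floor(timeout_s / tick_s))
    for _ in range(n_ticks):
        delayed = state_hist[max(0, len(state_hist) - 1 - user.reaction_delay)]
        intended_cls, effort = user.intend(delayed, goal, target.width, user_rng)

        chunk = prep.process(source.emit(intended_cls, effort, tick_n))
        buffer = np.concatenate([buffer[:, tick_n:], chunk], axis=1)

        if user.bypass_decoder or decoder is None:
            cls = intended_cls
            if cls is MotionClass.NO_MOTION:
                v = np.zeros(2)
                speed = 0.0
            else:
                speed = effort_speed(effort, 1.0, cfg)  # effort stands in for X/Y
                v = speed * class_to_direction(cls, cfg.handedness)
        else:
            cls = _decode(decoder, buffer[:, -win:], synth_cfg.fs)
            x_mav = channel_averaged_mav(buffer[:, -win:])
            v = command(cls, x_mav, cfg)
            speed = float(np.linalg.norm(v))

        pos = pos + v * tick_s
        t += tick_s
        state_hist.append(pos.copy())
        log.times.append(round(t, 9))
        log.xs.append(float(pos[0]))
        log.thetas.append(float(pos[1]))
        log.classes.append(cls.value)
        log.speeds.append(speed)

        dist = float(np.linalg.norm(goal - pos))
        now_in = dist < target.width / 2
        if now_in and not in_target:
            log.entries += 1
            if log.first_entry_t is None:
                log.first_entry_t = t
            dwell_start = t
        elif not now_in and in_target:
            dwell_start = None  # dwell timer resets on exit
        in_target = now_in
        if in_target and dwell_start is not None and t - dwell_start >= dwell_s - 1e-9:
            log.acquired = True
            log.acquisition_t = t
            log.movement_time = dwell_start  # dwell itself excluded
            break
    if not log.acquired:
        log.timed_out = True
    return log


def run_session(decoder, user: SimulatedUser, targets: list[Target],
                cfg: ControlConfig, synth_cfg: SynthConfig | None = None,
                seed: int = 0, tick_s: float = TICK_S, dwell_s: float = DWELL_S,
                timeout_s: float = TIMEOUT_S) -> list[TrialLog]:
    """Run every target in order, each from a re-centred cursor.

    Per-target child seeds are spawned from ``seed``, so two decoders
    compared with the same seed and target order see identical user
    noise streams.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(targets))
    return [run_trial(tgt, decoder, user, cfg, synth_cfg, seed=child,
                      tick_s=tick_s, dwell_s=dwell_s, timeout_s=timeout_s)
            for tgt, child in zip(targets, children)]
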
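"""Filtering, windowing and training-protocol labeling.

The acquisition chain band-passes each channel between 5 and 500 Hz and
notches out 50 Hz mains interference, both with eighth-order Butterworth
filters.  Offline (training) data may be filtered zero-phase; the
closed-loop path uses the causal single-pass variant of the same filters.

Training trials follow a trapezoidal contraction-intensity protocol:
each 12 s cycle is 3 s rest, 3 s linear ramp up to full range, 3 s hold,
3 s ramp down, repeated four times per active trial.  Windows whose
commanded intensity is below 30% of full range are discarded so that
near-rest data does not contaminate the active classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EmgRecording
from .motions import MotionClass

WINDOW_MS = 160.0
INC_MS = 40.0
INTENSITY_THRESHOLD = 0.30


def design_filters(fs: float, low_hz: float = 5.0, high_hz: float = 500.0,
                   notch_hz: float = 50.0, order: int = 8,
                   notch_halfwidth_hz: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Second-order sections for the band-pass and band-stop stages.

    ``order`` is the final filter order: ``butter`` is called with
    ``order // 2`` because band-pass/-stop designs double the prototype
    order.  The notch is a Butterworth band-stop centred on ``notch_hz``
    with a +/- ``notch_halfwidth_hz`` stop band.
    """
    if order <= 0 or order % 2:
        raise ValueError("order must be a positive even integer")
    if high_hz >= fs / 2:
        raise ValueError(f"high cut-off {high_hz} Hz must be below Nyquist {fs / 2} Hz")
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    sos_bp = signal.butter(order // 2, [low_hz, high_hz], btype="bandpass",
                           fs=fs, output="sos")
    sos_notch = signal.butter(order // 2,
                              [notch_hz - notch_halfwidth_hz,
                               notch_hz + notch_halfwidth_hz],
                              btype="bandstop", fs=fs, output="sos")
    return sos_bp, sos_notch


def bandpass_notch(rec: EmgRecording, low_hz: float = 5.0, high_hz: float = 500.0,
                   notch_hz: float = 50.0, order: int = 8,
                   zero_phase: bool = True) -> EmgRecording:
    """Band-pass (5-500 Hz) and notch (50 Hz) each channel.

    ``zero_phase=True`` runs forward-backward (offline training data);
    ``zero_phase=False`` is the causal single-pass variant for streaming.
    Shape and sampling rate are preserved.
    """
    sos_bp, sos_notch = design_filters(rec.fs, low_hz, high_hz, notch_hz, order)
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    x = filt(sos_bp, rec.samples, axis=1)
    x = filt(sos_notch, x, axis=1)
    return EmgRecording(samples=np.ascontiguousarray(x), fs=rec.fs,
                        trial_id=rec.trial_id, motion_class=rec.motion_class)


def window_sample_counts(fs: float, window_ms: float = WINDOW_MS,
                         inc_ms: float = INC_MS) -> tuple[int, int]:
    """(window length, increment) in samples at rate ``fs``."""
    return int(round(fs * window_ms / 1000.0)), int(round(fs * inc_ms / 1000.0))


def segment_windows(rec: EmgRecording, window_ms: float = WINDOW_MS,
                    inc_ms: float = INC_MS) -> tuple[np.ndarray, np.ndarray]:
    """Slide a window over the recording.

    Returns ``(windows, end_times)`` where ``windows`` has shape
    (n_windows, n_channels, win) -- window k covers samples
    ``[k*inc, k*inc + win)`` -- and ``end_times`` holds the time (s) of
    each window's final sample, used as the window's reference instant.

    Raises
    ------
    ValueError
        If the recording is shorter than one window.
    """
    win, inc = window_sample_counts(rec.fs, window_ms, inc_ms)
    n = rec.n_samples
    if n < win:
        raise ValueError(f"recording of {n} samples shorter than one {win}-sample window")
    count = (n - win) // inc + 1
    starts = np.arange(count) * inc
    windows = np.stack([rec.samples[:, s:s + win] for s in starts])
    end_times = (starts + win - 1) / rec.fs
    return windows, end_times


@dataclass
class IntensityProfile:
    """Piecewise-linear commanded contraction intensity, in [0, 1].

    One cycle is rest / ramp-up / hold / ramp-down with the given
    durations (3 s each by default, hence a 12 s period), repeated
    ``reps`` times.  Evaluates to 0 outside the active span.
    """

    reps: int = 4
    ramp_s: float = 3.0
    hold_s: float = 3.0
    rest_s: float = 3.0

    def __post_init__(self) -> None:
        if self.reps < 1 or min(self.ramp_s, self.hold_s, self.rest_s) <= 0:
            raise ValueError("durations must be positive and reps >= 1")

    @property
    def cycle_s(self) -> float:
        return self.rest_s + 2 * self.ramp_s + self.hold_s

    @property
    def total_s(self) -> float:
        return self.reps * self.cycle_s

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        tc = np.mod(t, self.cycle_s)
        active = (t >= 0) & (t < self.total_s)
        r, a, h = self.rest_s, self.ramp_s, self.hold_s
        up = active & (tc >= r) & (tc < r + a)
        out[up] = (tc[up] - r) / a
        out[active & (tc >= r + a) & (tc < r + a + h)] = 1.0
        down = active & (tc >= r + a + h)
        out[down] = 1.0 - (tc[down] - (r + a + h)) / a
        return float(out[0]) if scalar else out


def make_intensity_profile(reps: int = 4, ramp_s: float = 3.0, hold_s: float = 3.0,
                           rest_s: float = 3.0) -> IntensityProfile:
    """The training-protocol trapezoid: rest 3 s, ramp 3 s, hold 3 s, ramp 3 s."""
    return IntensityProfile(reps=reps, ramp_s=ramp_s, hold_s=hold_s, rest_s=rest_s)


@dataclass
class LabeledWindowSet:
    """Windowed, labeled training data for both decoders.

    ``windows`` is (n, 8, 192) at the default 1.2 kHz / 160 ms setting;
    ``labels`` holds one :class:`MotionClass` per window.
    """

    windows: np.ndarray
    labels: list[MotionClass]
    fs: float
    window_ms: float = WINDOW_MS
    inc_ms: float = INC_MS

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, channels, samples)")
        if len(self.labels) != len(self.windows):
            raise ValueError("labels/windows length mismatch")
        self.labels = [MotionClass(c) for c in self.labels]

    def __len__(self) -> int:
        return len(self.windows)

    def extend(self, other: "LabeledWindowSet") -> "LabeledWindowSet":
        if other.fs != self.fs:
            raise ValueError("sampling-rate mismatch")
        return LabeledWindowSet(
            windows=np.concatenate([self.windows, other.windows]),
            labels=self.labels + other.labels,
            fs=self.fs, window_ms=self.window_ms, inc_ms=self.inc_ms,
        )


def label_and_filter(windows: np.ndarray, end_times: np.ndarray,
                     profile: IntensityProfile | None,
                     motion_class: MotionClass, fs: float,
                     threshold: float = INTENSITY_THRESHOLD,
                     reference: str = "end",
                     window_ms: float = WINDOW_MS,
                     inc_ms: float = INC_MS) -> LabeledWindowSet:
    """Label windows with their trial's class, dropping low-intensity ones.

    For active trials (``motion_class`` != no-motion), windows whose
    commanded intensity at the reference instant is below ``threshold``
    are removed.  ``reference`` is ``"end"`` (profile at the window's
    final sample -- the most recent instant, matching what a real-time
    labeler would see) or ``"mean"`` (profile averaged over the window).
    No-motion trials keep every window.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    motion_class = MotionClass(motion_class)
    if motion_class is MotionClass.NO_MOTION or profile is None:
        keep = np.ones(len(windows), dtype=bool)
    else:
        if reference == "end":
            ref = profile(end_times)
        elif reference == "mean":
            win_s = window_ms / 1000.0
            grid = np.linspace(0.0, win_s, 17)
            ref = np.array([profile(t_end - win_s + grid).mean() for t_end in end_times])
        else:
            raise ValueError(f"unknown reference {reference!r}")
        keep = ref >= threshold
    kept = windows[keep]
    return LabeledWindowSet(windows=kept, labels=[motion_class] * len(kept), fs=fs,
                            window_ms=window_ms, inc_ms=inc_ms)


def infer_profile(recs: list[EmgRecording]) -> IntensityProfile:
    """Recover the trapezoid profile from active-trial durations.

    Active trials run ``reps`` 12 s cycles, so the repetition count is
    the longest active-trial duration divided by the cycle length.
    """
    active = [r for r in recs
              if r.motion_class not in (None, MotionClass.NO_MOTION)]
    if not active:
        return make_intensity_profile()
    reps = max(1, int(round(max(r.duration_s for r in active) / 12.0)))
    return make_intensity_profile(reps=reps)


def prepare_training_set(recs: list[EmgRecording],
                         profile: IntensityProfile | None = None,
                         threshold: float = INTENSITY_THRESHOLD,
                         window_ms: float = WINDOW_MS, inc_ms: float = INC_MS,
                         zero_phase: bool = True,
                         prefiltered: bool = False) -> LabeledWindowSet:
    """Full offline chain: filter, segment per trial, label, intensity-filter.

    Windows never straddle trial boundaries.  Each recording must carry
    its motion class.  ``profile`` defaults to the trapezoid inferred
    from the active trials' durations (4 cycles at the standard 48 s).
    """
    if profile is None:
        profile = infer_profile(recs)
    out: LabeledWindowSet | None = None
    for rec in recs:
        if rec.motion_class is None:
            raise ValueError(f"trial {rec.trial_id!r} has no motion class")
        filtered = rec if prefiltered else bandpass_notch(rec, zero_phase=zero_phase)
        windows, end_times = segment_windows(filtered, window_ms, inc_ms)
        part = label_and_filter(windows, end_times, profile, rec.motion_class,
                                rec.fs, threshold, window_ms=window_ms, inc_ms=inc_ms)
        out = part if out is None else out.extend(part)
    if out is None:
        raise ValueError("no recordings given")
    return out
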
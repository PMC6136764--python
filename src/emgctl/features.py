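"""Time-domain feature set plus mean frequency.

Per channel and per 160 ms window the SVM pipeline computes the four
classic time-domain features -- mean absolute value (MAV), zero
crossings (ZC), waveform length (WL), slope sign changes (SSC) -- and
the power-spectrum mean frequency (MNF).  MAV and WL carry amplitude
(temporal) information, ZC/SSC and MNF carry spectral information.

The ZC/SSC dead-band threshold is the main knob that differs across
published TD implementations; it defaults to 0 here because the
synthetic data has a controlled noise floor, and is configurable
throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

FEATURE_NAMES = ("mav", "zc", "wl", "ssc", "mnf")


def mav(x: np.ndarray) -> float:
    """Mean absolute value."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(x)))


def zero_crossings(x: np.ndarray, dead_band: float = 0.0) -> int:
    """Sign changes between adjacent samples exceeding the dead band.

    A crossing is counted when ``x[i]`` and ``x[i+1]`` have opposite
    sign and ``|x[i] - x[i+1]| >= dead_band``.
    """
    if dead_band < 0:
        raise ValueError("dead_band must be >= 0")
    x = np.asarray(x, dtype=float)
    sign_change = (x[:-1] * x[1:]) < 0
    big_enough = np.abs(np.diff(x)) >= dead_band
    return int(np.sum(sign_change & big_enough))


def waveform_length(x: np.ndarray) -> float:
    """Cumulative absolute first difference (trajectory length)."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(np.abs(np.diff(x))))


def slope_sign_changes(x: np.ndarray, dead_band: float = 0.0) -> int:
    """Interior samples where the slope flips sign.

    Counted when consecutive differences ``d1 = x[i] - x[i-1]`` and
    ``d2 = x[i+1] - x[i]`` have opposite sign and both exceed the dead
    band in magnitude.
    """
    if dead_band < 0:
        raise ValueError("dead_band must be >= 0")
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    d1, d2 = d[:-1], d[1:]
    flips = (d1 * d2) < 0
    if dead_band > 0:
        flips &= (np.abs(d1) >= dead_band) & (np.abs(d2) >= dead_band)
    else:
        flips &= (np.abs(d1) > 0) & (np.abs(d2) > 0)
    return int(np.sum(flips))


def mean_frequency(x: np.ndarray, fs: float) -> float:
    """Power-spectrum-weighted mean frequency, DC bin excluded.

    Uses a single rectangular-window periodogram of the whole segment:
    160 ms windows are too short for multi-segment averaging.
    """
    x = np.asarray(x, dtype=float)
    f, p = _signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    f, p = f[1:], p[1:]  # drop DC
    total = p.sum()
    if total <= 0:
        return 0.0
    return float(np.sum(f * p) / total)


def extract(window: np.ndarray, fs: float, dead_band: float = 0.0) -> np.ndarray:
    """Feature vector for one multichannel window, channel-major.

    Returns ``5 * n_channels`` values ordered
    ``(mav, zc, wl, ssc, mnf)`` for channel 0, then channel 1, ...
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError(f"window must be channels x samples, got shape {window.shape}")
    out = np.empty(5 * window.shape[0])
    for c, x in enumerate(window):
        out[5 * c:5 * c + 5] = (
            mav(x),
            zero_crossings(x, dead_band),
            waveform_length(x),
            slope_sign_changes(x, dead_band),
            mean_frequency(x, fs),
        )
    return out


def feature_names(n_channels: int = 8) -> list[str]:
    """Column names matching :func:`extract`'s ordering."""
    return [f"ch{c}_{f}" for c in range(n_channels) for f in FEATURE_NAMES]


def write_feature_table(path, features: np.ndarray, n_channels: int = 8) -> None:
    """Write a feature matrix as delimited text with named columns."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    np.savetxt(path, features, delimiter=",", comments="",
               header=",".join(feature_names(n_channels)), fmt="%.8g")


def extract_many(windows: np.ndarray, fs: float, dead_band: float = 0.0) -> np.ndarray:
    """Feature matrix (n_windows, 5 * n_channels) for a stack of windows.

    Vectorized equivalent of calling :func:`extract` per window (the
    scalar path remains the reference in tests).
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3:
        raise ValueError("windows must be (n, channels, samples)")
    d = np.diff(w, axis=-1)
    _mav = np.mean(np.abs(w), axis=-1)
    _wl = np.sum(np.abs(d), axis=-1)
    _zc = np.sum((w[..., :-1] * w[..., 1:] < 0) & (np.abs(d) >= dead_band), axis=-1)
    flips = d[..., :-1] * d[..., 1:] < 0
    db = dead_band if dead_band > 0 else 0.0
    if db > 0:
        flips &= (np.abs(d[..., :-1]) >= db) & (np.abs(d[..., 1:]) >= db)
    else:
        flips &= (np.abs(d[..., :-1]) > 0) & (np.abs(d[..., 1:]) > 0)
    _ssc = np.sum(flips, axis=-1)
    f, p = _signal.periodogram(w, fs=fs, window="boxcar", detrend=False, axis=-1)
    f, p = f[1:], p[..., 1:]
    tot = p.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _mnf = np.where(tot > 0, np.sum(f * p, axis=-1) / np.where(tot > 0, tot, 1.0), 0.0)
    stacked = np.stack([_mav, _zc, _wl, _ssc, _mnf], axis=-1)  # (n, ch, 5)
    return stacked.reshape(len(w), -1)
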
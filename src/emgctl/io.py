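"""Recording container and on-disk formats.

An :class:`EmgRecording` is a channels x time float matrix with its
sampling rate and (optionally) the trial identity and motion class it was
recorded under.  Recordings round-trip through two equivalent formats:

* delimited text -- one column per channel, ``#``-prefixed header lines
  carrying ``fs`` and class metadata (human-inspectable, diff-friendly);
* HDF5 -- one dataset per recording with the same metadata as attributes.

Session-level trial annotations live in a JSON manifest next to the
per-trial files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motions import MotionClass

N_CHANNELS = 8  # electrode pairs around the forearm
DEFAULT_FS = 1200.0  # Hz


@dataclass
class EmgRecording:
    """Multichannel surface-EMG signal with acquisition metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz; must be positive.
    trial_id : str
        Free-form trial identifier.
    motion_class : MotionClass or None
        Class performed throughout the trial, if assigned.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    trial_id: str = ""
    motion_class: MotionClass | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.motion_class is not None:
            self.motion_class = MotionClass(self.motion_class)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (t=0 at the first sample)."""
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# delimited text


def write_recording_csv(rec: EmgRecording, path: str | Path) -> None:
    path = Path(path)
    cls = rec.motion_class.value if rec.motion_class is not None else ""
    header = (
        f"# fs={rec.fs}\n"
        f"# trial_id={rec.trial_id}\n"
        f"# motion_class={cls}\n"
        + ",".join(f"ch{i}" for i in range(rec.n_channels))
    )
    np.savetxt(path, rec.samples.T, delimiter=",", header=header, comments="",
               fmt="%.6g")


def read_recording_csv(path: str | Path) -> EmgRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    data = np.loadtxt(path, delimiter=",", comments="#", skiprows=len(meta) + 1)
    data = np.atleast_2d(data)
    cls = meta.get("motion_class") or None
    return EmgRecording(
        samples=data.T,
        fs=float(meta.get("fs", DEFAULT_FS)),
        trial_id=meta.get("trial_id", ""),
        motion_class=MotionClass(cls) if cls else None,
    )


# ---------------------------------------------------------------------------
# HDF5


def write_recording_h5(rec: EmgRecording, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("emg", data=rec.samples)
        ds.attrs["fs"] = rec.fs
        ds.attrs["trial_id"] = rec.trial_id
        ds.attrs["motion_class"] = (
            rec.motion_class.value if rec.motion_class is not None else ""
        )


def read_recording_h5(path: str | Path) -> EmgRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["emg"]
        cls = ds.attrs["motion_class"] or None
        return EmgRecording(
            samples=ds[()],
            fs=float(ds.attrs["fs"]),
            trial_id=str(ds.attrs["trial_id"]),
            motion_class=MotionClass(cls) if cls else None,
        )


# ---------------------------------------------------------------------------
# session directories


@dataclass
class SessionManifest:
    """JSON-sidecar description of a multi-trial session directory."""

    fs: float
    trials: list[dict] = field(default_factory=list)  # {file, trial_id, motion_class}
    seed: int | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"fs": self.fs, "seed": self.seed, "trials": self.trials}, fh, indent=2
            )

    @classmethod
    def load(cls, path: str | Path) -> "SessionManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(fs=d["fs"], trials=d["trials"], seed=d.get("seed"))


def write_session(recs: list[EmgRecording], outdir: str | Path,
                  seed: int | None = None, fmt: str = "csv") -> Path:
    """Write a list of trial recordings plus a manifest; returns the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = SessionManifest(fs=recs[0].fs, seed=seed)
    for i, rec in enumerate(recs):
        name = f"trial_{i:02d}.{ 'h5' if fmt == 'h5' else 'csv' }"
        if fmt == "h5":
            write_recording_h5(rec, outdir / name)
        else:
            write_recording_csv(rec, outdir / name)
        manifest.trials.append(
            {
                "file": name,
                "trial_id": rec.trial_id,
                "motion_class": rec.motion_class.value if rec.motion_class else None,
            }
        )
    manifest.save(outdir / "manifest.json")
    return outdir


def read_session(indir: str | Path) -> list[EmgRecording]:
    indir = Path(indir)
    manifest = SessionManifest.load(indir / "manifest.json")
    recs = []
    for t in manifest.trials:
        p = indir / t["file"]
        rec = read_recording_h5(p) if p.suffix == ".h5" else read_recording_csv(p)
        recs.append(rec)
    return recs
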
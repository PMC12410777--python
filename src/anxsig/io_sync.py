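"""Stream containers, delimited-text readers/writers, resampling and epoching.

All streams in a study recording share one clock origin (the acquisition
software timestamps every device against a common time base), so
synchronization reduces to resampling each uniformly sampled stream onto a
shared 100 Hz grid and slicing sliding analysis windows from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

#: Stream names the pipeline knows how to process.
KNOWN_STREAMS = frozenset(
    {"eeg", "ecg", "eog", "gsr", "resp", "pupil", "imu_roll"}
)

#: Common analysis rate in Hz after synchronization.
COMMON_FS = 100.0

#: Sliding-window epoching defaults: 30 s windows advanced by 5 s.
WINDOW_S = 30.0
STEP_S = 5.0


class StreamFormatError(ValueError):
    """Raised for malformed stream files (bad header, non-uniform time)."""


@dataclass
class Stream:
    """One uniformly sampled, timestamped multichannel signal.

    Parameters
    ----------
    name : str
        Stream identifier, e.g. ``"ecg"``.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Timestamp of the first sample in seconds on the shared clock.
    channel_labels : list of str
        One label per channel.
    samples : ndarray, shape (n_channels, n_samples)
        Signal values in physical units.
    """

    name: str
    fs: float
    t0: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"stream {self.name!r}: fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"stream {self.name!r}: {len(self.channel_labels)} labels "
                f"for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "Stream":
        return Stream(self.name, self.fs, self.t0,
                      list(self.channel_labels), self.samples.copy())


@dataclass
class Recording:
    """A participant's set of streams plus pre/post questionnaire items.

    ``gad7_pre`` / ``gad7_post`` are the 7 item scores (each on a 0-3
    continuous visual-analogue scale) collected immediately before and
    after the anticipation task.
    """

    participant_id: str
    streams: dict[str, Stream]
    gad7_pre: np.ndarray
    gad7_post: np.ndarray
    meta: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gad7_pre = np.asarray(self.gad7_pre, dtype=float)
        self.gad7_post = np.asarray(self.gad7_post, dtype=float)


@dataclass
class EpochSet:
    """Sliding-window epochs cut from one stream at the common rate."""

    window_s: float
    step_s: float
    fs: float
    channel_labels: list[str]
    epochs: np.ndarray  # (n_epochs, n_channels, n_window_samples)
    start_times: np.ndarray  # (n_epochs,), seconds

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def resample_to_common(stream: Stream, target_fs: float = COMMON_FS) -> Stream:
    """Resample a uniformly sampled stream to ``target_fs``.

    Uses polyphase rational resampling (zero-phase FIR anti-alias filter),
    which preserves the amplitude spectrum below the target Nyquist.
    """
    if stream.n_samples == 0:
        raise ValueError(f"stream {stream.name!r} is empty")
    if stream.fs == target_fs:
        return stream.copy()
    frac = Fraction(target_fs / stream.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(stream.samples, up, down, axis=1, padtype="line")
    return Stream(stream.name, target_fs, stream.t0,
                  list(stream.channel_labels), out)


def n_epochs_for(duration_s: float, window_s: float = WINDOW_S,
                 step_s: float = STEP_S) -> int:
    """Number of sliding windows: floor((duration - window)/step) + 1."""
    if duration_s < window_s:
        raise ValueError(
            f"duration {duration_s} s shorter than one {window_s} s window"
        )
    # integer arithmetic on sample-equivalent counts avoids float fencepost
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def make_epochs(stream: Stream, window_s: float = WINDOW_S,
                step_s: float = STEP_S) -> EpochSet:
    """Cut half-open [k*step, k*step + window) epochs from a stream.

    A 300 s stream at 100 Hz with the default 30 s / 5 s scheme yields
    exactly 55 epochs of 3000 samples each.
    """
    win_n = int(round(window_s * stream.fs))
    step_n = int(round(step_s * stream.fs))
    if stream.n_samples < win_n:
        raise ValueError(
            f"stream {stream.name!r}: {stream.duration_s:.6g} s is shorter "
            f"than one {window_s:g} s window"
        )
    n_ep = (stream.n_samples - win_n) // step_n + 1
    starts = np.arange(n_ep) * step_n
    idx = starts[:, None] + np.arange(win_n)[None, :]
    epochs = stream.samples[:, idx].transpose(1, 0, 2)
    return EpochSet(window_s, step_s, stream.fs, list(stream.channel_labels),
                    np.ascontiguousarray(epochs),
                    stream.t0 + starts / stream.fs)


# ---------------------------------------------------------------------------
# Delimited-text persistence
# ---------------------------------------------------------------------------

def _write_stream_file(stream: Stream, path: Path) -> None:
    header = "time," + ",".join(stream.channel_labels)
    data = np.column_stack([stream.times, stream.samples.T])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=header,
               comments="")


def _read_stream_file(path: Path, name: str, fs: float) -> Stream:
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    if not cols or cols[0] != "time":
        raise StreamFormatError(
            f"stream {name!r}: malformed header in {path.name} "
            "(first column must be 'time')"
        )
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    times, samples = data[:, 0], data[:, 1:].T
    if len(times) > 1:
        dt = np.diff(times)
        bad = np.flatnonzero(dt > 1.5 / fs)
        if bad.size:
            raise StreamFormatError(
                f"stream {name!r}: non-uniform timestamps at t="
                f"{times[bad[0]]:.6g} s (gap {dt[bad[0]]:.6g} s > 1.5/fs)"
            )
    return Stream(name, fs, float(times[0]), cols[1:], samples)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write one directory per participant: CSV per stream + JSON manifest.

    Ground-truth arrays (beat times, tonic/phasic traces, EOG traces) are
    stored alongside so feature extractors can be validated by parameter
    recovery after a round trip.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "participant_id": rec.participant_id,
        "streams": {},
        "gad7_pre": rec.gad7_pre.tolist(),
        "gad7_post": rec.gad7_post.tolist(),
        "meta": rec.meta,
    }
    for name, stream in rec.streams.items():
        fname = f"{name}.csv"
        _write_stream_file(stream, path / fname)
        manifest["streams"][name] = {"file": fname, "fs": stream.fs}
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if rec.ground_truth:
        gt_out: dict = {}
        for key, val in rec.ground_truth.items():
            if isinstance(val, (str, dict)):
                gt_out[key] = val
                continue
            arr = np.asarray(val)
            if arr.ndim == 0 or (arr.ndim == 1 and arr.size <= 10_000):
                gt_out[key] = arr.tolist()
            else:  # long traces go to their own delimited file
                fname = f"gt_{key}.csv"
                np.savetxt(path / fname, np.atleast_2d(arr).T, fmt="%.17g",
                           delimiter=",")
                gt_out[key] = {"file": fname}
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(gt_out, fh)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a participant directory written by :func:`write_recording`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    streams = {}
    for name, entry in manifest["streams"].items():
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"stream {name!r}: file {entry['file']} missing under {path}"
            )
        if name not in KNOWN_STREAMS:
            warnings.warn(
                f"unknown stream {name!r} carried through untouched",
                stacklevel=2,
            )
        streams[name] = _read_stream_file(fpath, name, entry["fs"])
    ground_truth = {}
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            raw = json.load(fh)
        for key, val in raw.items():
            if isinstance(val, dict) and "file" in val:
                arr = np.loadtxt(path / val["file"], delimiter=",", ndmin=2).T
                ground_truth[key] = arr[0] if arr.shape[0] == 1 else arr
            elif isinstance(val, list):
                ground_truth[key] = np.asarray(val, dtype=float)
            else:
                ground_truth[key] = val
    return Recording(
        participant_id=manifest["participant_id"],
        streams=streams,
        gad7_pre=np.asarray(manifest["gad7_pre"], dtype=float),
        gad7_post=np.asarray(manifest["gad7_post"], dtype=float),
        meta=manifest.get("meta", {}),
        ground_truth=ground_truth,
    )
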
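"""Per-epoch feature extraction.

Each 30 s epoch of each processed stream is reduced to scalar features:
heart rate and an interval-variability ratio from beat detection, epoch
means for the slow conductance/pupil signals, a peak-counted respiratory
rate, head-roll variance, and Welch power spectra with 1 Hz bins for the
gyroscope and every EEG channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .io_sync import COMMON_FS, EpochSet, Recording, make_epochs
from .synth import EEG_BANDS

#: Minimum spacing between cardiac beats (240 bpm ceiling).
HR_REFRACTORY_S = 0.25
#: Minimum spacing between breaths (30 brpm ceiling).
RESP_REFRACTORY_S = 2.0
#: Plausibility gate: maximum coefficient of variation of detected
#: inter-beat intervals before an epoch is flagged missing.
MAX_INTERVAL_CV = 0.4


def _znorm(x: np.ndarray) -> np.ndarray | None:
    sd = np.std(x)
    if sd < 1e-12:
        return None
    return (x - np.mean(x)) / sd


def detect_beats(epoch: np.ndarray, fs: float = COMMON_FS) -> np.ndarray:
    """Detect beat times (s, epoch-relative) on the normalized negative
    derivative of a cardiac epoch.

    The epoch is z-normalized, differenced and negated; peaks above half
    the epoch maximum with a 250 ms refractory period are beat events.
    """
    z = _znorm(np.asarray(epoch, dtype=float))
    if z is None:
        return np.empty(0)
    d = -np.diff(z)
    if d.max() <= 0:
        return np.empty(0)
    peaks, _ = _sig.find_peaks(d, height=0.5 * d.max(),
                               distance=max(1, int(round(HR_REFRACTORY_S * fs))))
    return peaks / fs


def _interval_rate(peak_times: np.ndarray, lo: float, hi: float
                   ) -> float:
    """Events/min from inter-peak intervals, gated on plausibility."""
    if len(peak_times) < 2:
        return np.nan
    iv = np.diff(peak_times)
    rate = 60.0 * len(iv) / iv.sum()
    if not lo <= rate <= hi:
        return np.nan
    if len(iv) >= 3 and np.std(iv) / np.mean(iv) > MAX_INTERVAL_CV:
        return np.nan
    return rate


def extract_hr(epoch: np.ndarray, fs: float = COMMON_FS) -> float:
    """Heart rate in bpm from one cardiac epoch; NaN when detection fails
    or the detected rhythm is implausible (e.g. a pure-noise epoch)."""
    return _interval_rate(detect_beats(epoch, fs), 30.0, 240.0)


def extract_hrv(beat_times: np.ndarray) -> float:
    """SD of inter-beat intervals divided by their RMS (dimensionless).

    Sample (n-1) standard deviation over the intervals; NaN for fewer
    than 3 beats.  A perfectly regular rhythm scores exactly 0, and the
    ratio is invariant to rescaling all intervals.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 3:
        return np.nan
    iv = np.diff(beat_times)
    rms = np.sqrt(np.mean(iv**2))
    if rms == 0:
        return np.nan
    return float(np.std(iv, ddof=1) / rms)


def epoch_mean(epoch: np.ndarray) -> float:
    """Arithmetic mean over the epoch samples (tonic/phasic/pupil)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size == 0:
        raise ValueError("empty epoch")
    return float(epoch.mean())


def zero_baseline(series: np.ndarray) -> np.ndarray:
    """Subtract the first epoch's value so the trace starts at zero."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty feature series")
    return series - series[0]


def extract_resp_rate(epoch: np.ndarray, fs: float = COMMON_FS) -> float:
    """Respiratory rate in breaths/min from a normalized epoch; peaks with
    a 2 s refractory period; NaN on degenerate input."""
    z = _znorm(np.asarray(epoch, dtype=float))
    if z is None:
        return np.nan
    peaks, _ = _sig.find_peaks(
        z, height=0.5 * z.max(),
        distance=max(1, int(round(RESP_REFRACTORY_S * fs))))
    return _interval_rate(peaks / fs, 4.0, 30.0)


def roll_variance(epoch: np.ndarray) -> float:
    """Sample variance of the head-roll epoch, (deg/s)^2."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size == 0:
        raise ValueError("empty epoch")
    return float(np.var(epoch, ddof=1))


def welch_psd(epoch: np.ndarray, fs: float = COMMON_FS,
              bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with ``bin_width``-spaced bins (1 s Hann segments, 50%
    overlap at the defaults).  Returns ``(freqs, psd)``; works on 1-D or
    (channels, time) input along the last axis."""
    epoch = np.asarray(epoch, dtype=float)
    nperseg = int(round(fs / bin_width))
    if epoch.shape[-1] < nperseg:
        raise ValueError(
            f"epoch of {epoch.shape[-1]} samples shorter than one "
            f"{nperseg}-sample Welch segment")
    freqs, psd = _sig.welch(epoch, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2, axis=-1)
    return freqs, psd


def band_power(psd: np.ndarray, freqs: np.ndarray,
               band: tuple[float, float]) -> np.ndarray:
    """Mean PSD over the half-open frequency band [lo, hi)."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"no PSD bins inside band [{lo}, {hi})")
    return np.asarray(psd)[..., mask].mean(axis=-1)


# ---------------------------------------------------------------------------
# Recording-level extraction
# ---------------------------------------------------------------------------

#: Scalar measures emitted per epoch, with their units.
MEASURE_UNITS: dict[str, str] = {
    "hr": "bpm", "hrv": "ratio", "tonic": "uS", "phasic": "uS",
    "pupil_left": "mm", "pupil_right": "mm", "pupil_mean": "mm",
    "resp_rate": "brpm", "roll_variance": "dps2",
}


def extract_features(proc: Recording, window_s: float = 30.0,
                     step_s: float = 5.0) -> dict:
    """Extract every per-epoch measure from one preprocessed recording.

    Returns a dict with scalar series (one value per epoch) under the
    keys of :data:`MEASURE_UNITS`, plus ``roll_psd`` (epochs x bins),
    ``eeg_psd`` (epochs x channels x bins), ``psd_freqs`` and
    ``eeg_labels``.  Pupil traces are first-epoch zeroed.
    """
    eps = {name: make_epochs(proc.streams[name], window_s, step_s)
           for name in ("hr_raw", "tonic", "phasic", "pupil", "resp",
                        "roll", "eeg25")}
    fs = proc.streams["hr_raw"].fs
    n_ep = eps["hr_raw"].n_epochs

    out: dict = {}
    hr = np.empty(n_ep)
    hrv = np.empty(n_ep)
    for k in range(n_ep):
        beats = detect_beats(eps["hr_raw"].epochs[k, 0], fs)
        hr[k] = _interval_rate(beats, 30.0, 240.0)
        hrv[k] = extract_hrv(beats) if not np.isnan(hr[k]) else np.nan
    out["hr"], out["hrv"] = hr, hrv

    out["tonic"] = eps["tonic"].epochs[:, 0].mean(axis=-1)
    out["phasic"] = eps["phasic"].epochs[:, 0].mean(axis=-1)

    pup_l = eps["pupil"].epochs[:, 0].mean(axis=-1)
    pup_r = eps["pupil"].epochs[:, 1].mean(axis=-1)
    out["pupil_left"] = zero_baseline(pup_l)
    out["pupil_right"] = zero_baseline(pup_r)
    out["pupil_mean"] = zero_baseline((pup_l + pup_r) / 2.0)

    out["resp_rate"] = np.array(
        [extract_resp_rate(eps["resp"].epochs[k, 0], fs)
         for k in range(n_ep)])
    out["roll_variance"] = np.array(
        [roll_variance(eps["roll"].epochs[k, 0]) for k in range(n_ep)])

    freqs, roll_psd = welch_psd(eps["roll"].epochs[:, 0], fs)
    out["roll_psd"] = roll_psd
    _, eeg_psd = welch_psd(eps["eeg25"].epochs, fs)
    out["eeg_psd"] = eeg_psd
    out["psd_freqs"] = freqs
    out["eeg_labels"] = list(eps["eeg25"].channel_labels)
    return out


def cohort_feature_tables(per_participant: dict[str, dict]
                          ) -> dict[str, pd.DataFrame]:
    """Stack per-participant feature dicts into participants x epochs
    DataFrames, one per scalar measure."""
    tables = {}
    ids = list(per_participant)
    for measure in MEASURE_UNITS:
        tables[measure] = pd.DataFrame(
            {pid: per_participant[pid][measure] for pid in ids}).T
    return tables
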
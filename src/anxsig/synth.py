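"""Synthetic multimodal cohort generator.

Emulates the statistical structure the downstream analysis consumes — not
realistic physiology.  Each participant gets seven signal streams at their
native acquisition rates (electrophysiology at 500 Hz, pupillometry at
200 Hz, head gyroscope at 110 Hz) plus pre/post anxiety-questionnaire item
scores.  The two groups differ in heart rate, respiratory rate, tonic skin
conductance level, head-roll variance and EEG band power, mirroring the
group contrasts the analysis is designed to detect.  Ground truth (beat
times, tonic/phasic traces, ocular traces, per-band power settings) is
attached to every recording so feature extractors can be validated by
parameter recovery.

Everything is driven by one integer seed through ``numpy``'s Generator, so
a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .io_sync import Recording, Stream, WINDOW_S
from .preprocess import EEG_MONTAGE

#: Native acquisition rates in Hz.
NATIVE_RATES: dict[str, float] = {
    "eeg": 500.0, "ecg": 500.0, "eog": 500.0, "gsr": 500.0, "resp": 500.0,
    "pupil": 200.0, "imu_roll": 110.0,
}

#: EEG band edges in Hz, half-open [lo, hi).
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0), "gamma": (30.0, 50.0),
}

#: Head-roll synthesis band (Hz). Kept well inside the 45 Hz effective
#: low-pass of preprocessing so the filter conserves the signal variance.
ROLL_BAND: tuple[float, float] = (0.5, 35.0)

#: Skin-conductance-response decay time constant in seconds.
SCR_TAU_S = 3.0


@dataclass
class ParticipantSpec:
    """Generator parameters for one participant."""

    id: str
    group: str  # "anxious" | "non_anxious"
    hr_bpm: float = 70.0
    hr_jitter_sd_ms: float = 30.0
    resp_brpm: float = 16.0
    tonic_level_uS: float = 6.0
    tonic_slope_uS_per_s: float = 0.0
    tonic_drift_amp_uS: float = 0.0
    phasic_event_rate_per_min: float = 3.0
    roll_noise_variance_dps2: float = 4.0
    eeg_band_power: dict[str, float] = field(default_factory=dict)
    eog_mixing_gain: float = 0.15
    powerline_amp_uV: float = 3.0
    pupil_base_mm: float = 3.5
    pupil_trend_mm_per_s: float = -0.001
    gad7_pre: float = 3.0
    gad7_post: float = 6.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.hr_bpm <= 200.0:
            raise ValueError(f"hr_bpm {self.hr_bpm} outside [30, 200]")
        if not 6.0 <= self.resp_brpm <= 40.0:
            raise ValueError(f"resp_brpm {self.resp_brpm} outside [6, 40]")
        if self.tonic_level_uS <= 0:
            raise ValueError("tonic_level_uS must be positive")
        if self.roll_noise_variance_dps2 < 0:
            raise ValueError("roll variance must be non-negative")
        for v in (self.gad7_pre, self.gad7_post):
            if not 0.0 <= v <= 21.0:
                raise ValueError(f"GAD-7 total {v} outside [0, 21]")
        if not self.eeg_band_power:
            self.eeg_band_power = dict(BASELINE_BAND_POWER)


#: Baseline EEG band power levels in uV^2/Hz.
BASELINE_BAND_POWER: dict[str, float] = {
    "delta": 2.0, "theta": 1.5, "alpha": 2.0, "beta": 0.8, "gamma": 0.3,
}

#: Group-level generator targets.  Means follow the study's descriptive
#: table; between-subject SDs are scaled-down versions of the printed SDs
#: so that small synthetic cohorts keep distinct, well-ordered groups.
GROUP_TEMPLATES: dict[str, dict] = {
    "anxious": dict(
        hr_bpm=79.445, resp_brpm=17.879, tonic_level_uS=8.099,
        roll_noise_variance_dps2=8.261,
        eeg_band_power={"delta": 2.0, "theta": 3.0, "alpha": 2.0,
                        "beta": 1.6, "gamma": 0.6},
    ),
    "non_anxious": dict(
        hr_bpm=66.75, resp_brpm=15.37, tonic_level_uS=4.84,
        roll_noise_variance_dps2=2.104,
        eeg_band_power=dict(BASELINE_BAND_POWER),
    ),
}

#: Between-subject SDs applied around the group means.
BETWEEN_SD: dict[str, float] = {
    "hr_bpm": 5.0, "resp_brpm": 1.2, "tonic_level_uS": 1.0,
    "roll_rel": 0.25,  # multiplicative SD on roll variance
    "eeg_rel": 0.25,   # multiplicative SD on per-band EEG power
}


@dataclass
class CohortSpec:
    """Cohort-level generator settings."""

    n_participants: int = 17
    duration_s: float = 300.0
    seed: int = 0
    native_rates: dict[str, float] = field(
        default_factory=lambda: dict(NATIVE_RATES))
    group_templates: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 GROUP_TEMPLATES.items()})

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        if self.duration_s < WINDOW_S:
            raise ValueError(
                f"duration {self.duration_s} s shorter than one "
                f"{WINDOW_S:g} s analysis window")


# ---------------------------------------------------------------------------
# Per-stream synthesizers
# ---------------------------------------------------------------------------

def synth_ecg(hr_bpm: float, hr_jitter_sd_ms: float, duration_s: float,
              fs: float, rng: np.random.Generator,
              qrs_amp: float = 1.0, noise_sd: float = 0.02,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Two-electrode cardiac signal whose bipolar difference carries one
    sharp QRS-like deflection per beat.

    Beat times follow inter-beat intervals of 60/hr_bpm seconds with
    Gaussian jitter; the QRS template is a narrow Gaussian (sigma 8 ms).
    Returns ``(samples (2, n), beat_times)``.
    """
    if not 30.0 <= hr_bpm <= 200.0:
        raise ValueError(f"hr_bpm {hr_bpm} outside [30, 200]")
    if fs < 100.0:
        raise ValueError("ECG synthesis needs fs >= 100 Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ibi = 60.0 / hr_bpm
    beats = []
    tb = 0.3 + rng.uniform(0, ibi)
    while tb < duration_s - 0.1:
        beats.append(tb)
        tb += ibi + rng.normal(0.0, hr_jitter_sd_ms / 1000.0)
    beat_times = np.asarray(beats)
    sigma = 0.008
    diff = np.zeros(n)
    half = int(round(5 * sigma * fs))
    for tb in beat_times:
        i0 = int(round(tb * fs))
        lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
        diff[lo:hi] += qrs_amp * np.exp(
            -0.5 * ((t[lo:hi] - tb) / sigma) ** 2)
    common = 0.05 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    ch1 = 0.5 * diff + common + rng.normal(0, noise_sd, n)
    ch2 = -0.5 * diff + common + rng.normal(0, noise_sd, n)
    return np.vstack([ch1, ch2]), beat_times


def synth_eda(tonic_level_uS: float, tonic_slope_uS_per_s: float,
              phasic_event_rate_per_min: float, duration_s: float, fs: float,
              rng: np.random.Generator, drift_amp_uS: float = 0.0,
              noise_sd: float = 0.005,
              ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Skin-conductance signal = tonic (level + slope + sub-0.05 Hz drift)
    + phasic (sparse exponential-decay responses) + sensor noise.

    Returns ``(samples (1, n), {"tonic": ..., "phasic": ...})`` where the
    dict carries the noiseless ground-truth components.
    """
    if tonic_level_uS <= 0:
        raise ValueError("tonic level must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    tonic = tonic_level_uS + tonic_slope_uS_per_s * t
    if drift_amp_uS > 0:
        for f in (0.005, 0.012):  # well below the 0.05 Hz split
            tonic = tonic + drift_amp_uS * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    phasic = np.zeros(n)
    n_events = rng.poisson(phasic_event_rate_per_min * duration_s / 60.0)
    kernel_len = int(round(8 * SCR_TAU_S * fs))
    kernel = np.exp(-np.arange(kernel_len) / (SCR_TAU_S * fs))
    for _ in range(n_events):
        i0 = int(rng.uniform(0, n))
        amp = rng.uniform(0.1, 0.5)
        hi = min(n, i0 + kernel_len)
        phasic[i0:hi] += amp * kernel[: hi - i0]
    x = tonic + phasic + rng.normal(0, noise_sd, n)
    return x[None, :], {"tonic": tonic, "phasic": phasic}


def synth_resp(resp_brpm: float, duration_s: float, fs: float,
               rng: np.random.Generator, amp: float = 1.0,
               noise_sd: float = 0.05) -> np.ndarray:
    """Respiration belt signal: a sinusoid at resp_brpm/60 Hz plus noise."""
    import warnings as _w
    if not 6.0 <= resp_brpm <= 30.0:
        _w.warn(f"respiratory rate {resp_brpm} brpm falls outside the "
                "0.1-0.5 Hz analysis band", stacklevel=2)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    return (amp * np.sin(2 * np.pi * resp_brpm / 60.0 * t + phase)
            + rng.normal(0, noise_sd, n))[None, :]


def synth_pupil(base_mm: float, trend_mm_per_s: float, duration_s: float,
                fs: float, rng: np.random.Generator,
                fluct_mm: float = 0.05) -> np.ndarray:
    """Two-channel (left/right eye) slowly varying pupil diameter trace."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    out = np.empty((2, n))
    for eye in range(2):
        slow = np.zeros(n)
        for f in (0.02, 0.07):
            slow += fluct_mm * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        offset = rng.normal(0, 0.05)
        out[eye] = base_mm + offset + trend_mm_per_s * t + slow \
            + rng.normal(0, 0.01, n)
    return out


def synth_imu_roll(variance_dps2: float, duration_s: float, fs: float,
                   rng: np.random.Generator,
                   band: tuple[float, float] = ROLL_BAND) -> np.ndarray:
    """Zero-mean head-roll angular velocity: band-limited noise rescaled to
    the requested stationary sample variance."""
    if variance_dps2 < 0:
        raise ValueError("variance must be non-negative")
    n = int(round(duration_s * fs))
    if variance_dps2 == 0:
        return np.zeros((1, n))
    white = rng.standard_normal(n)
    sos = _sig.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, white)
    x = x - x.mean()
    x *= np.sqrt(variance_dps2) / x.std(ddof=1)
    return x[None, :]


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], variance: float) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = _sig.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, white)
    x *= np.sqrt(variance) / x.std()
    return x


def synth_eog(duration_s: float, fs: float, rng: np.random.Generator,
              amp_uV: float = 20.0) -> tuple[np.ndarray, dict]:
    """Four EOG electrodes (2 vertical, 2 horizontal) whose pairwise
    differences recover the stored ground-truth ocular traces."""
    n = int(round(duration_s * fs))
    veog = _band_noise(rng, n, fs, (0.3, 5.0), amp_uV**2)
    heog = _band_noise(rng, n, fs, (0.3, 5.0), amp_uV**2)
    noise = lambda: rng.normal(0, 1.0, n)  # noqa: E731
    elec = np.vstack([
        0.5 * veog + noise(), -0.5 * veog + noise(),
        0.5 * heog + noise(), -0.5 * heog + noise(),
    ])
    return elec, {"veog": veog, "heog": heog}


def synth_eeg(band_power: dict[str, float], eog_gt: dict,
              eog_mixing_gain: float, powerline_amp_uV: float,
              duration_s: float, fs: float, rng: np.random.Generator,
              channel_labels: tuple[str, ...] = EEG_MONTAGE,
              channel_band_scale: dict[str, dict[str, float]] | None = None,
              return_clean: bool = False,
              ) -> tuple[np.ndarray, np.ndarray | None]:
    """27-channel EEG: per-band shaped noise + scaled ocular traces +
    50 Hz powerline.

    ``band_power`` maps band name to PSD level in uV^2/Hz (band variance =
    level x bandwidth).  ``eog_mixing_gain`` is a scalar applied to both
    ocular traces on every channel, or an array of shape (27,) or (27, 2)
    for per-channel (vertical, horizontal) gains.  ``channel_band_scale``
    optionally boosts specific (channel, band) cells, e.g. theta on
    C3/Cz/T7 only.
    """
    if set(channel_labels) != set(EEG_MONTAGE) or len(channel_labels) != 27:
        raise ValueError("channel labels must match the 27-electrode montage")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    veog, heog = eog_gt["veog"], eog_gt["heog"]
    gains = np.asarray(eog_mixing_gain, dtype=float)
    if gains.ndim == 0:
        gains = np.tile([float(gains), 0.5 * float(gains)], (27, 1))
    elif gains.ndim == 1:
        gains = np.column_stack([gains, 0.5 * gains])
    eeg = np.empty((27, n))
    clean = np.empty((27, n)) if return_clean else None
    for ci, label in enumerate(channel_labels):
        acc = np.zeros(n)
        for bname, (lo, hi) in EEG_BANDS.items():
            level = band_power[bname]
            if channel_band_scale and label in channel_band_scale:
                level *= channel_band_scale[label].get(bname, 1.0)
            acc += _band_noise(rng, n, fs, (lo, hi), level * (hi - lo))
        if clean is not None:
            clean[ci] = acc
        eeg[ci] = (acc + gains[ci, 0] * veog + gains[ci, 1] * heog
                   + powerline_amp_uV * np.sin(2 * np.pi * 50.0 * t))
    return eeg, clean


def synth_gad7(pre_total: float, post_total: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seven continuous item scores in [0, 3] summing to each total."""
    items = []
    for total in (pre_total, post_total):
        if not 0.0 <= total <= 21.0:
            raise ValueError(f"GAD-7 total {total} infeasible (0-21)")
        base = total / 7.0
        max_dev = min(base, 3.0 - base)
        e = rng.uniform(-1.0, 1.0, 7)
        e -= e.mean()
        peak = np.abs(e).max()
        if peak > 0 and max_dev > 0:
            e *= 0.9 * max_dev / peak
        else:
            e[:] = 0.0
        items.append(base + e)
    return items[0], items[1]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _draw_participant(pid: str, group: str, template: dict,
                      rng: np.random.Generator,
                      change_score: float) -> ParticipantSpec:
    hr = np.clip(template["hr_bpm"]
                 + rng.normal(0, BETWEEN_SD["hr_bpm"]), 40, 180)
    resp = np.clip(template["resp_brpm"]
                   + rng.normal(0, BETWEEN_SD["resp_brpm"]), 8, 28)
    tonic = max(0.5, template["tonic_level_uS"]
                + rng.normal(0, BETWEEN_SD["tonic_level_uS"]))
    roll = template["roll_noise_variance_dps2"] * float(
        np.exp(rng.normal(0, BETWEEN_SD["roll_rel"])))
    band_power = {b: v * float(np.exp(rng.normal(0, BETWEEN_SD["eeg_rel"])))
                  for b, v in template["eeg_band_power"].items()}
    pre_total = rng.uniform(1.0, 3.0)
    post_total = min(21.0, pre_total + 7.0 * change_score)
    return ParticipantSpec(
        id=pid, group=group, hr_bpm=float(hr), resp_brpm=float(resp),
        tonic_level_uS=float(tonic), tonic_slope_uS_per_s=0.0,
        tonic_drift_amp_uS=0.2, phasic_event_rate_per_min=3.0,
        roll_noise_variance_dps2=float(roll),
        eeg_band_power=band_power,
        gad7_pre=float(pre_total), gad7_post=float(post_total),
    )


def _synth_recording(spec: ParticipantSpec, duration_s: float,
                     rates: dict[str, float],
                     rng: np.random.Generator) -> Recording:
    streams: dict[str, Stream] = {}
    gt: dict = {"group": spec.group}

    ecg, beats = synth_ecg(spec.hr_bpm, spec.hr_jitter_sd_ms, duration_s,
                           rates["ecg"], rng)
    streams["ecg"] = Stream("ecg", rates["ecg"], 0.0,
                            ["ecg1", "ecg2"], ecg)
    gt["beat_times"] = beats

    eda, eda_gt = synth_eda(spec.tonic_level_uS, spec.tonic_slope_uS_per_s,
                            spec.phasic_event_rate_per_min, duration_s,
                            rates["gsr"], rng,
                            drift_amp_uS=spec.tonic_drift_amp_uS)
    streams["gsr"] = Stream("gsr", rates["gsr"], 0.0, ["gsr"], eda)
    gt["tonic"] = eda_gt["tonic"]
    gt["phasic"] = eda_gt["phasic"]

    streams["resp"] = Stream(
        "resp", rates["resp"], 0.0, ["resp"],
        synth_resp(spec.resp_brpm, duration_s, rates["resp"], rng))

    streams["pupil"] = Stream(
        "pupil", rates["pupil"], 0.0, ["pupil_left", "pupil_right"],
        synth_pupil(spec.pupil_base_mm, spec.pupil_trend_mm_per_s,
                    duration_s, rates["pupil"], rng))

    streams["imu_roll"] = Stream(
        "imu_roll", rates["imu_roll"], 0.0, ["roll"],
        synth_imu_roll(spec.roll_noise_variance_dps2, duration_s,
                       rates["imu_roll"], rng))

    eog_elec, eog_gt = synth_eog(duration_s, rates["eog"], rng)
    streams["eog"] = Stream("eog", rates["eog"], 0.0,
                            ["veog_up", "veog_down", "heog_l", "heog_r"],
                            eog_elec)
    gt["veog"] = eog_gt["veog"]
    gt["heog"] = eog_gt["heog"]

    eeg, _ = synth_eeg(spec.eeg_band_power, eog_gt, spec.eog_mixing_gain,
                       spec.powerline_amp_uV, duration_s, rates["eeg"], rng)
    streams["eeg"] = Stream("eeg", rates["eeg"], 0.0, list(EEG_MONTAGE), eeg)
    gt["band_power"] = spec.eeg_band_power

    pre, post = synth_gad7(spec.gad7_pre, spec.gad7_post, rng)
    meta = {
        "group": spec.group,
        "hr_bpm": spec.hr_bpm,
        "resp_brpm": spec.resp_brpm,
        "tonic_level_uS": spec.tonic_level_uS,
        "roll_noise_variance_dps2": spec.roll_noise_variance_dps2,
    }
    return Recording(spec.id, streams, pre, post, meta, gt)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate the full synthetic cohort, deterministic given the seed.

    Group sizes follow the study design: ``ceil(n/2)`` anxious (9 of 17 by
    default) and the rest non-anxious.  Questionnaire change scores are
    drawn all-distinct, with every anxious change above every non-anxious
    change, so a median split recovers the generating groups exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    n_anx = (n + 1) // 2
    groups = ["anxious"] * n_anx + ["non_anxious"] * (n - n_anx)
    # distinct, well-separated change scores (mean-item units)
    while True:
        anx_changes = rng.uniform(0.9, 2.2, n_anx)
        non_changes = rng.uniform(0.1, 0.7, n - n_anx)
        allc = np.concatenate([anx_changes, non_changes])
        if len(np.unique(allc)) == n:
            break
    recs = []
    for i, group in enumerate(groups):
        pid = f"p{i + 1:02d}"
        pspec = _draw_participant(pid, group,
                                  spec.group_templates[group], rng, allc[i])
        recs.append(_synth_recording(pspec, spec.duration_s,
                                     spec.native_rates, rng))
    return recs


def cohort_with_overrides(spec: CohortSpec, **participant_overrides
                          ) -> list[Recording]:
    """Like :func:`generate_cohort` but forcing participant parameters.

    Used for parameter-recovery studies where every participant must share
    one exact generator setting (e.g. a fixed heart rate).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    n_anx = (n + 1) // 2
    groups = ["anxious"] * n_anx + ["non_anxious"] * (n - n_anx)
    recs = []
    for i, group in enumerate(groups):
        pid = f"p{i + 1:02d}"
        base = _draw_participant(pid, group, spec.group_templates[group],
                                 rng, 1.0 if group == "anxious" else 0.3)
        pspec = replace(base, **participant_overrides)
        recs.append(_synth_recording(pspec, spec.duration_s,
                                     spec.native_rates, rng))
    return recs
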
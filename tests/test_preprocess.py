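"""Filters, derivations, referencing and the full preprocessing chain."""

import numpy as np
import pytest

from anxsig.features import welch_psd
from anxsig.io_sync import resample_to_common
from anxsig.preprocess import (
    DEFAULT_FILTERS, EEG_MONTAGE, FilterSpec, common_average_reference,
    derive_bipolar, preprocess_recording, regress_out_eog,
    rereference_to_mastoids, zero_phase_filter,
)


class TestZeroPhaseFilter:
    def test_lowpass_dc_gain_unity(self):
        x = np.full(50000, 8.099)
        out = zero_phase_filter(x, FilterSpec("lowpass", (0.05,)), 500.0)
        np.testing.assert_allclose(out, 8.099, rtol=1e-6)

    def test_highpass_dc_gain_zero(self):
        x = np.full(50000, 8.099)
        out = zero_phase_filter(x, FilterSpec("highpass", (0.05,)), 500.0)
        assert np.abs(out[10000:-10000]).max() < 0.05

    def test_bandpass_passband_gain(self):
        t = np.arange(0, 600, 1 / 100)
        x = np.sin(2 * np.pi * 0.25 * t)
        out = zero_phase_filter(x, FilterSpec("bandpass", (0.1, 0.5)),
                                100.0)
        mid = out[len(out) // 4: -len(out) // 4]
        assert abs(mid.max() - 1.0) < 0.05

    def test_zero_phase_time_reversal_symmetry(self, rng):
        x = rng.normal(size=30000)
        spec = FilterSpec("bandpass", (2.0, 30.0))
        fwd = zero_phase_filter(x, spec, 500.0)
        rev = zero_phase_filter(x[::-1], spec, 500.0)[::-1]
        # identical once the low-edge boundary transient (~2 Hz) has decayed
        np.testing.assert_allclose(fwd[5000:-5000], rev[5000:-5000],
                                   atol=1e-6)

    def test_zero_lag_impulse_alignment(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        out = zero_phase_filter(x, FilterSpec("lowpass", (30.0,)), 500.0)
        assert np.argmax(out) == 2000

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            zero_phase_filter(np.zeros(100), FilterSpec("lowpass", (50.0,)),
                              100.0)


class TestDerivations:
    def test_identical_channels_cancel(self, rng):
        a = rng.normal(size=100)
        np.testing.assert_array_equal(derive_bipolar(a, a), 0.0)

    def test_common_mode_removed_exactly(self, rng):
        s, c = rng.normal(size=100), rng.normal(size=100)
        np.testing.assert_allclose(derive_bipolar(s + c, c), s)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            derive_bipolar(np.zeros(5), np.zeros(6))

    def test_ecg_difference_recovers_qrs_train(self, rng):
        from anxsig.synth import synth_ecg
        ecg, beats = synth_ecg(70.0, 20.0, 30.0, 500.0, rng)
        diff = derive_bipolar(ecg[0], ecg[1])
        t = np.arange(len(diff)) / 500.0
        template = np.zeros_like(diff)
        for tb in beats:
            template += np.exp(-0.5 * ((t - tb) / 0.008) ** 2)
        assert np.corrcoef(diff, template)[0, 1] > 0.9


class TestRereference:
    def _eeg(self, rng):
        return rng.normal(size=(27, 500)), list(EEG_MONTAGE)

    def test_27_to_25_channels(self, rng):
        data, labels = self._eeg(rng)
        out, labels25 = rereference_to_mastoids(data, labels)
        assert out.shape[0] == 25
        assert "TP9" not in labels25 and "TP10" not in labels25

    def test_zero_mastoids_leave_channels_unchanged(self, rng):
        data, labels = self._eeg(rng)
        data[labels.index("TP9")] = 0.0
        data[labels.index("TP10")] = 0.0
        out, labels25 = rereference_to_mastoids(data, labels)
        keep = [i for i, lab in enumerate(labels) if lab in labels25]
        np.testing.assert_allclose(out, data[keep])

    def test_constant_montage_becomes_zero(self):
        data = np.full((27, 100), 4.2)
        out, _ = rereference_to_mastoids(data, list(EEG_MONTAGE))
        np.testing.assert_allclose(out, 0.0)

    def test_missing_mastoid_rejected(self, rng):
        labels = [lab if lab != "TP9" else "XX" for lab in EEG_MONTAGE]
        with pytest.raises(ValueError, match="TP9"):
            rereference_to_mastoids(rng.normal(size=(27, 10)), labels)


class TestEOGRegression:
    def test_known_contamination_removed(self, rng):
        n = 30000
        clean = rng.normal(size=n)
        veog = rng.normal(size=n)
        heog = rng.normal(size=n)
        eeg = (clean + 0.3 * veog)[None, :]
        out = regress_out_eog(eeg, veog, heog)[0]
        assert abs(np.corrcoef(out, veog)[0, 1]) < 0.01
        assert np.corrcoef(out, clean)[0, 1] > 0.99

    def test_zero_variance_eog_passes_through(self, rng):
        eeg = rng.normal(size=(3, 100))
        with pytest.warns(UserWarning, match="zero variance"):
            out = regress_out_eog(eeg, np.zeros(100), np.zeros(100))
        np.testing.assert_array_equal(out, eeg)

    def test_only_contaminated_channel_changes(self, rng):
        n = 30000
        eeg = rng.normal(size=(5, n))
        veog = rng.normal(size=n)
        eeg[2] += 0.5 * veog
        out = regress_out_eog(eeg, veog, rng.normal(size=n))
        deltas = np.linalg.norm(out - eeg, axis=1) / np.sqrt(n)
        assert deltas[2] > 0.4
        assert np.all(deltas[[0, 1, 3, 4]] < 0.05)


class TestCAR:
    def test_identical_channels_zeroed(self):
        x = np.tile(np.arange(10.0), (4, 1))
        np.testing.assert_allclose(common_average_reference(x), 0.0)

    def test_columnwise_mean_exactly_zero(self, rng):
        out = common_average_reference(rng.normal(size=(25, 1000)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        x = rng.normal(size=(8, 100))
        once = common_average_reference(x)
        np.testing.assert_allclose(common_average_reference(once), once)


class TestFullChain:
    def test_processed_stream_contract(self, long_recording):
        proc = preprocess_recording(long_recording)
        assert set(proc.streams) == {"hr_raw", "tonic", "phasic", "pupil",
                                     "resp", "roll", "eeg25"}
        for s in proc.streams.values():
            assert s.fs == 100.0
            assert s.n_samples == 30000
        assert proc.streams["eeg25"].n_channels == 25

    def test_missing_stream_named_in_error(self, long_recording):
        broken = type(long_recording)(
            long_recording.participant_id,
            {k: v for k, v in long_recording.streams.items() if k != "resp"},
            long_recording.gad7_pre, long_recording.gad7_post)
        with pytest.raises(ValueError, match="resp"):
            preprocess_recording(broken)

    def test_notch_suppresses_powerline_by_20db(self, long_recording):
        x = long_recording.streams["eeg"].samples[0]
        bp = zero_phase_filter(x, DEFAULT_FILTERS["eeg_band"], 500.0)
        nt = zero_phase_filter(bp, DEFAULT_FILTERS["eeg_notch"], 500.0)
        f, p_before = welch_psd(bp, 500.0)
        _, p_after = welch_psd(nt, 500.0)
        i50 = np.argmin(np.abs(f - 50.0))
        assert 10 * np.log10(p_before[i50] / p_after[i50]) >= 20.0

    def test_tonic_plus_phasic_complementarity(self, long_recording):
        proc = preprocess_recording(long_recording)
        gsr100 = resample_to_common(long_recording.streams["gsr"])
        total = (proc.streams["tonic"].samples[0]
                 + proc.streams["phasic"].samples[0])
        mid = slice(3000, 27000)
        r = np.corrcoef(gsr100.samples[0, mid], total[mid])[0, 1]
        assert r > 0.99

    def test_tonic_phasic_spectral_split(self, rng):
        # broadband input: tonic keeps energy below 0.1 Hz, phasic above
        x = rng.normal(size=150000)
        tonic = zero_phase_filter(x, DEFAULT_FILTERS["tonic"], 500.0)
        phasic = zero_phase_filter(x, DEFAULT_FILTERS["phasic"], 500.0)
        f, pt = welch_psd(tonic, 500.0, bin_width=1 / 120)
        _, pp = welch_psd(phasic, 500.0, bin_width=1 / 120)
        assert pt[f > 0.1].sum() / pt.sum() < 0.05
        assert pp[(f < 0.025) & (f > 0)].sum() / pp.sum() < 0.05

    def test_eeg_residual_decorrelated_from_eog(self, long_recording):
        from anxsig.io_sync import Stream
        proc = preprocess_recording(long_recording)
        eeg = proc.streams["eeg25"].samples
        for key in ("veog", "heog"):
            trace = np.asarray(long_recording.ground_truth[key])
            t100 = resample_to_common(
                Stream(key, 500.0, 0.0, [key], trace)).samples[0]
            r = np.abs([np.corrcoef(ch, t100)[0, 1] for ch in eeg])
            assert r.max() < 0.05
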
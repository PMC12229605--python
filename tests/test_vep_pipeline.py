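"""Filtering, epoching, difference waves and component measurement."""

import math

import numpy as np
import pandas as pd
import pytest

import sketchvep as sv
from sketchvep.synthetic_data import CHANNELS


def _make_session(data, onsets=None):
    onsets = [1000] if onsets is None else onsets
    events = pd.DataFrame({
        "sample": onsets,
        "kind": ["single"] * len(onsets),
        "field": ["upper"] * len(onsets),
        "snr": [0] * len(onsets),
        "afc_high_snr": [pd.NA] * len(onsets),
        "afc_high_field": [None] * len(onsets),
        "isi_ms": [750.0] * len(onsets),
        "duration_ms": [25.0] * len(onsets),
    })
    return sv.EEGSession(sfreq=500.0, ch_names=CHANNELS, data=data,
                         events=events)


class TestPreprocess:
    def test_common_average_reference(self, quiet_session):
        out = sv.preprocess(quiet_session)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_line_noise_attenuated_20db(self):
        t = np.arange(20000) / 500.0
        tone = np.sin(2 * np.pi * 50 * t)
        data = np.tile(tone, (30, 1))
        data[0] *= -29.0  # break the common average so CAR keeps the tone
        out = sv.preprocess(_make_session(data))
        mid = slice(8000, 12000)  # away from edge transients
        in_rms = np.sqrt((data[0, mid] ** 2).mean())
        out_rms = np.sqrt((out.data[0, mid] ** 2).mean())
        assert out_rms < in_rms / 10  # >= 20 dB

    def test_dc_removed(self):
        data = np.full((30, 20000), 7.0)
        data[0] = -7.0 * 29  # non-zero after CAR
        out = sv.preprocess(_make_session(data))
        assert np.abs(out.data[:, 8000:12000]).max() < 0.2

    def test_zero_phase_pulse_latency(self):
        data = np.zeros((30, 20000))
        pulse = np.exp(-0.5 * ((np.arange(20000) - 10000) / 10) ** 2)
        data[0] = pulse * 30  # CAR leaves 29/30 of it on channel 0
        out = sv.preprocess(_make_session(data))
        assert abs(int(np.argmax(out.data[0])) - 10000) <= 1

    def test_missing_cluster_channel_rejected(self, quiet_session):
        params = sv.PreprocessParams(cluster=("POz", "NoSuchChannel"))
        with pytest.raises(ValueError, match="NoSuchChannel"):
            sv.preprocess(quiet_session, params)


class TestEpoching:
    def test_constant_signal_zeroed_by_baseline(self):
        data = np.full((30, 4000), 3.5)
        epochs = sv.epoch_and_baseline(_make_session(data, [2000]))
        assert np.allclose(epochs.data, 0.0)
        assert len(epochs.info) == 1

    def test_epoch_count_bookkeeping(self, quiet_session):
        epochs = sv.epoch_and_baseline(quiet_session)
        n_single = (quiet_session.events["kind"] == "single").sum()
        n_afc = (quiet_session.events["kind"] == "afc").sum()
        assert epochs.drop_log["afc"] == n_afc
        dropped = sum(epochs.drop_log.values()) - n_afc
        assert len(epochs.info) == n_single - dropped

    def test_planted_gaps_are_dropped(self, quiet_session):
        sess = sv.EEGSession(
            sfreq=quiet_session.sfreq, ch_names=quiet_session.ch_names,
            data=quiet_session.data.copy(), events=quiet_session.events,
        )
        singles = sess.events[sess.events["kind"] == "single"]
        for s in singles["sample"].iloc[[3, 10]]:
            sess.data[:, s + 10 : s + 14] = np.nan
        epochs = sv.epoch_and_baseline(sess)
        assert epochs.drop_log["missing_signal"] == 2
        assert len(epochs.info) == len(singles) - 2

    def test_amplitude_rejection(self, quiet_session):
        sess = sv.EEGSession(
            sfreq=quiet_session.sfreq, ch_names=quiet_session.ch_names,
            data=quiet_session.data.copy(), events=quiet_session.events,
        )
        singles = sess.events[sess.events["kind"] == "single"]
        s = int(singles["sample"].iloc[0])
        poz = sess.ch_names.index("POz")
        sess.data[poz, s + 20] += 400.0  # artifact spike on a cluster channel
        epochs = sv.epoch_and_baseline(sess)
        assert epochs.drop_log["amplitude"] == 1

    def test_edge_trial_dropped(self):
        data = np.zeros((30, 500))
        epochs_err = None
        sess = _make_session(data, [30, 250])  # first too close to the start
        epochs = sv.epoch_and_baseline(sess)
        assert epochs.drop_log["edge"] == 1
        assert len(epochs.info) == 1


class TestVEPAveraging:
    def test_single_epoch_equals_lowpassed_cluster_mean(self, quiet_session):
        epochs = sv.epoch_and_baseline(quiet_session)
        sub = sv.Epochs(data=epochs.data[:1], times=epochs.times,
                        info=epochs.info.iloc[:1], ch_names=epochs.ch_names,
                        sfreq=epochs.sfreq)
        snr = int(sub.info["snr"].iloc[0])
        fld = sub.info["field"].iloc[0]
        vep = sv.compute_vep(sub, (snr, fld))
        from scipy import signal
        cluster = [epochs.ch_names.index(ch) for ch in sv.CLUSTER]
        sos = signal.butter(4, 35.0, fs=500.0, output="sos")
        expected = signal.sosfiltfilt(sos, epochs.data[0, cluster].mean(axis=0))
        assert np.allclose(vep.values, expected)

    def test_empty_condition_rejected(self, quiet_session):
        epochs = sv.epoch_and_baseline(quiet_session)
        with pytest.raises(ValueError, match="no epochs"):
            sv.compute_vep(epochs, (0, "nowhere"))


class TestDifferenceWave:
    @staticmethod
    def _vep(values):
        t = np.arange(-75, 151) / 500.0
        return sv.VEP(t, np.asarray(values, dtype=float))

    def test_identical_inputs_cancel(self):
        t = np.arange(-75, 151) / 500.0
        v = self._vep(np.sin(t * 20))
        assert np.allclose(sv.difference_wave(v, v).values, 0.0)

    def test_planted_opposite_c1_superposes(self):
        t = np.arange(-75, 151) / 500.0
        bump = 2.0 * np.exp(-0.5 * ((t - 0.072) / 0.010) ** 2)
        diff = sv.difference_wave(self._vep(bump), self._vep(-bump))
        m = sv.measure_component(diff, "C1")
        assert m.detected
        assert m.amplitude_uv == pytest.approx(4.0, rel=1e-6)
        assert m.latency_s == pytest.approx(0.072, abs=5e-4)

    def test_common_signal_cancels(self):
        t = np.arange(-75, 151) / 500.0
        a, b = np.sin(20 * t), np.cos(17 * t)
        c = np.exp(-t)
        d1 = sv.difference_wave(self._vep(a + c), self._vep(b + c))
        d2 = sv.difference_wave(self._vep(a), self._vep(b))
        assert np.allclose(d1.values, d2.values)

    def test_grid_mismatch_rejected(self):
        a = self._vep(np.zeros(226))
        b = sv.VEP(a.times + 0.002, a.values)
        with pytest.raises(ValueError, match="time grid"):
            sv.difference_wave(a, b)


class TestMeasureComponent:
    T = np.arange(-75, 151) / 500.0

    def test_flat_signal_not_detected(self):
        m = sv.measure_component(sv.VEP(self.T, np.zeros_like(self.T)), "C1")
        assert not m.detected and math.isnan(m.latency_s)

    def test_gaussian_closed_forms(self):
        v = 1.0 * np.exp(-0.5 * ((self.T - 0.070) / 0.010) ** 2)
        m = sv.measure_component(sv.VEP(self.T, v), "C1")
        assert m.detected
        assert abs(m.latency_s - 0.070) <= 5e-4
        assert m.width_s == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 0.010,
                                          rel=0.01)
        assert m.onset_s == pytest.approx(0.070 - 1.1774 * 0.010, abs=5e-4)
        assert m.amplitude_uv == pytest.approx(1.0, rel=0.01)
        assert m.prominence_uv == pytest.approx(1.0, rel=0.01)

    def test_raised_cosine_closed_forms(self):
        t0, w, amp = 0.068, 0.030, 1.5
        v = np.where(np.abs(self.T - t0) <= w,
                     amp / 2 * (1 + np.cos(np.pi * (self.T - t0) / w)), 0.0)
        m = sv.measure_component(sv.VEP(self.T, v), "C1")
        assert abs(m.latency_s - t0) <= 5e-4
        assert m.width_s == pytest.approx(w, rel=0.01)  # FWHM of raised cosine
        assert m.onset_s == pytest.approx(t0 - w / 2, abs=1e-3)
        assert m.amplitude_uv == pytest.approx(amp, rel=0.01)

    def test_subthreshold_bump_not_detected(self):
        v = 0.15 * np.exp(-0.5 * ((self.T - 0.070) / 0.010) ** 2)
        assert not sv.measure_component(sv.VEP(self.T, v), "C1").detected

    def test_c2_is_negative_peak_in_late_window(self):
        v = -1.2 * np.exp(-0.5 * ((self.T - 0.130) / 0.015) ** 2)
        m = sv.measure_component(sv.VEP(self.T, v), "C2")
        assert m.detected
        assert m.latency_s == pytest.approx(0.130, abs=5e-4)
        assert m.amplitude_uv == pytest.approx(-1.2, rel=0.01)

    def test_peak_outside_window_ignored(self):
        v = 1.0 * np.exp(-0.5 * ((self.T - 0.150) / 0.010) ** 2)
        assert not sv.measure_component(sv.VEP(self.T, v), "C1").detected

    def test_short_waveform_rejected(self):
        t = np.arange(0, 30) / 500.0
        with pytest.raises(ValueError, match="window"):
            sv.measure_component(sv.VEP(t, np.zeros_like(t)), "C1")


class TestExclusion:
    @staticmethod
    def _measures(detected_by_pid):
        rows = []
        for pid, flags in detected_by_pid.items():
            for snr, det in zip((0, 30, 60, 100), flags):
                rows.append({"participant": pid, "snr": snr,
                             "component": "C1", "detected": det})
        return pd.DataFrame(rows)

    def test_all_detected_included(self):
        inc, exc = sv.apply_exclusion(self._measures({"p1": [1, 1, 1, 1]}))
        assert inc == ["p1"] and exc == []

    def test_three_of_four_excluded(self):
        inc, exc = sv.apply_exclusion(
            self._measures({"p1": [1, 1, 1, 0], "p2": [1, 1, 1, 1]}))
        assert inc == ["p2"] and exc == ["p1"]

    def test_missing_condition_rejected(self):
        bad = self._measures({"p1": [1, 1, 1, 1]}).iloc[:3]
        with pytest.raises(ValueError, match="missing"):
            sv.apply_exclusion(bad)


def test_default_simulations_rarely_excluded():
    """Planted C1 is far above the 0.2 uV floor, so exclusions are rare."""
    measures = sv.run_synthetic_study(
        n_participants=6, seed=123,
        schedule_config=sv.scaled_schedule_config(10))
    included, excluded = sv.apply_exclusion(measures)
    assert len(included) >= 5
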
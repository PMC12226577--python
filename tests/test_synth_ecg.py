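"""Simulator contracts: determinism, subject distinctness, HF content,
beat timing, noise validation and cohort protocol shape."""

import numpy as np
import pytest
from scipy import signal

from doorecg.synth_ecg import (
    DISPO_NOISE,
    DOOR_NOISE,
    ECGRecord,
    HFAtom,
    NoiseModel,
    SessionSpec,
    make_subject_template,
    read_cohort,
    simulate_cohort,
    simulate_recording,
    write_cohort,
)


def peak_normalized_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    c = np.correlate(a, b, mode="full")
    return float(np.max(np.abs(c)) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


class TestSubjectTemplate:
    def test_deterministic_by_seed(self):
        t1 = make_subject_template(1)
        t2 = make_subject_template(1)
        np.testing.assert_array_equal(t1.beat_waveform, t2.beat_waveform)
        assert t1.hf_atoms == t2.hf_atoms

    def test_unique_r_maximum(self, template1):
        w = template1.beat_waveform
        assert np.sum(w == w.max()) == 1
        assert w[template1.r_index] == template1.nominal_r_amplitude

    def test_templates_differ_between_seeds(self, template1, template2):
        r = peak_normalized_xcorr(template1.beat_waveform, template2.beat_waveform)
        assert r < 0.99

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_hf_band_energy_fraction(self, seed):
        """>=5 % of the above-40 Hz residual energy sits in 40-150 Hz."""
        t = make_subject_template(seed)
        sos = signal.butter(4, 40.0, btype="lowpass", fs=t.fs, output="sos")
        residual = t.beat_waveform - signal.sosfiltfilt(sos, t.beat_waveform)
        f, pxx = signal.periodogram(residual, fs=t.fs)
        band = (f >= 40) & (f <= 150)
        assert pxx[band].sum() / pxx.sum() >= 0.05

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_qrs_support_under_120ms(self, seed):
        """The high-frequency content is confined to a <120 ms QRS window."""
        t = make_subject_template(seed)
        hf = t.hf_waveform
        energy = hf**2
        win = int(0.060 * t.fs)
        r = int(np.argmax(t.beat_waveform))
        inside = energy[r - win : r + win].sum()
        assert inside / energy.sum() > 0.9

    def test_atom_frequency_band_enforced(self):
        with pytest.raises(ValueError):
            HFAtom(center=0, freq=200.0, amp=0.1, width=10, phase=0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            make_subject_template(1, fs=250)


class TestSimulateRecording:
    def test_zero_hr_variability_exact_rr(self, template1):
        rec = simulate_recording(template1, 20.0, 60.0, 0.0, NoiseModel(), seed=0)
        assert abs(len(rec.true_r_peaks) - 20) <= 1
        assert np.all(np.diff(rec.true_r_peaks) == 1000)

    def test_noiseless_r_amplitude(self, template1):
        scale = 1.3
        rec = simulate_recording(
            template1, 10.0, 60.0, 0.0, NoiseModel(amplitude_scale=scale), seed=0
        )
        np.testing.assert_allclose(
            rec.samples[rec.true_r_peaks],
            template1.nominal_r_amplitude * scale,
            rtol=1e-10,
        )

    def test_deterministic_by_seed(self, template1):
        r1 = simulate_recording(template1, 20.0, 72.0, 3.0, seed=42)
        r2 = simulate_recording(template1, 20.0, 72.0, 3.0, seed=42)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        np.testing.assert_array_equal(r1.true_r_peaks, r2.true_r_peaks)

    @pytest.mark.parametrize("mean_hr,hr_sd", [(60, 0), (72, 3), (88, 5), (120, 5)])
    def test_beat_count_conservation(self, template1, mean_hr, hr_sd):
        rec = simulate_recording(template1, 20.0, mean_hr, hr_sd, seed=3)
        assert abs(len(rec.true_r_peaks) - 20 * mean_hr / 60) <= 3

    def test_invalid_inputs_rejected(self, template1):
        with pytest.raises(ValueError):
            simulate_recording(template1, -1.0, 60.0)
        with pytest.raises(ValueError):
            simulate_recording(template1, 20.0, 20.0)
        with pytest.raises(ValueError):
            NoiseModel(white_sd=-0.1)
        with pytest.raises(ValueError):
            NoiseModel(amplitude_scale=0.0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ECGRecord(samples=np.array([np.nan]), fs=1000.0, subject_id="x")
        with pytest.raises(ValueError):
            ECGRecord(
                samples=np.zeros(10), fs=1000.0, subject_id="x",
                true_r_peaks=np.array([5, 5]),
            )

    def test_door_noisier_than_dispo(self, template1):
        """Template-referenced SNR of door recordings <= dispo recordings."""
        clean = simulate_recording(template1, 20.0, 72.0, 3.0, NoiseModel(), seed=5)
        snr = {}
        for name, preset in [("dispo", DISPO_NOISE), ("door", DOOR_NOISE)]:
            rec = simulate_recording(template1, 20.0, 72.0, 3.0, preset, seed=5)
            resid = rec.samples - clean.samples
            snr[name] = np.var(clean.samples) / np.var(resid)
        assert snr["door"] < snr["dispo"]


class TestSimulateCohort:
    def test_protocol_shape(self):
        recs = simulate_cohort(10, seed=0)  # default: one session of 5 x 20 s
        assert len(recs) == 50
        per_subject = {}
        for r in recs:
            per_subject[r.subject_id] = per_subject.get(r.subject_id, 0) + 1
        assert set(per_subject.values()) == {5}

    def test_min_subjects(self):
        with pytest.raises(ValueError):
            simulate_cohort(1)

    def test_subjects_have_distinct_waveforms(self):
        sessions = [SessionSpec(noise=NoiseModel(), n_records=1)]
        recs = simulate_cohort(2, sessions=sessions, seed=3)
        a, b = (r.samples for r in recs)
        n = min(len(a), len(b))
        assert peak_normalized_xcorr(a[:n], b[:n]) < 0.99

    def test_different_day_changes_only_gain(self):
        sessions = [
            SessionSpec(name="day1", noise=NoiseModel(), n_records=1),
            SessionSpec(name="day2", noise=NoiseModel(), n_records=1, different_day=True),
        ]
        recs = simulate_cohort(2, sessions=sessions, seed=9)
        by = {(r.subject_id, r.session): r for r in recs}
        for sid in ("S00", "S01"):
            d1, d2 = by[(sid, "day1")], by[(sid, "day2")]
            amp1 = d1.samples[d1.true_r_peaks]
            amp2 = d2.samples[d2.true_r_peaks]
            gain = amp2.mean() / amp1.mean()
            assert gain != pytest.approx(1.0)
            # same template: day-2 divided by its gain matches day-1 R amplitude
            np.testing.assert_allclose(amp2 / gain, amp1.mean(), rtol=1e-6)

    def test_cohort_deterministic(self):
        r1 = simulate_cohort(3, seed=4)
        r2 = simulate_cohort(3, seed=4)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_unknown_session_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown subjects"):
            simulate_cohort(2, sessions=[SessionSpec(subjects=("S99",))])


class TestCohortIO:
    def test_roundtrip(self, tmp_path):
        recs = simulate_cohort(2, sessions=[SessionSpec(n_records=1, duration=5.0)], seed=1)
        write_cohort(recs, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == len(recs)
        orig = {r.record_id: r for r in recs}
        for r in back:
            o = orig[r.record_id]
            assert r.subject_id == o.subject_id
            assert r.electrode == o.electrode
            assert r.fs == o.fs
            np.testing.assert_array_equal(r.true_r_peaks, o.true_r_peaks)
            np.testing.assert_allclose(r.samples, o.samples, atol=1e-6)
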
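"""Synthetic-session generators: determinism, ground-truth recovery, bounds."""

import numpy as np
import pytest

from therasig.core import central_window
from therasig.eeg import compute_band_power, period_summary
from therasig.synth import (
    AutonomicProfile,
    EEGEffectProfile,
    EMGProfile,
    ProfileError,
    gen_clinical_table,
    gen_ecg_session,
    gen_eeg_session,
    gen_emg_session,
)


class TestDeterminism:
    def test_eeg_fixed_seed(self):
        p = EEGEffectProfile()
        a, _ = gen_eeg_session(p, durations=(10, 10, 10), fs=256, seed=9)
        b, _ = gen_eeg_session(p, durations=(10, 10, 10), fs=256, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_ecg_fixed_seed(self):
        p = AutonomicProfile()
        a = gen_ecg_session(p, durations=(20, 20, 20), fs=256, seed=3, noise_sd=0.05)
        b = gen_ecg_session(p, durations=(20, 20, 20), fs=256, seed=3, noise_sd=0.05)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[2], b[2])

    def test_clinical_fixed_seed(self):
        a = gen_clinical_table(seed=5)
        b = gen_clinical_table(seed=5)
        assert a.equals(b)


class TestEEGGenerator:
    def test_band_power_multipliers_recovered(self):
        # requested multipliers are recovered through the analysis
        # pipeline within 10 % relative for 60-s periods
        profile = EEGEffectProfile(multipliers={
            ("O1", "Alpha"): {"MTI": 2.0}, ("Fp1", "Delta"): {"MTI": 0.5}})
        rec, seg = gen_eeg_session(profile, durations=(60, 60, 60), fs=256, seed=10)
        series = compute_band_power(rec, seg)
        labels = np.asarray(series.periods)
        mean_power = {p: series.power[labels == p].mean(axis=0)
                      for p in ("PRE", "MTI")}
        ci = {c: i for i, c in enumerate(series.channels)}
        bi = {b: i for i, b in enumerate(series.bands)}
        ratio_o1 = mean_power["MTI"][ci["O1"], bi["Alpha"]] / \
            mean_power["PRE"][ci["O1"], bi["Alpha"]]
        ratio_fp1 = mean_power["MTI"][ci["Fp1"], bi["Delta"]] / \
            mean_power["PRE"][ci["Fp1"], bi["Delta"]]
        assert ratio_o1 == pytest.approx(2.0, rel=0.10)
        assert ratio_fp1 == pytest.approx(0.5, rel=0.10)

    def test_null_profile_near_zero_z(self, null_eeg_session):
        rec, seg = null_eeg_session
        summ = period_summary(compute_band_power(rec, seg))
        mti = summ[summ.period == "MTI"]
        assert np.abs(mti.mean_z).mean() < 0.3

    def test_unknown_cell_rejected(self):
        with pytest.raises(ProfileError):
            EEGEffectProfile(multipliers={("Cz", "Alpha"): {"MTI": 2.0}})
        with pytest.raises(ProfileError, match="PRE"):
            EEGEffectProfile(multipliers={("O1", "Alpha"): {"PRE": 2.0}})

    def test_blinks_are_frontal(self):
        rec, _ = gen_eeg_session(EEGEffectProfile(), durations=(20, 20, 20),
                                 fs=256, seed=2, blinks=True, blink_amplitude=150.0)
        assert np.max(np.abs(rec.channel("Fp1"))) > 2 * np.max(np.abs(rec.channel("O1")))


class TestECGGenerator:
    def test_bounds_guard(self):
        with pytest.raises(ProfileError, match="excursion"):
            AutonomicProfile(mean_rr={p: 400.0 for p in ("PRE", "MTI", "POST")},
                             a_lf={p: 80.0 for p in ("PRE", "MTI", "POST")})

    def test_rr_stays_physiologic(self):
        prof = AutonomicProfile()
        _, _, peaks = gen_ecg_session(prof, durations=(60, 60, 60), fs=256, seed=4)
        rr = np.diff(peaks) * 1000
        assert rr.min() >= 300.0 and rr.max() <= 1500.0

    def test_detector_ground_truth_alignment_at_snr(self):
        prof = AutonomicProfile()
        rec, _, truth = gen_ecg_session(prof, durations=(60, 60, 60), fs=512,
                                        seed=6, noise_sd=0.1)  # 10:1 SNR
        from therasig.hrv import detect_r_peaks
        from therasig.preprocess import bandpass
        det = detect_r_peaks(bandpass(rec, 1.0, 40.0).data[0], 512.0)
        matched = sum(np.min(np.abs(det - t)) <= 0.010 for t in truth)
        assert matched / len(truth) >= 0.99
        assert len(det) <= len(truth) * 1.01


class TestEMGGenerator:
    def test_rms_targets_met(self):
        prof = EMGProfile(rms={"PRE": 5.0, "MTI": 12.0, "POST": 5.0})
        rec, seg = gen_emg_session(prof, durations=(30, 30, 30), fs=512, seed=7)
        win = central_window(seg["MTI"], 0.5)
        x = rec.extract(seg["MTI"])[0]
        assert np.sqrt(np.mean(x**2)) == pytest.approx(12.0, rel=1e-6)

    def test_gate(self):
        with pytest.raises(ValueError, match="512"):
            gen_emg_session(EMGProfile(), durations=(10, 10, 10), fs=256, seed=1)

    def test_centroid_validation(self):
        with pytest.raises(ProfileError):
            EMGProfile(centroid={"PRE": 10.0, "MTI": 100.0, "POST": 100.0})


class TestClinicalGenerator:
    def test_exact_uniform_shift(self):
        tab = gen_clinical_table(n_patients=20, vas_shift=-2.0, seed=8)
        change = tab["vas_post"] - tab["vas_pre"]
        assert change.mean() == pytest.approx(-2.0, abs=0.8)

    def test_missing_last_accounting(self):
        tab = gen_clinical_table(n_patients=9, missing_last_fraction=1 / 9,
                                 single_session_patients=1, seed=3)
        assert tab["patient_id"].nunique() == 9
        assert len(tab) == 17
        n_missing = tab.groupby("patient_id")["hads_anxiety_last"].first().isna().sum()
        assert n_missing == 1

    def test_minimum_patients(self):
        with pytest.raises(ValueError):
            gen_clinical_table(n_patients=1)

    def test_scores_in_range(self):
        tab = gen_clinical_table(n_patients=30, vas_shift=3.0,
                                 hads_anxiety_shift=-5.0, seed=4)
        assert tab["vas_post"].between(0, 10).all()
        assert tab["hads_anxiety_last"].dropna().between(0, 21).all()
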
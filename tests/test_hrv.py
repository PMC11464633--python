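"""R-peak detection, R-R cleaning, time/nonlinear/frequency HRV."""

import numpy as np
import pytest

from therasig.hrv import (
    NoPeaksError,
    RRQualityError,
    Tachogram,
    clean_rr,
    detect_r_peaks,
    hrv_session_summary,
    poincare,
    spectral_lf_hf,
    time_domain,
)
from therasig.synth import AutonomicProfile, gen_ecg_session


def _tach_from_rr(rr_ms, t0=0.2):
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(rr_ms) / 1000.0)])
    return Tachogram.from_peaks(times)


class TestDetector:
    def test_noiseless_recovery_within_one_sample(self):
        prof = AutonomicProfile()
        rec, _, truth = gen_ecg_session(prof, durations=(60, 60, 60), fs=256,
                                        seed=1, noise_sd=0.0)
        det = detect_r_peaks(rec.data[0], 256.0)
        assert len(det) == len(truth)
        assert np.max(np.abs(det - truth)) <= 1.0 / 256.0 + 1e-9

    def test_flat_signal_raises(self):
        with pytest.raises(NoPeaksError):
            detect_r_peaks(np.zeros(2560), 256.0)

    def test_flatline_segment_has_no_spurious_peaks(self):
        prof = AutonomicProfile()
        rec, _, _ = gen_ecg_session(prof, durations=(30, 30, 30), fs=256,
                                    seed=2, noise_sd=0.05)
        x = rec.data[0].copy()
        x[int(30 * 256): int(60 * 256)] = 0.0  # lead disconnection
        det = detect_r_peaks(x, 256.0)
        inside = det[(det > 31.0) & (det < 59.0)]
        assert inside.size == 0


class TestCleanRR:
    def test_all_valid_unchanged(self):
        tach = clean_rr(_tach_from_rr([800.0] * 10))
        assert tach.rr == pytest.approx(800.0) and not tach.interpolated.any()

    def test_single_outlier_interpolated(self):
        tach = clean_rr(_tach_from_rr([800, 800, 1600, 800, 800]))
        assert tach.rr[2] == pytest.approx(800.0)
        assert tach.interpolated.tolist() == [False, False, True, False, False]

    def test_invalid_run_linear_interp(self):
        tach = clean_rr(_tach_from_rr([800, 200, 1900, 800]),
                        max_invalid_fraction=0.6)
        assert tach.rr.tolist() == pytest.approx([800, 800, 800, 800])

    def test_count_preserved_and_idempotent(self):
        raw = _tach_from_rr([700, 1700, 750, 820, 790, 250, 810])
        cleaned = clean_rr(raw, max_invalid_fraction=0.5)
        assert len(cleaned.rr) == len(raw.rr)
        again = clean_rr(cleaned, max_invalid_fraction=0.5)
        assert np.allclose(again.rr, cleaned.rr)

    def test_quality_threshold(self):
        with pytest.raises(RRQualityError):
            clean_rr(_tach_from_rr([800, 1900, 1900, 1900, 800]))


class TestTimeDomain:
    def test_constant_series(self):
        out = time_domain(np.full(20, 800.0))
        assert out == {"meanRR": 800.0, "STDRR": 0.0, "pRR50": 0.0}

    def test_alternating_all_over_50(self):
        rr = np.tile([770.0, 830.0], 10)
        assert time_domain(rr)["pRR50"] == 100.0

    def test_successive_difference_oracle(self):
        # diffs 40, 10 -> none exceed 50 ms
        assert time_domain(np.array([800.0, 840.0, 850.0]))["pRR50"] == 0.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            time_domain(np.array([800.0]))


class TestPoincare:
    def test_constant_series_zero_dispersion(self):
        out, _ = poincare(np.full(10, 820.0), pre_mean=800.0, pre_sd=50.0)
        assert out["SD1"] == 0.0 and out["SD2"] == 0.0

    def test_iid_series_sd1_close_to_sd2(self, rng):
        rr = rng.normal(800, 40, 4000)
        out, _ = poincare(rr, 800.0, 40.0)
        assert out["SD1"] == pytest.approx(out["SD2"], rel=0.1)

    def test_sd1_equals_rmssd_identity(self, rng):
        rr = rng.normal(800, 40, 300)
        out, _ = poincare(rr, 805.0, 38.0)
        z = (rr - 805.0) / 38.0
        rmssd = np.sqrt(np.mean(np.diff(z) ** 2))
        assert out["SD1"] == pytest.approx(rmssd / np.sqrt(2), rel=1e-9)

    def test_variance_identity(self, rng):
        rr = rng.normal(800, 40, 512)
        out, _ = poincare(rr, 800.0, 40.0)
        z = (rr - 800.0) / 40.0
        assert out["SD1"]**2 + out["SD2"]**2 == pytest.approx(
            2 * np.var(z), rel=0.05)

    def test_degenerate_baseline(self):
        with pytest.raises(ValueError, match="degenerate"):
            poincare(np.full(10, 800.0), 800.0, 0.0)


class TestSpectral:
    @staticmethod
    def _oscillating_tach(a_lf, a_hf, seconds=300.0, mean=800.0,
                          f_lf=0.1, f_hf=0.25):
        times = [0.2]
        while times[-1] < seconds:
            t = times[-1]
            rr = (mean + a_lf * np.sin(2 * np.pi * f_lf * t)
                  + a_hf * np.sin(2 * np.pi * f_hf * t))
            times.append(t + rr / 1000.0)
        return Tachogram.from_peaks(np.asarray(times))

    def test_hf_sinusoid_concentrates(self):
        tach = self._oscillating_tach(0.0, 50.0)
        out = spectral_lf_hf(tach, (0.0, 300.0))
        assert out["HF"] / (out["LF"] + out["HF"]) >= 0.95

    def test_equal_amplitudes_unit_ratio(self):
        tach = self._oscillating_tach(40.0, 40.0)
        out = spectral_lf_hf(tach, (0.0, 300.0))
        assert out["LF/HF"] == pytest.approx(1.0, rel=0.10)

    def test_adaptive_cutoff_rule(self):
        # 240-s window -> f_low = 12/240 = 0.05 Hz (up to edge-anchor slack)
        tach = self._oscillating_tach(40.0, 40.0, seconds=245.0)
        out = spectral_lf_hf(tach, (0.0, 240.0))
        assert out["f_low"] == pytest.approx(0.05, abs=0.001)
        long = spectral_lf_hf(self._oscillating_tach(40.0, 40.0), (0.0, 300.0))
        assert long["f_low"] == pytest.approx(0.04, abs=1e-9)

    def test_percentages_bounded(self):
        tach = self._oscillating_tach(30.0, 30.0)
        out = spectral_lf_hf(tach, (0.0, 300.0))
        assert 0 <= out["LF"] and 0 <= out["HF"]
        assert out["LF"] + out["HF"] <= 100.0 + 1e-9

    def test_too_short_window(self):
        tach = self._oscillating_tach(30.0, 30.0, seconds=50.0)
        with pytest.raises(ValueError, match="short"):
            spectral_lf_hf(tach, (0.0, 50.0))


class TestSessionSummary:
    def test_hf_dominant_mti_pattern(self):
        prof = AutonomicProfile(
            mean_rr={"PRE": 800.0, "MTI": 800.0, "POST": 800.0},
            a_lf={"PRE": 45.0, "MTI": 10.0, "POST": 45.0},
            a_hf={"PRE": 10.0, "MTI": 45.0, "POST": 10.0},
            jitter_sd={"PRE": 5.0, "MTI": 5.0, "POST": 5.0},
        )
        rec, seg, _ = gen_ecg_session(prof, durations=(300, 300, 300), fs=256,
                                      seed=4, noise_sd=0.02)
        out = hrv_session_summary(rec, seg)
        d = out["deltas"]["MTI-PRE"]
        assert d["HF"] > 0 and d["LF"] < 0 and d["LF/HF"] < 0

    def test_identical_profiles_small_deltas_and_antisymmetry(self):
        prof = AutonomicProfile(jitter_sd={p: 5.0 for p in ("PRE", "MTI", "POST")})
        rec, seg, _ = gen_ecg_session(prof, durations=(120, 120, 120), fs=256,
                                      seed=5, noise_sd=0.02)
        out = hrv_session_summary(rec, seg)
        d = out["deltas"]
        assert abs(d["MTI-PRE"]["meanRR"]) < 20.0
        for feat in ("meanRR", "STDRR", "LF/HF"):
            lhs = d["MTI-PRE"][feat] + d["POST-PRE"][feat] * 0  # sign check below
            assert d["MTI-PRE"][feat] == pytest.approx(
                -(out["per_period"]["PRE"][feat] - out["per_period"]["MTI"][feat]))

    def test_constant_rr_zero_variability(self):
        prof = AutonomicProfile(
            a_lf={p: 0.0 for p in ("PRE", "MTI", "POST")},
            a_hf={p: 0.0 for p in ("PRE", "MTI", "POST")},
            jitter_sd={p: 0.0 for p in ("PRE", "MTI", "POST")},
        )
        rec, seg, _ = gen_ecg_session(prof, durations=(90, 90, 90), fs=256, seed=6)
        peaks = detect_r_peaks(rec.data[0], 256.0)
        tach = clean_rr(Tachogram.from_peaks(peaks))
        td = time_domain(tach.in_window((0.0, 90.0)))
        assert td["STDRR"] <= 2.0 and td["pRR50"] == 0.0
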
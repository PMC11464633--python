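"""Filters, artifact masks, and ocular-component removal."""

import numpy as np
import pytest

from therasig.core import Modality, Recording
from therasig.eeg import band_power, epoch_psd
from therasig.preprocess import (
    ArtifactMask,
    apply_artifact_mask,
    auto_artifact_mask,
    bandpass,
    epochs_surviving_mask,
    mask_from_recording,
    notch_comb,
    notch_frequencies,
    remove_ocular_component,
)
from therasig.synth import EEGEffectProfile, gen_eeg_session

FS = 256.0


def _rec(x, fs=FS, modality=Modality.ECG, labels=("ECG",)):
    return Recording(modality, labels, fs, np.atleast_2d(x))


def _sine(freq, fs=FS, seconds=20.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _mid_rms(x, fs=FS, trim_s=2.0):
    mid = x[int(trim_s * fs): -int(trim_s * fs)]
    return np.sqrt(np.mean(mid**2))


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass(_rec(np.full(int(20 * FS), 50.0)), 1.0, 30.0)
        assert np.max(np.abs(out.data[0][int(2 * FS):-int(2 * FS)])) < 1e-6 * 50.0

    def test_passband_amplitude_preserved(self):
        out = bandpass(_rec(_sine(10.0)), 1.0, 30.0)
        assert _mid_rms(out.data[0]) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_stopband_attenuation(self):
        out = bandpass(_rec(_sine(60.0)), 1.0, 30.0)
        ratio = _mid_rms(out.data[0]) / (1 / np.sqrt(2))
        assert 20 * np.log10(ratio) < -40.0

    def test_zero_phase_no_lag(self):
        x = _sine(8.0, seconds=10.0)
        y = bandpass(_rec(x), 1.0, 30.0).data[0]
        lags = np.arange(-20, 21)
        xc = [np.dot(x[50:-50], np.roll(y, k)[50:-50]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_rec(_sine(10.0)), 1.0, 200.0)


class TestNotch:
    def test_line_frequency_rejected(self):
        rec = _rec(_sine(60.0, fs=512.0), fs=512.0)
        out = notch_comb(rec, base=60.0, up_to=200.0)
        assert _mid_rms(out.data[0], fs=512.0) < 0.03 / np.sqrt(2)

    def test_off_notch_preserved(self):
        rec = _rec(_sine(100.0, fs=512.0), fs=512.0)
        out = notch_comb(rec, base=60.0, up_to=200.0)
        assert _mid_rms(out.data[0], fs=512.0) == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_harmonic_ladder(self):
        assert notch_frequencies(60.0, 512.0, 200.0) == [60.0, 120.0, 180.0]


class TestArtifactMask:
    def test_empty_mask_is_noop(self):
        rec = _rec(_sine(5.0))
        out = apply_artifact_mask(rec, ArtifactMask(()))
        assert np.array_equal(out.data, rec.data)

    def test_epoch_overlap_enumeration(self):
        # 3-s bad span starting at 4 s; 3-s epochs stepping 1.5 s over 12 s
        mask = ArtifactMask(((4.0, 3.0, None),))
        offsets = [0.0, 1.5, 3.0, 4.5, 6.0, 7.5, 9.0]
        keep = epochs_surviving_mask(offsets, 3.0, mask)
        # epochs [1.5,4.5) [3,6) [4.5,7.5) [6,9) overlap [4,7)
        assert keep == [0, 5, 6]

    def test_mask_roundtrips_through_annotations(self):
        rec = _rec(_sine(5.0))
        mask = ArtifactMask(((1.0, 2.0, None), (3.0, 0.5, "ECG")))
        out = apply_artifact_mask(rec, mask)
        assert mask_from_recording(out).spans == mask.spans

    def test_auto_mask_flags_injected_pulse(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, int(60 * FS))
        x[int(30 * FS): int(30.5 * FS)] += 500.0
        mask = auto_artifact_mask(_rec(x), z_threshold=5.0)
        assert any(onset == 30.0 for onset, _, _ in mask.spans)

    def test_clean_signal_unflagged_and_inf_threshold(self):
        rng = np.random.default_rng(2)
        rec = _rec(rng.normal(0, 10, int(60 * FS)))
        assert len(auto_artifact_mask(rec, 8.0)) == 0
        assert len(auto_artifact_mask(rec, np.inf)) == 0


class TestOcularRemoval:
    @staticmethod
    def _band(rec, ch, lo, hi):
        psd = epoch_psd(rec.channel(ch), rec.sampling_rate)
        return band_power(psd, (lo, hi))

    def test_blink_removal_spares_occipital_alpha(self):
        rec, _ = gen_eeg_session(EEGEffectProfile(), durations=(30, 30, 30),
                                 fs=256, seed=3, blinks=True, blink_amplitude=120.0)
        rec = bandpass(rec, 1.0, 30.0)
        clean, info = remove_ocular_component(rec, seed=0)
        assert info["removed"] is not None
        blink_before = self._band(rec, "Fp1", 1.0, 4.0)
        blink_after = self._band(clean, "Fp1", 1.0, 4.0)
        assert blink_after <= 0.5 * blink_before
        alpha_before = self._band(rec, "O1", 8.0, 12.0)
        alpha_after = self._band(clean, "O1", 8.0, 12.0)
        assert alpha_after == pytest.approx(alpha_before, rel=0.05)

    def test_blink_free_eeg_untouched(self, null_eeg_session):
        rec, _ = null_eeg_session
        rec = bandpass(rec, 1.0, 30.0)
        clean, info = remove_ocular_component(rec, seed=0)
        assert info["removed"] is None
        assert np.array_equal(clean.data, rec.data)

    def test_at_most_one_component_removed_then_idempotent(self):
        rec, _ = gen_eeg_session(EEGEffectProfile(), durations=(30, 30, 30),
                                 fs=256, seed=4, blinks=True, blink_amplitude=120.0)
        rec = bandpass(rec, 1.0, 30.0)
        clean, info = remove_ocular_component(rec, seed=0)
        assert info["removed"] is not None
        again, info2 = remove_ocular_component(clean, seed=0)
        assert info2["removed"] is None  # second pass finds no blink component
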
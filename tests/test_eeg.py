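"""Band power estimation, baseline z-scoring, and topographic contrasts."""

import numpy as np
import pandas as pd
import pytest

from therasig.core import DEFAULT_BANDS, SpectralEstimate
from therasig.eeg import (
    BandPowerSeries,
    DegenerateBaselineError,
    band_power,
    compute_band_power,
    epoch_psd,
    period_summary,
    topographic_contrast,
    zscore_to_pre,
)
from therasig.synth import EEGEffectProfile, gen_eeg_session

FS = 256.0


def _epoch(freq=10.0, amp=1.0, seconds=3.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestEpochPSD:
    def test_parseval_sinusoid(self):
        psd = epoch_psd(_epoch(), FS)
        # Parseval on the density estimate itself (trapezoidal integral)
        assert np.trapezoid(psd.density, psd.frequencies) == pytest.approx(0.5, rel=0.05)
        # Simpson band integration overshoots a 3-grid-point peak by a
        # bounded quadratic-interpolation factor (<= 1/9 for a Hann peak)
        total = band_power(psd, (psd.frequencies[0], psd.frequencies[-1]))
        assert 0.5 * 0.95 <= total <= 0.5 * (1 + 1 / 9) * 1.01
        peak = psd.frequencies[np.argmax(psd.density)]
        assert abs(peak - 10.0) <= np.diff(psd.frequencies)[0]

    def test_parseval_white_noise(self, rng):
        sigma = 3.0
        x = rng.normal(0, sigma, int(3 * FS))
        psd = epoch_psd(x, FS)
        total = band_power(psd, (psd.frequencies[0], psd.frequencies[-1]))
        assert total == pytest.approx(sigma**2, rel=0.10)

    def test_zero_signal(self):
        psd = epoch_psd(np.zeros(int(3 * FS)), FS)
        assert np.all(psd.density == 0)

    def test_resolution_below_one_hz(self):
        psd = epoch_psd(_epoch(), FS)
        assert np.diff(psd.frequencies)[0] <= 1.0


class TestBandPower:
    def test_flat_density_exact(self):
        f = np.arange(0.0, 31.0, 0.5)
        psd = SpectralEstimate(f, np.full_like(f, 2.0))
        assert band_power(psd, (8.0, 12.0)) == pytest.approx(8.0, abs=1e-12)

    def test_additive_over_partition(self, rng):
        psd = epoch_psd(rng.normal(0, 1, int(3 * FS)), FS)
        parts = sum(band_power(psd, (lo, hi)) for _, lo, hi in DEFAULT_BANDS.bands)
        whole = band_power(psd, DEFAULT_BANDS.full_range)
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_alpha_concentration(self):
        psd = epoch_psd(_epoch(10.0), FS)
        alpha = band_power(psd, (8.0, 12.0))
        total = band_power(psd, (1.0, 30.0))
        assert alpha / total >= 0.95

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(0, 1, int(3 * FS))
        p1 = band_power(epoch_psd(x, FS), (4.0, 8.0))
        p2 = band_power(epoch_psd(-x, FS), (4.0, 8.0))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_band_outside_range(self):
        psd = epoch_psd(_epoch(), FS)
        with pytest.raises(ValueError, match="outside"):
            band_power(psd, (100.0, 200.0))


class TestZScore:
    def test_pre_epochs_standardized(self, rng):
        x = rng.normal(5, 2, 40)
        pre = np.zeros(40, bool)
        pre[:15] = True
        z = zscore_to_pre(x, pre)
        assert z[pre].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[pre].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_matched_distribution_near_zero(self, rng):
        x = rng.normal(0, 1, 400)
        pre = np.arange(400) < 200
        z = zscore_to_pre(x, pre)
        assert abs(z[~pre].mean()) < 0.2

    def test_degenerate_baseline(self):
        with pytest.raises(DegenerateBaselineError):
            zscore_to_pre(np.array([1.0, 1.0, 2.0, 3.0]), np.array([True, True, False, False]))


class TestPipeline:
    def test_gain_invariance_of_z(self):
        profile = EEGEffectProfile(multipliers={("O1", "Alpha"): {"MTI": 2.0}})
        rec, seg = gen_eeg_session(profile, durations=(40, 40, 40), fs=FS, seed=5)
        series = compute_band_power(rec, seg)
        gains = np.where(np.arange(rec.n_channels) % 2, 0.5, 2.0)[:, None]
        rec2 = type(rec)(rec.modality, rec.channel_labels, rec.sampling_rate,
                         rec.data * gains, rec.annotations)
        series2 = compute_band_power(rec2, seg)
        assert np.allclose(series.z, series2.z, atol=1e-8)

    def test_recovery_prediction(self):
        # doubling O1 alpha power in MTI: mean MTI z should be the largest
        # positive alpha z across channels
        profile = EEGEffectProfile(multipliers={("O1", "Alpha"): {"MTI": 2.0}})
        rec, seg = gen_eeg_session(profile, durations=(60, 60, 60), fs=FS, seed=6)
        summ = period_summary(compute_band_power(rec, seg))
        alpha_mti = summ[(summ.period == "MTI") & (summ.band == "Alpha")]
        best = alpha_mti.loc[alpha_mti.mean_z.idxmax(), "channel"]
        assert best == "O1"
        assert alpha_mti.mean_z.max() > 0.5

    def test_null_profile_small_z(self, null_eeg_session):
        rec, seg = null_eeg_session
        summ = period_summary(compute_band_power(rec, seg))
        off_pre = summ[summ.period != "PRE"]
        assert np.abs(off_pre.mean_z).max() < 0.6  # sampling-error envelope

    def test_single_epoch_period_summary(self):
        power = np.abs(np.random.default_rng(0).normal(5, 1, (5, 2, 1)))
        labels = ("PRE", "PRE", "PRE", "MTI", "POST")
        z = zscore_to_pre(power, np.array([True, True, True, False, False]))
        series = BandPowerSeries(power=power, z=z, periods=labels,
                                 channels=("O1", "O2"), bands=("Alpha",))
        summ = period_summary(series)
        post = summ[summ.period == "POST"]
        assert np.allclose(post.mean_z.to_numpy(), z[4, :, 0])


class TestTopographicContrast:
    @staticmethod
    def _summaries(rng, n_rec=6, effect=0.0):
        rows = []
        for r in range(n_rec):
            for period in ("PRE", "MTI"):
                for ch in ("O1", "O2", "Fp1"):
                    shift = effect if (period == "MTI" and ch == "O1") else 0.0
                    rows.append({"recording": f"r{r}", "period": period,
                                 "channel": ch, "band": "Alpha",
                                 "mean_z": shift + rng.normal(0, 0.2)})
        return pd.DataFrame(rows)

    def test_equal_pvalues_unchanged_by_bh(self, rng):
        df = self._summaries(rng)
        # identical data in every channel -> identical p in the band
        base = df[df.channel == "O1"].copy()
        clones = []
        for ch in ("O1", "O2", "Fp1"):
            c = base.copy()
            c["channel"] = ch
            clones.append(c)
        out = topographic_contrast(pd.concat(clones, ignore_index=True), seed=2)
        assert np.allclose(out["p_adjusted"], out["p"])

    def test_injected_effect_flagged(self, rng):
        out = topographic_contrast(self._summaries(rng, effect=2.0), seed=3)
        o1 = out[out.channel == "O1"].iloc[0]
        assert o1["significant"] and o1["mean_change"] > 0

    def test_requires_replication(self, rng):
        df = self._summaries(rng, n_rec=1)
        with pytest.raises(ValueError, match="2 recordings"):
            topographic_contrast(df)
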
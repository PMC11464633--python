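"""Synthetic session generator with known ground-truth effect structure.

Generates complete sessions — 8-channel EEG, single-lead ECG, facial
EMG, and a small clinical score table — whose per-period effect
structure (band-power multipliers, autonomic LF/HF balance, EMG
spectral centroid and amplitude) is specified exactly, so every
analysis stage can be validated by parameter recovery.  All generators
are pure functions of (profile, seed).

EEG channels are sums of band-limited Gaussian noise built by spectral
shaping (construct in the frequency domain, inverse transform), giving
exact control of the within-band variance per period.  The ECG is a
stereotyped Mexican-hat QRS train whose R-R sequence carries
fixed-frequency LF and HF sinusoids plus truncated-Gaussian jitter.
The EMG is Gaussian noise shaped by a Gaussian spectral envelope
(SD 30 Hz, truncated to 20-200 Hz) with a controlled centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    EEG_CHANNELS,
    DEFAULT_BANDS,
    BandScheme,
    Modality,
    PeriodSegmentation,
    PERIODS,
    Recording,
)

__all__ = [
    "EEGEffectProfile",
    "AutonomicProfile",
    "EMGProfile",
    "gen_eeg_session",
    "gen_ecg_session",
    "gen_emg_session",
    "gen_clinical_table",
    "ProfileError",
    "study_effect_profiles",
]


class ProfileError(ValueError):
    """Effect profile references unknown cells or violates physiology."""


#: default PRE band powers (uV^2): a rough resting 1/f-shaped profile
DEFAULT_BASE_POWER = {"Delta": 30.0, "Theta": 15.0, "Alpha": 15.0,
                      "SlowBeta": 8.0, "FastBeta": 5.0}


@dataclass(frozen=True)
class EEGEffectProfile:
    """Per-channel, per-band, per-period power multipliers (PRE == 1).

    ``multipliers`` maps (channel, band) -> {period: multiplier}; any
    cell/period not listed defaults to 1.0.
    """

    base_power: dict = field(default_factory=lambda: dict(DEFAULT_BASE_POWER))
    multipliers: dict = field(default_factory=dict)
    channels: tuple[str, ...] = EEG_CHANNELS
    bands: BandScheme = DEFAULT_BANDS

    def __post_init__(self):
        for band in self.base_power:
            if band not in self.bands.names:
                raise ProfileError(f"unknown band in base_power: {band}")
        for (ch, band), per in self.multipliers.items():
            if ch not in self.channels:
                raise ProfileError(f"unknown channel: {ch}")
            if band not in self.bands.names:
                raise ProfileError(f"unknown band: {band}")
            for period, mult in per.items():
                if period not in PERIODS:
                    raise ProfileError(f"unknown period: {period}")
                if not mult > 0:
                    raise ProfileError(f"multiplier must be > 0 ({ch}/{band}/{period})")
                if period == "PRE" and mult != 1.0:
                    raise ProfileError("PRE multipliers must all equal 1")

    def multiplier(self, channel: str, band: str, period: str) -> float:
        return float(self.multipliers.get((channel, band), {}).get(period, 1.0))


@dataclass(frozen=True)
class AutonomicProfile:
    """Per-period R-R structure: mean (ms), LF/HF sinusoid amplitudes (ms),
    white jitter SD (ms); oscillation frequencies shared across periods."""

    mean_rr: dict = field(default_factory=lambda: {p: 800.0 for p in PERIODS})
    a_lf: dict = field(default_factory=lambda: {p: 30.0 for p in PERIODS})
    a_hf: dict = field(default_factory=lambda: {p: 30.0 for p in PERIODS})
    jitter_sd: dict = field(default_factory=lambda: {p: 10.0 for p in PERIODS})
    f_lf: float = 0.1
    f_hf: float = 0.25

    def __post_init__(self):
        if not (0.04 <= self.f_lf < 0.15):
            raise ProfileError("f_lf must lie in [0.04, 0.15)")
        if not (0.15 <= self.f_hf < 0.4):
            raise ProfileError("f_hf must lie in [0.15, 0.4)")
        for p in PERIODS:
            mean = self.mean_rr[p]
            if not 300.0 <= mean <= 1500.0:
                raise ProfileError(f"mean RR out of [300, 1500] ms in {p}")
            if self.a_lf[p] < 0 or self.a_hf[p] < 0 or self.jitter_sd[p] < 0:
                raise ProfileError("amplitudes and jitter SD must be >= 0")
            excursion = self.a_lf[p] + self.a_hf[p] + 3.0 * self.jitter_sd[p]
            if mean - excursion < 300.0 or mean + excursion > 1500.0:
                raise ProfileError(
                    f"{p}: R-R excursion {excursion:.0f} ms around {mean:.0f} ms "
                    "would leave [300, 1500] ms"
                )


@dataclass(frozen=True)
class EMGProfile:
    """Per-period spectral centroid target (Hz in 20-200) and RMS (uV)."""

    centroid: dict = field(default_factory=lambda: {p: 110.0 for p in PERIODS})
    rms: dict = field(default_factory=lambda: {p: 10.0 for p in PERIODS})
    envelope_sd: float = 30.0

    def __post_init__(self):
        for p in PERIODS:
            if not 20.0 <= self.centroid[p] <= 200.0:
                raise ProfileError(f"centroid outside 20-200 Hz in {p}")
            if self.rms[p] <= 0:
                raise ProfileError("RMS must be positive")


def _segmentation(durations: dict[str, float]) -> PeriodSegmentation:
    t0 = 0.0
    ivs = {}
    for p in PERIODS:
        ivs[p] = (t0, t0 + float(durations[p]))
        t0 += float(durations[p])
    return PeriodSegmentation(pre=ivs["PRE"], mti=ivs["MTI"], post=ivs["POST"])


def _as_durations(durations) -> dict[str, float]:
    if isinstance(durations, dict):
        d = {p: float(durations[p]) for p in PERIODS}
    else:
        d = dict(zip(PERIODS, map(float, durations)))
    if any(v <= 0 for v in d.values()):
        raise ValueError("durations must be positive")
    return d


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float, variance: float) -> np.ndarray:
    """Band-limited Gaussian noise with exactly the requested variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < low) | (f > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        return x
    return x * (np.sqrt(variance) / sd)


def _blink_template(fs: float) -> np.ndarray:
    # biphasic ~400-ms pulse, dominant energy below 4 Hz
    t = np.arange(int(0.4 * fs)) / fs
    return np.sin(2 * np.pi * 2.5 * t) * np.hanning(t.size)


def gen_eeg_session(
    profile: EEGEffectProfile,
    durations=(300.0, 900.0, 300.0),
    fs: float = 256.0,
    seed: int = 0,
    blinks: bool = False,
    blink_amplitude: float = 80.0,
    blink_rate: float = 0.25,
) -> tuple[Recording, PeriodSegmentation]:
    """Synthetic 8-channel EEG with per-period band-power structure.

    Each channel is, per period, a sum over bands of band-limited noise
    whose variance equals multiplier(period) * base PRE power.  Optional
    blink transients are biphasic low-frequency pulses, full-size on
    Fp1/Fp2 with a posterior falloff.
    """
    if fs < 256:
        raise ValueError("EEG requires fs >= 256 Hz")
    durs = _as_durations(durations)
    rng = np.random.default_rng(seed)
    seg = _segmentation(durs)
    chunks = {ch: [] for ch in profile.channels}
    for period in PERIODS:
        n = int(round(durs[period] * fs))
        for ch in profile.channels:
            x = np.zeros(n)
            for band, lo, hi in profile.bands.bands:
                var = profile.base_power[band] * profile.multiplier(ch, band, period)
                x += _band_noise(rng, n, fs, lo, hi, var)
            chunks[ch].append(x)
    data = np.vstack([np.concatenate(chunks[ch]) for ch in profile.channels])
    if blinks:
        tpl = _blink_template(fs)
        falloff = {"Fp1": 1.0, "Fp2": 1.0, "C3": 0.3, "C4": 0.3,
                   "T3": 0.2, "T4": 0.2, "O1": 0.1, "O2": 0.1}
        n_total = data.shape[1]
        t = tpl.size
        pos = 0
        while pos + t < n_total:
            gap = rng.exponential(1.0 / blink_rate)
            pos += int(gap * fs)
            if pos + t >= n_total:
                break
            for c, ch in enumerate(profile.channels):
                data[c, pos: pos + t] += blink_amplitude * falloff.get(ch, 0.1) * tpl
    annotations = tuple((seg[p][0], seg[p][1] - seg[p][0], p) for p in PERIODS)
    rec = Recording(Modality.EEG, profile.channels, fs, data, annotations)
    return rec, seg


def _qrs_template(fs: float, width_s: float = 0.08, amplitude: float = 1.0) -> np.ndarray:
    """Mexican-hat-like QRS pulse of ~80 ms total width, amplitude in mV."""
    sigma = width_s / 5.0
    t = np.arange(-width_s, width_s, 1.0 / fs)
    psi = (1 - (t / sigma) ** 2) * np.exp(-(t**2) / (2 * sigma**2))
    return amplitude * psi / psi.max()


def gen_ecg_session(
    profile: AutonomicProfile,
    durations=(300.0, 900.0, 300.0),
    fs: float = 256.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[Recording, PeriodSegmentation, np.ndarray]:
    """Synthetic single-lead ECG (mV) with a controlled R-R sequence.

    RR_n = meanRR + a_LF sin(2 pi f_LF t_n) + a_HF sin(2 pi f_HF t_n)
    + eps_n with eps truncated at +/-3 SD; a QRS template is placed at
    each cumulative peak time on additive white noise of ``noise_sd``
    mV.  Returns the recording, the segmentation, and the ground-truth
    peak times for detector validation.
    """
    if fs < 256:
        raise ValueError("ECG requires fs >= 256 Hz")
    durs = _as_durations(durations)
    seg = _segmentation(durs)
    rng = np.random.default_rng(seed)
    total = sum(durs.values())
    times = []
    t = 0.2  # first peak shortly after start
    while t < total:
        period = "PRE" if t < seg.pre[1] else ("MTI" if t < seg.mti[1] else "POST")
        eps = rng.standard_normal() * profile.jitter_sd[period]
        eps = float(np.clip(eps, -3 * profile.jitter_sd[period],
                            3 * profile.jitter_sd[period]))
        rr_ms = (profile.mean_rr[period]
                 + profile.a_lf[period] * np.sin(2 * np.pi * profile.f_lf * t)
                 + profile.a_hf[period] * np.sin(2 * np.pi * profile.f_hf * t)
                 + eps)
        times.append(t)
        t += rr_ms / 1000.0
    peak_times = np.asarray(times)
    n = int(round(total * fs))
    x = rng.standard_normal(n) * noise_sd if noise_sd > 0 else np.zeros(n)
    tpl = _qrs_template(fs)
    half = tpl.size // 2
    for pt in peak_times:
        c = int(round(pt * fs))
        lo, hi = c - half, c - half + tpl.size
        if lo < 0 or hi > n:
            continue
        x[lo:hi] += tpl
    annotations = tuple((seg[p][0], seg[p][1] - seg[p][0], p) for p in PERIODS)
    rec = Recording(Modality.ECG, ("ECG",), fs, x[np.newaxis, :], annotations)
    return rec, seg, peak_times


def gen_emg_session(
    profile: EMGProfile,
    durations=(300.0, 900.0, 300.0),
    fs: float = 512.0,
    seed: int = 0,
) -> tuple[Recording, PeriodSegmentation]:
    """Synthetic facial EMG: spectrum-shaped noise with controlled centroid.

    Per period, white Gaussian noise is shaped so its PSD follows a
    Gaussian envelope centred on the period's target (SD 30 Hz,
    truncated to 20-200 Hz) and scaled to the period's RMS.
    """
    if fs < 512:
        raise ValueError("EMG generation requires fs >= 512 Hz (analysis gate)")
    durs = _as_durations(durations)
    seg = _segmentation(durs)
    rng = np.random.default_rng(seed)
    chunks = []
    for period in PERIODS:
        n = int(round(durs[period] * fs))
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        c = profile.centroid[period]
        envelope = np.exp(-((f - c) ** 2) / (2 * profile.envelope_sd**2))
        envelope[(f < 20.0) | (f > 200.0)] = 0.0
        x = np.fft.irfft(spec * np.sqrt(envelope), n=n)
        x *= profile.rms[period] / np.sqrt(np.mean(x**2))
        chunks.append(x)
    data = np.concatenate(chunks)[np.newaxis, :]
    annotations = tuple((seg[p][0], seg[p][1] - seg[p][0], p) for p in PERIODS)
    rec = Recording(Modality.EMG, ("EMG",), fs, data, annotations)
    return rec, seg


def gen_clinical_table(
    n_patients: int = 9,
    vas_shift: float = 0.0,
    hads_anxiety_shift: float = 0.0,
    hads_depression_shift: float = 0.0,
    missing_last_fraction: float = 0.0,
    single_session_patients: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic clinical table (one row per patient-session).

    Integer VAS 0-10 per session PRE/POST and integer HADS subscales
    0-21 at first/last timepoints.  ``*_shift`` are mean POST-PRE /
    last-first effects; scores falling outside their range are clipped
    with a warning.  A configurable fraction of patients miss the last
    HADS timepoint, and ``single_session_patients`` patients get only
    one recording session.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    rows = []
    clipped = False

    def draw_score(base_lam, shift, top):
        first = int(min(rng.poisson(base_lam), top))
        last_f = first + shift + rng.normal(0, 1.0)
        last = int(round(last_f))
        nonlocal clipped
        if last < 0 or last > top:
            clipped = True
        return first, int(np.clip(last, 0, top))

    missing_last = set(
        rng.choice(n_patients, size=int(round(missing_last_fraction * n_patients)),
                   replace=False).tolist()
    )
    for p in range(n_patients):
        age = int(rng.integers(18, 66))
        sex = "Female" if rng.random() < 1 / 9 else "Male"
        burn = "Thermal" if rng.random() < 2 / 3 else "Electric"
        severity = int(rng.integers(1, 3))
        anx_first, anx_last = draw_score(6.0, hads_anxiety_shift, 21)
        dep_first, dep_last = draw_score(4.0, hads_depression_shift, 21)
        n_sessions = 1 if p < single_session_patients else 2
        for s in range(1, n_sessions + 1):
            vas_pre = int(min(rng.poisson(2.0), 10))
            post_f = vas_pre + vas_shift + rng.normal(0, 1.0)
            vas_post = int(round(post_f))
            if vas_post < 0 or vas_post > 10:
                clipped = True
            vas_post = int(np.clip(vas_post, 0, 10))
            rows.append({
                "patient_id": f"{p + 1:02d}", "session": s,
                "age": age, "sex": sex, "burn_type": burn, "severity": severity,
                "vas_pre": vas_pre, "vas_post": vas_post,
                "hads_anxiety_first": anx_first,
                "hads_anxiety_last": np.nan if p in missing_last else anx_last,
                "hads_depression_first": dep_first,
                "hads_depression_last": np.nan if p in missing_last else dep_last,
            })
    if clipped:
        warnings.warn("some synthetic scores were clipped to their valid range")
    return pd.DataFrame(rows)


def study_effect_profiles() -> dict:
    """Default effect profiles emulating the observed intervention pattern.

    EEG: occipital Alpha up and frontal Delta/Theta plus frontotemporal
    FastBeta down during MTI only.  Autonomic: HF amplitude dominant
    during MTI (parasympathetic shift), larger overall variability in
    POST.  EMG: spectral centroid lowered ~6.5 Hz during MTI with
    unchanged amplitude.
    """
    eeg = EEGEffectProfile(multipliers={
        ("O1", "Alpha"): {"MTI": 2.0},
        ("O2", "Alpha"): {"MTI": 1.5},
        ("Fp1", "Delta"): {"MTI": 0.75},
        ("Fp2", "Delta"): {"MTI": 0.7},
        ("Fp2", "Theta"): {"MTI": 0.7},
        ("Fp1", "FastBeta"): {"MTI": 0.6},
        ("T3", "FastBeta"): {"MTI": 0.6},
        ("T4", "FastBeta"): {"MTI": 0.6},
    })
    autonomic = AutonomicProfile(
        mean_rr={"PRE": 800.0, "MTI": 790.0, "POST": 810.0},
        a_lf={"PRE": 40.0, "MTI": 20.0, "POST": 40.0},
        a_hf={"PRE": 20.0, "MTI": 45.0, "POST": 20.0},
        jitter_sd={"PRE": 12.0, "MTI": 12.0, "POST": 25.0},
    )
    emg = EMGProfile(
        centroid={"PRE": 110.0, "MTI": 103.5, "POST": 111.5},
        rms={"PRE": 10.0, "MTI": 10.0, "POST": 10.0},
    )
    return {"eeg": eeg, "autonomic": autonomic, "emg": emg}
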
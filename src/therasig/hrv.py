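"""Heart-rate variability from a single-lead ECG.

Pipeline: 1-40 Hz band-passed ECG -> R-peak detection (derivative-energy
with adaptive threshold and 250-ms refractory period) -> R-R series;
intervals outside 0.3-1.5 s are excluded and linearly interpolated in
place.  Per period (central 5/15/5-min windows) the module computes the
time-domain indices meanRR / STDRR / pRR50, the Poincare descriptors
SD1 / SD2 on the PRE-z-normalized tachogram, and the LF / HF spectral
balance of the 4-Hz cubic-spline-resampled tachogram (Welch, total-power
normalized, Simpson band integrals).  For windows shorter than 5 min
the lower LF edge rises to 12/T Hz so at least 12 oscillation cycles
fit in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_simpson
from scipy.interpolate import CubicSpline

from .core import Interval, PeriodSegmentation, Recording, central_window

__all__ = [
    "Tachogram",
    "detect_r_peaks",
    "clean_rr",
    "time_domain",
    "poincare",
    "spectral_lf_hf",
    "hrv_session_summary",
    "NoPeaksError",
    "RRQualityError",
    "HRV_FEATURES",
]

#: physiologic R-R bounds used for exclusion (ms)
RR_BOUNDS_MS = (300.0, 1500.0)

#: Table-2 feature set, in its column order
HRV_FEATURES = ("meanRR", "STDRR", "pRR50", "SD1", "SD2", "SD1/SD2",
                "LF", "HF", "LF/HF")

WINDOW_MINUTES = {"PRE": 5.0, "MTI": 15.0, "POST": 5.0}


class NoPeaksError(ValueError):
    """No R peaks found (flat or disconnected lead)."""


class RRQualityError(ValueError):
    """Too large a fraction of R-R intervals outside physiologic bounds."""


@dataclass(frozen=True)
class Tachogram:
    """R-peak times (s) and the R-R series (ms) between consecutive peaks.

    ``valid`` marks intervals inside the physiologic bounds;
    ``interpolated`` marks values replaced by interpolation during
    cleaning.  Each R-R value is anchored at the time of its
    terminating peak.
    """

    peak_times: np.ndarray       # seconds, strictly increasing
    rr: np.ndarray               # ms, len == len(peak_times) - 1
    valid: np.ndarray            # bool per interval
    interpolated: np.ndarray     # bool per interval

    def __post_init__(self):
        t = np.asarray(self.peak_times, float)
        rr = np.asarray(self.rr, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if rr.shape != (len(t) - 1,):
            raise ValueError("rr length must be len(peak_times) - 1")
        object.__setattr__(self, "peak_times", t)
        object.__setattr__(self, "rr", rr)
        object.__setattr__(self, "valid", np.asarray(self.valid, bool))
        object.__setattr__(self, "interpolated", np.asarray(self.interpolated, bool))

    @property
    def anchor_times(self) -> np.ndarray:
        """Time stamp of each R-R value (its terminating peak)."""
        return self.peak_times[1:]

    @classmethod
    def from_peaks(cls, peak_times) -> "Tachogram":
        t = np.asarray(peak_times, float)
        rr = np.diff(t) * 1000.0
        ok = np.ones(rr.shape, bool)
        return cls(t, rr, ok, np.zeros(rr.shape, bool))

    def in_window(self, window: Interval) -> np.ndarray:
        """R-R values whose anchor time lies in the half-open window."""
        at = self.anchor_times
        return self.rr[(at >= window[0]) & (at < window[1])]


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (s) via a derivative-energy detector.

    Squared-derivative energy is smoothed over an 80-ms window; peaks
    must clear an adaptive threshold (refined from the first pass's
    median peak energy) and respect a 250-ms refractory period.  The
    R time is the absolute-amplitude maximum within +/-60 ms of the
    energy peak.  Flat (disconnected-lead) stretches produce no energy
    and therefore no detections.
    """
    x = np.asarray(ecg, float).ravel()
    if x.size < int(fs):
        raise NoPeaksError("signal shorter than 1 s")
    if np.ptp(x) == 0:
        raise NoPeaksError("flat signal")
    energy = np.gradient(x) ** 2
    win = max(int(round(0.08 * fs)), 1)
    kernel = np.ones(win) / win
    energy = np.convolve(energy, kernel, mode="same")
    refractory = int(round(0.25 * fs))
    h0 = 0.1 * np.percentile(energy, 99.5)
    peaks, _ = signal.find_peaks(energy, height=h0, distance=refractory)
    if peaks.size == 0:
        raise NoPeaksError("no QRS-like energy found")
    # second pass: threshold from the detected peak population
    h1 = 0.25 * np.median(energy[peaks])
    peaks, _ = signal.find_peaks(energy, height=max(h0, h1), distance=refractory)
    if peaks.size == 0:
        raise NoPeaksError("no QRS-like energy found")
    half = int(round(0.06 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(r)
    return np.asarray(keep, float) / fs


def clean_rr(tach: Tachogram, max_invalid_fraction: float = 0.2) -> Tachogram:
    """Exclude R-R values outside 0.3-1.5 s and interpolate them in place.

    Each invalid run is replaced by linear interpolation between the
    flanking valid values (nearest-valid fill at the edges); the number
    of intervals never changes.  Raises :class:`RRQualityError` when
    more than ``max_invalid_fraction`` of intervals are invalid.
    Idempotent.
    """
    if len(tach.rr) < 4:
        raise ValueError("need at least 4 R-R intervals")
    lo, hi = RR_BOUNDS_MS
    invalid = (tach.rr < lo) | (tach.rr > hi)
    frac = invalid.mean()
    if frac > max_invalid_fraction:
        raise RRQualityError(
            f"{frac:.0%} of R-R intervals outside [{lo:.0f}, {hi:.0f}] ms "
            f"(threshold {max_invalid_fraction:.0%})"
        )
    if not invalid.any():
        return replace(tach, valid=~invalid)
    if invalid.all():
        raise RRQualityError("all intervals invalid")
    idx = np.arange(len(tach.rr))
    rr = tach.rr.copy()
    rr[invalid] = np.interp(idx[invalid], idx[~invalid], rr[~invalid])
    return Tachogram(tach.peak_times, rr, ~invalid,
                     tach.interpolated | invalid)


def time_domain(rr: np.ndarray) -> dict[str, float]:
    """meanRR (ms), STDRR (sample SD, ms), pRR50 (% successive diffs > 50 ms)."""
    rr = np.asarray(rr, float)
    if rr.size < 2:
        raise ValueError("need at least 2 R-R intervals")
    diffs = np.abs(np.diff(rr))
    return {
        "meanRR": float(rr.mean()),
        "STDRR": float(rr.std(ddof=1)),
        "pRR50": float(100.0 * np.mean(diffs > 50.0)),
    }


def poincare(
    rr: np.ndarray, pre_mean: float, pre_sd: float,
) -> tuple[dict[str, float], np.ndarray]:
    """Poincare SD1/SD2 of the PRE-z-normalized tachogram.

    Each R-R value is z-scored against the patient's PRE mean/SD, and
    (z_n, z_{n+1}) pairs form the Poincare cloud.  SD1 is the RMS
    perpendicular distance to the identity line, |z_n - z_{n+1}| / sqrt(2)
    — identically RMSSD/sqrt(2) of the z-series — and SD2 the population
    SD of the projection onto the line, (z_n + z_{n+1}) / sqrt(2).
    Returns the descriptors and the (z_n, z_{n+1}) point cloud.
    """
    rr = np.asarray(rr, float)
    if rr.size < 3:
        raise ValueError("need at least 3 R-R intervals")
    if not pre_sd > 0:
        raise ValueError("degenerate PRE baseline (SD = 0)")
    z = (rr - pre_mean) / pre_sd
    d = (z[:-1] - z[1:]) / np.sqrt(2.0)
    s = (z[:-1] + z[1:]) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d**2)))
    sd2 = float(np.std(s, ddof=0))
    ratio = sd1 / sd2 if sd2 > 0 else np.nan
    cloud = np.column_stack([z[:-1], z[1:]])
    return {"SD1": sd1, "SD2": sd2, "SD1/SD2": ratio}, cloud


def spectral_lf_hf(
    tach: Tachogram, window: Interval, fs_resample: float = 4.0,
) -> dict[str, float]:
    """LF/HF balance of the cubic-spline-resampled tachogram over a window.

    The R-R series (anchored at terminating peaks) is cubic-spline
    resampled to ``fs_resample`` Hz over the window, mean-removed, and
    Welch-estimated (Hann, segment length min(T, 256 s), 50 % overlap).
    The density is normalized by total 0-2 Hz power; LF integrates
    [f_low, 0.15] Hz and HF [0.15, 0.4] Hz (Simpson), both as % of total
    power; LF/HF is the ratio of the unscaled integrals.  f_low =
    max(0.04, 12/T) so at least 12 LF cycles fit the window.
    """
    start, end = window
    at = tach.anchor_times
    sel = (at >= start) & (at < end)
    if sel.sum() < 4:
        raise ValueError("too few R-R intervals in window")
    t_sel, rr_sel = at[sel], tach.rr[sel]
    g0, g1 = max(start, t_sel[0]), min(end, t_sel[-1])
    duration = g1 - g0
    if duration < 60.0:
        raise ValueError(f"window of {duration:.1f} s too short (< 60 s)")
    # proportional rule uses the requested window length, so a nominal
    # 240-s window gives exactly 12/240 = 0.05 Hz
    f_low = max(0.04, 12.0 / (end - start))
    if f_low >= 0.15:
        raise ValueError(f"adaptive LF cutoff {f_low:.3f} Hz >= 0.15 Hz; LF undefined")
    spline = CubicSpline(t_sel, rr_sel)
    grid = np.arange(g0, g1, 1.0 / fs_resample)
    x = spline(grid)
    x = x - x.mean()
    nperseg = min(x.size, int(256 * fs_resample))
    f, pxx = signal.welch(x, fs=fs_resample, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, scaling="density")
    cum = cumulative_simpson(pxx, x=f, initial=0.0)

    def integral(lo, hi):
        idx = np.nonzero((f >= lo - 1e-12) & (f <= hi + 1e-12))[0]
        return float(cum[idx[-1]] - cum[idx[0]]) if idx.size >= 2 else 0.0

    total = integral(0.0, 2.0)
    lf = integral(f_low, 0.15)
    hf = integral(0.15, 0.4)
    if total <= 0:
        raise ValueError("zero total spectral power")
    return {
        "LF": 100.0 * lf / total,
        "HF": 100.0 * hf / total,
        "LF/HF": lf / hf if hf > 0 else np.inf,
        "f_low": f_low,
        "total_power": total,
    }


def hrv_session_summary(
    recording: Recording,
    segmentation: PeriodSegmentation,
    window_minutes: dict[str, float] | None = None,
    max_invalid_fraction: float = 0.2,
) -> dict:
    """Table-2 feature set per period plus pairwise deltas.

    Deltas follow the first-minus-second sign convention: a positive
    MTI-PRE value is an increase during MTI relative to PRE.
    """
    window_minutes = dict(WINDOW_MINUTES, **(window_minutes or {}))
    ecg = np.asarray(recording.data[0], float)
    peaks = detect_r_peaks(ecg, recording.sampling_rate)
    if peaks.size < 5:
        raise NoPeaksError("too few R peaks for HRV analysis")
    tach = clean_rr(Tachogram.from_peaks(peaks), max_invalid_fraction)
    windows = {p: central_window(segmentation[p], window_minutes[p])
               for p in ("PRE", "MTI", "POST")}
    rr_pre = tach.in_window(windows["PRE"])
    if rr_pre.size < 3:
        raise ValueError("too few PRE intervals")
    pre_mean, pre_sd = float(rr_pre.mean()), float(rr_pre.std(ddof=1))
    per_period: dict[str, dict[str, float]] = {}
    for period, win in windows.items():
        rr = tach.in_window(win)
        feats = time_domain(rr)
        pc, _ = poincare(rr, pre_mean, pre_sd)
        feats.update(pc)
        spec = spectral_lf_hf(tach, win)
        feats.update({k: spec[k] for k in ("LF", "HF", "LF/HF")})
        per_period[period] = feats
    deltas = {}
    for a, b in (("MTI", "PRE"), ("POST", "PRE"), ("MTI", "POST")):
        deltas[f"{a}-{b}"] = {
            feat: per_period[a][feat] - per_period[b][feat] for feat in HRV_FEATURES
        }
    return {"per_period": per_period, "deltas": deltas, "tachogram": tach,
            "n_interpolated": int(tach.interpolated.sum())}
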
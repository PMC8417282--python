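"""Filtering, time-frequency decomposition, session PSDs, and theta/delta ratios.

Spectral state of a lead is summarized three ways: a frame-by-frame
spectrogram (1000 ms Hamming windows, 200 ms overlap, so one frame every
800 ms and 1 Hz frequency resolution at a 1 kHz sampling rate), a
session-averaged power spectral density normalized to unit mass over a
stated frequency range, and band powers / theta-delta (TD) ratios derived
from either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: canonical rodent band edges, Hz (inclusive bins); gamma edges are
#: conventional CA1 choices that exclude the 60 Hz line
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (6.0, 13.0),
    "slow_gamma": (25.0, 55.0),
    "fast_gamma": (65.0, 100.0),
}

#: normalization range for session spectral summaries (Hz)
NORM_RANGE_SUMMARY = (1.0, 100.0)
#: normalization range for decoding features (Hz)
NORM_RANGE_DECODING = (1.0, 50.0)


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got [{self.lo}, {self.hi}]")


def band(name: str) -> BandDef:
    lo, hi = BANDS[name]
    return BandDef(name, lo, hi)


@dataclass
class Spectrogram:
    """Per-frame one-sided PSD: power[n_freqs x n_frames], frame_times at window centers."""

    power: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray
    window_ms: float = 1000.0
    overlap_ms: float = 200.0


@dataclass
class LeadSpectrum:
    """Session-mean PSD normalized to unit sum over ``norm_range``."""

    lead_id: str
    freqs: np.ndarray
    norm_power: np.ndarray
    norm_range: tuple[float, float]


def notch_60hz(x: np.ndarray, sample_rate: float, width_hz: float = 4.0) -> np.ndarray:
    """Remove 60 Hz line noise with a zero-phase Butterworth band-stop.

    The stop band spans 60 +- width_hz/2; forward-backward filtering keeps
    the passband (1-50 Hz) flat to well under 0.5 dB.
    """
    if sample_rate <= 120:
        raise ValueError("sample_rate must exceed 120 Hz to notch 60 Hz")
    lo, hi = 60.0 - width_hz / 2, 60.0 + width_hz / 2
    sos = sps.butter(4, [lo, hi], btype="bandstop", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, float))


def compute_spectrogram(
    x: np.ndarray,
    sample_rate: float,
    window_ms: float = 1000.0,
    overlap_ms: float = 200.0,
) -> Spectrogram:
    """Hamming-window spectrogram with mean removal per window.

    With the defaults the hop is 800 ms and
    n_frames = floor((n_samples - window) / hop) + 1.
    """
    x = np.asarray(x, float)
    nperseg = int(round(window_ms * sample_rate / 1000.0))
    noverlap = int(round(overlap_ms * sample_rate / 1000.0))
    if x.size < nperseg:
        raise ValueError(f"signal ({x.size} samples) shorter than the {nperseg}-sample window")
    freqs, times, power = sps.spectrogram(
        x,
        fs=sample_rate,
        window=sps.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return Spectrogram(power=power, freqs=freqs, frame_times=times,
                       window_ms=window_ms, overlap_ms=overlap_ms)


def session_psd(
    spec: Spectrogram,
    norm_range: tuple[float, float] = NORM_RANGE_SUMMARY,
    lead_id: str = "",
) -> LeadSpectrum:
    """Frame-mean PSD restricted to ``norm_range`` and normalized to unit sum."""
    lo, hi = norm_range
    keep = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(keep):
        raise ValueError(f"normalization range {norm_range} outside the frequency grid")
    mean_power = spec.power.mean(axis=1)[keep]
    total = mean_power.sum()
    if total <= 0:
        raise ValueError("all-zero power: cannot normalize")
    return LeadSpectrum(lead_id=lead_id, freqs=spec.freqs[keep],
                        norm_power=mean_power / total, norm_range=(lo, hi))


def band_power(
    power: np.ndarray, freqs: np.ndarray, band: BandDef, per_frame: bool = False
) -> np.ndarray | float:
    """Mean power over a band's inclusive frequency bins.

    ``power`` is either a [n_freqs x n_frames] matrix (set ``per_frame`` for
    the frame series) or a 1-D spectrum.
    """
    power = np.asarray(power, float)
    freqs = np.asarray(freqs, float)
    keep = (freqs >= band.lo) & (freqs <= band.hi)
    if not np.any(keep):
        raise ValueError(f"band {band.name} [{band.lo},{band.hi}] Hz outside the grid")
    sel = power[keep]
    if per_frame:
        if sel.ndim != 2:
            raise ValueError("per_frame requires a [n_freqs x n_frames] matrix")
        return sel.mean(axis=0)
    return float(sel.mean())


def td_ratio(theta_power: np.ndarray | float, delta_power: np.ndarray | float):
    """Theta power divided by delta power, elementwise or scalar."""
    theta_power = np.asarray(theta_power, float)
    delta_power = np.asarray(delta_power, float)
    if np.any(delta_power <= 0):
        raise ValueError("delta power must be positive for a TD ratio")
    out = theta_power / delta_power
    return float(out) if out.ndim == 0 else out


def session_td_ratio(spec: Spectrogram) -> float:
    """Session TD ratio: session-mean theta power over session-mean delta power."""
    th = band_power(spec.power, spec.freqs, band("theta"), per_frame=True)
    de = band_power(spec.power, spec.freqs, band("delta"), per_frame=True)
    return td_ratio(float(np.mean(th)), float(np.mean(de)))


def peri_event_band_series(
    x: np.ndarray,
    sample_rate: float,
    event_times_s: np.ndarray,
    band_def: BandDef,
    window_s: tuple[float, float] = (-10.0, 4.0),
    step_s: float = 0.5,
    win_dur_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned band-power series with a dedicated 1 s window / 500 ms step.

    Returns (step_times, values) where ``values`` is [n_events x n_steps];
    events whose window falls outside the signal are dropped.  Each step's
    window is [t_event + step, t_event + step + win_dur).
    """
    x = np.asarray(x, float)
    nwin = int(round(win_dur_s * sample_rate))
    steps = np.arange(window_s[0], window_s[1] - win_dur_s + 1e-9, step_s)
    ham = sps.get_window("hamming", nwin)
    freqs = np.fft.rfftfreq(nwin, 1.0 / sample_rate)
    keep = (freqs >= band_def.lo) & (freqs <= band_def.hi)
    scale = 1.0 / (sample_rate * (ham * ham).sum())
    rows = []
    for t0 in np.asarray(event_times_s, float):
        i0 = int(round((t0 + window_s[0]) * sample_rate))
        i1 = int(round((t0 + window_s[1]) * sample_rate))
        if i0 < 0 or i1 > x.size:
            continue
        vals = np.empty(steps.size)
        for j, st in enumerate(steps):
            a = int(round((t0 + st) * sample_rate))
            seg = x[a : a + nwin]
            seg = (seg - seg.mean()) * ham
            psd = scale * np.abs(np.fft.rfft(seg)) ** 2
            psd[1:-1] *= 2.0
            vals[j] = psd[keep].mean()
        rows.append(vals)
    values = np.array(rows) if rows else np.empty((0, steps.size))
    return steps + win_dur_s / 2.0, values
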
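"""Phase-amplitude cross-frequency coupling via the entropy-based modulation index.

The modulation index (MI) of a (phase band, amplitude band) pair bins the
instantaneous phase of the slow band into 18 equal bins, computes the mean
fast-band amplitude per bin, normalizes those means to a distribution P,
and reports the Kullback-Leibler distance of P from uniform scaled to
[0, 1]:  MI = (ln N - H(P)) / ln N.  MI is 0 when amplitude is independent
of phase and 1 when all amplitude mass sits in a single phase bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps

from .spectral import BandDef

DEFAULT_N_BINS = 18

#: band pairs reported by default: (phase band, amplitude band)
DEFAULT_PAIRS = [("delta", "theta"), ("theta", "slow_gamma"), ("theta", "fast_gamma")]


@dataclass
class ModulationIndexGrid:
    """Comodulogram: MI over a (phase frequency x amplitude frequency) grid."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray  # [n_amp x n_phase], matching the plotting convention

    def argmax_pair(self) -> tuple[float, float]:
        """(phase_freq, amp_freq) of the grid maximum."""
        i, j = np.unravel_index(np.argmax(self.mi), self.mi.shape)
        return float(self.phase_freqs[j]), float(self.amp_freqs[i])


def bandpass(x: np.ndarray, sample_rate: float, lo: float, hi: float,
             cycles: int = 3) -> np.ndarray:
    """Zero-phase FIR band-pass, order spanning ``cycles`` of the low edge.

    A symmetric (linear-phase) FIR applied by FFT convolution with its
    group delay compensated is exactly zero-phase, which preserves the
    phase estimates downstream.
    """
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got [{lo}, {hi}]")
    if hi >= sample_rate / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist")
    # at least `cycles` periods of the low edge, and long enough that the
    # transition band (~6 fs / numtaps for a Hamming-windowed design) stays
    # well inside the band width
    numtaps = int(round(max(cycles * sample_rate / lo, 6.0 * sample_rate / (hi - lo))))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    if numtaps >= x.size:
        raise ValueError("band too narrow for the signal length (filter longer than data)")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sample_rate)
    return sps.fftconvolve(np.asarray(x, float), taps, mode="same")


def _analytic(x: np.ndarray) -> np.ndarray:
    n_fast = sfft.next_fast_len(x.size)
    return sps.hilbert(x, N=n_fast)[: x.size]


def extract_phase_amplitude(
    x: np.ndarray,
    sample_rate: float,
    phase_band: BandDef,
    amp_band: BandDef,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase of the slow band and amplitude envelope of the fast band."""
    ph = np.angle(_analytic(bandpass(x, sample_rate, phase_band.lo, phase_band.hi)))
    amp = np.abs(_analytic(bandpass(x, sample_rate, amp_band.lo, amp_band.hi)))
    return ph, amp


def phase_bin_means(phase: np.ndarray, amplitude: np.ndarray,
                    n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Mean amplitude per equal phase bin over (-pi, pi], normalized to sum 1."""
    phase = np.asarray(phase, float)
    amplitude = np.asarray(amplitude, float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude: modulation index undefined")
    return means / total


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = DEFAULT_N_BINS) -> float:
    """Entropy-based MI in [0, 1]; 0*log 0 counts as 0."""
    p = phase_bin_means(phase, amplitude, n_bins)
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return (np.log(n_bins) - entropy) / np.log(n_bins)


def band_pair_mi(
    x: np.ndarray,
    sample_rate: float,
    phase_band: BandDef,
    amp_band: BandDef,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    ph, amp = extract_phase_amplitude(x, sample_rate, phase_band, amp_band)
    return modulation_index(ph, amp, n_bins)


def comodulogram(
    x: np.ndarray,
    sample_rate: float,
    phase_freqs: np.ndarray | None = None,
    amp_freqs: np.ndarray | None = None,
    phase_bw: float = 2.0,
    amp_bw: float = 20.0,
    n_bins: int = DEFAULT_N_BINS,
) -> ModulationIndexGrid:
    """MI over a grid of (phase center, amplitude center) frequencies.

    Each phase band is center +- phase_bw/2 and each amplitude band center
    +- amp_bw/2; the amplitude bandwidth must exceed twice the fastest
    phase frequency for the modulation sidebands to pass.
    """
    phase_freqs = np.asarray(
        [2, 4, 6, 8, 10, 12] if phase_freqs is None else phase_freqs, float
    )
    amp_freqs = np.asarray(
        np.arange(20, 101, 10) if amp_freqs is None else amp_freqs, float
    )
    x = np.asarray(x, float)
    # amplitude envelopes are shared across the phase axis: extract once
    envelopes = []
    for fa in amp_freqs:
        lo, hi = max(fa - amp_bw / 2, 0.5), fa + amp_bw / 2
        envelopes.append(np.abs(_analytic(bandpass(x, sample_rate, lo, hi))))
    mi = np.empty((amp_freqs.size, phase_freqs.size))
    for j, fp in enumerate(phase_freqs):
        lo, hi = max(fp - phase_bw / 2, 0.25), fp + phase_bw / 2
        ph = np.angle(_analytic(bandpass(x, sample_rate, lo, hi)))
        for i, env in enumerate(envelopes):
            mi[i, j] = modulation_index(ph, env, n_bins)
    return ModulationIndexGrid(phase_freqs=phase_freqs, amp_freqs=amp_freqs, mi=mi)
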
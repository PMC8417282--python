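"""Phase-amplitude coupling: modulation index limits, oracle agreement,
planted-coupling recovery, comodulograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy as shannon_entropy

from thetadyn import coupling, synth
from thetadyn.coupling import (
    comodulogram,
    extract_phase_amplitude,
    modulation_index,
)
from thetadyn.spectral import band

FS = 1000.0
TWO_BIN_MI = 1.0 - np.log(2) / np.log(18)


def mi_sort_oracle(phase, amplitude, n_bins=18):
    """Direct-sort binning oracle: assign each sample to its bin by explicit
    comparison, average amplitudes, then entropy via scipy."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        hi_ok = phase <= edges[j + 1] if j == n_bins - 1 else phase < edges[j + 1]
        sel = (phase >= edges[j]) & hi_ok
        means.append(amplitude[sel].mean() if sel.any() else 0.0)
    p = np.array(means) / np.sum(means)
    return (np.log(n_bins) - shannon_entropy(p)) / np.log(n_bins)


def _empty_behavior():
    pos = pd.DataFrame(columns=["t_s", "x_cm", "y_cm"])
    ev = pd.DataFrame(
        columns=["trial_index", "delay_start_s", "trial_start_s",
                 "choice_time_s", "return_time_s", "outcome"]
    )
    return pos, ev


def planted_pac_signal(kappa_fg=0.0, kappa_sg=0.0, kappa_dt=0.0, seed=1, dur=200.0):
    pos, ev = _empty_behavior()
    phen = synth.PhenotypeParams(
        theta_amp=1.0,
        delta_amp=0.35,
        pac_depth={
            "delta_theta": kappa_dt,
            "theta_slow_gamma": kappa_sg,
            "theta_fast_gamma": kappa_fg,
        },
        speed_coupling={"theta": 0.0, "delta": 0.0},
    )
    return synth.synthesize_lead_signal(phen, pos, ev, dur, np.random.default_rng(seed))


class TestModulationIndexLimits:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 100_000)
        mi = modulation_index(phase, np.ones_like(phase))
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_mass_gives_one(self):
        phase = np.full(1000, 0.1)
        amplitude = np.ones(1000)
        assert modulation_index(phase, amplitude) == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self):
        # mass split equally over 2 of 18 bins: MI = 1 - ln2/ln18
        phase = np.concatenate([np.full(500, 0.05), np.full(500, 3.0)])
        amplitude = np.ones(1000)
        assert modulation_index(phase, amplitude) == pytest.approx(TWO_BIN_MI, abs=1e-12)

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.linspace(-3, 3, 500), np.zeros(500))


class TestModulationIndexProperties:
    @given(scale=st.floats(0.01, 100.0), rotation=st.floats(-np.pi, np.pi))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_amplitude_scale_and_phase_rotation(self, scale, rotation):
        rng = np.random.default_rng(13)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amplitude = rng.gamma(2.0, 1.0, 5000) * (1 + 0.5 * np.cos(phase))
        base = modulation_index(phase, amplitude)
        rotated = np.angle(np.exp(1j * (phase + rotation)))
        assert modulation_index(phase, scale * amplitude) == pytest.approx(base, abs=1e-12)
        assert modulation_index(rotated, amplitude) == pytest.approx(base, abs=0.02)

    def test_agrees_with_direct_sort_oracle(self):
        rng = np.random.default_rng(21)
        phase = rng.uniform(-np.pi, np.pi, 4000)
        amplitude = rng.gamma(2.0, 1.0, 4000) * (1 + 0.7 * np.cos(phase - 1.0))
        assert modulation_index(phase, amplitude) == pytest.approx(
            mi_sort_oracle(phase, amplitude), abs=1e-10
        )

    def test_mi_always_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            phase = rng.uniform(-np.pi, np.pi, 2000)
            amplitude = rng.gamma(1.0, 1.0, 2000)
            assert 0.0 <= modulation_index(phase, amplitude) <= 1.0


class TestPhaseAmplitudeExtraction:
    def test_pure_theta_tone_phase_advances_one_cycle_per_125ms(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 8 * t)
        ph, _ = extract_phase_amplitude(x, FS, band("theta"), band("fast_gamma"))
        mid = slice(2000, 18000)
        cycles = np.unwrap(ph[mid])
        rate = (cycles[-1] - cycles[0]) / (len(cycles) / FS)
        assert rate == pytest.approx(2 * np.pi * 8, rel=0.01)

    def test_constant_tone_has_flat_envelope(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 40 * t)
        _, amp = extract_phase_amplitude(x, FS, band("theta"), band("slow_gamma"))
        mid = amp[2000:18000]
        assert mid.std() / mid.mean() < 0.02

    def test_planted_pac_amplitude_peaks_at_preferred_phase(self):
        x = planted_pac_signal(kappa_fg=0.8)
        ph, amp = extract_phase_amplitude(x, FS, band("theta"), band("fast_gamma"))
        p = coupling.phase_bin_means(ph, amp)
        centers = np.linspace(-np.pi, np.pi, 19)[:-1] + np.pi / 18
        # planted preferred phase is 0 (envelope max at carrier phase 0)
        assert abs(centers[np.argmax(p)]) < np.pi / 4


class TestPlantedCouplingRecovery:
    def test_no_planted_coupling_gives_near_zero_mi(self):
        x = planted_pac_signal()
        for pb, ab in ((("delta"), ("theta")), (("theta"), ("slow_gamma")),
                       (("theta"), ("fast_gamma"))):
            assert coupling.band_pair_mi(x, FS, band(pb), band(ab)) < 2e-4

    def test_planted_fast_gamma_coupling_exceeds_null_tenfold(self):
        mi0 = coupling.band_pair_mi(
            planted_pac_signal(kappa_fg=0.0), FS, band("theta"), band("fast_gamma")
        )
        mi1 = coupling.band_pair_mi(
            planted_pac_signal(kappa_fg=0.8), FS, band("theta"), band("fast_gamma")
        )
        assert mi1 > 10 * mi0

    def test_mi_monotone_in_planted_depth(self):
        mis = [
            coupling.band_pair_mi(
                planted_pac_signal(kappa_fg=k, seed=5, dur=150.0),
                FS, band("theta"), band("fast_gamma"),
            )
            for k in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert all(b > a for a, b in zip(mis, mis[1:]))


class TestComodulogram:
    def test_white_noise_grid_stays_below_001(self):
        rng = np.random.default_rng(9)
        grid = comodulogram(rng.standard_normal(200_000), FS)
        assert grid.mi.max() < 0.01

    def test_planted_pair_is_grid_argmax(self):
        grid = comodulogram(planted_pac_signal(kappa_sg=0.45, seed=2), FS)
        assert grid.argmax_pair() == (8.0, 40.0)
        grid2 = comodulogram(planted_pac_signal(kappa_fg=0.5, seed=3), FS)
        assert grid2.argmax_pair() == (8.0, 80.0)
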
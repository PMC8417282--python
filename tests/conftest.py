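"""Shared fixtures: a small paper-like synthetic cohort, its analysis tables,
and a well-separated spectra dataset for the decoding protocol."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thetadyn import pipeline, synth
from thetadyn.decoding import build_phenotype_dataset
from thetadyn.session import LeadInfo
from thetadyn.spectral import LeadSpectrum

COHORT_SEED = 1234


@pytest.fixture(scope="session")
def mini_cohort() -> list:
    """Six sessions (3 control, 3 STZ subjects, 20 trials each) with the
    default presets: hippocampal TD gap, PAC elevation, speed coupling and
    outcome-dependent coherence all planted."""
    cfg = synth.default_cohort_config(
        seed=COHORT_SEED, n_trials=20, n_sessions_per_subject=1
    )
    cfg.n_subjects = {"control": 3, "STZ": 3}
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def mini_analysis(mini_cohort) -> dict:
    """Per-session analysis tables for the mini cohort, concatenated."""
    config = pipeline.AnalysisConfig(seed=0)
    parts = [pipeline.analyze_session(s, config) for s in mini_cohort]
    out = {
        key: pd.concat([p[key] for p in parts], ignore_index=True)
        for key in ("band_powers", "speed_correlations", "mi", "trials", "trial_coherence")
    }
    out["spectra"] = [sp for p in parts for sp in p["spectra"]]
    out["leads"] = [li for s in mini_cohort for li in s.leads]
    return out


def separable_spectra(
    n_per_class: int = 120, noise: float = 0.02, seed: int = 0, n_subjects: int = 4
):
    """Four well-separated synthetic classes: distinct spectral peaks, low noise."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(1.0, 101.0)
    peaks = {"ACC-control": 8.0, "HPC-control": 14.0, "ACC-STZ": 22.0, "HPC-STZ": 32.0}
    spectra, leads = [], []
    for label, pk in peaks.items():
        area, group = label.split("-")
        for i in range(n_per_class):
            base = np.exp(-(((freqs - pk) / 3.0) ** 2)) + 0.2 / freqs
            v = np.maximum(base + noise * rng.standard_normal(freqs.size), 1e-9)
            lead_id = f"{label}_{i}"
            subject = f"{group}{i % n_subjects}"
            spectra.append(LeadSpectrum(lead_id, freqs, v / v.sum(), (1.0, 100.0)))
            leads.append(
                LeadInfo(lead_id, subject, f"{subject}_sess{i % 2 + 1}", area, "L", group)
            )
    return spectra, leads


@pytest.fixture(scope="session")
def separable_dataset():
    spectra, leads = separable_spectra()
    return build_phenotype_dataset(spectra, leads)
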
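"""Synthetic delayed-alternation sessions with planted oscillatory structure.

Each lead's voltage trace is built as

    x(t) = pink noise
         + a_delta(t) * cos(phi_delta(t))
         + a_theta(t) * theta_wave(t)
         + sum_gamma A_g * [1 + kappa_g * cos(phi_carrier(t) - phi0_g)] * cos(phi_g(t))

where the band amplitudes are coupled to normalized running speed
(a_theta rises with speed, a_delta falls), the theta wave of every lead in
a hemisphere mixes a shared source with a private one (mixing weight
lambda plants inter-area coherence, shifted on error-trial delay windows),
and the gamma envelopes are modulated by the theta phase (planting
phase-amplitude coupling with depth kappa).  Oscillator phases integrate a
jittered instantaneous frequency so every band has nonzero width, and the
1/f background is spectrally shaped white noise.

Every stream of randomness derives from the master seed through a named
seed sequence per (group, subject, session, lead), so cohorts are
reproducible and adding leads does not perturb existing ones.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from .session import EVENT_COLUMNS, LeadInfo, SessionRecording, delay_category, write_session

PAC_PAIRS = ("delta_theta", "theta_slow_gamma", "theta_fast_gamma")


@dataclass
class PhenotypeParams:
    """Generative parameters for one (group x area) phenotype.

    Amplitudes are in arbitrary units on a common scale with the unit-ish
    1/f background; ``pac_depth`` kappas and the coherence mixing weight
    lambda live in [0, 1]; ``speed_coupling`` betas multiply normalized
    speed (delta beta <= 0, theta beta >= 0 by convention).
    """

    theta_amp: float = 1.0
    delta_amp: float = 0.5
    theta_freq: float = 8.0
    delta_freq: float = 2.5
    slow_gamma_amp: float = 0.3
    slow_gamma_freq: float = 40.0
    fast_gamma_amp: float = 0.25
    fast_gamma_freq: float = 80.0
    pac_depth: dict = field(
        default_factory=lambda: {k: 0.0 for k in PAC_PAIRS}
    )
    speed_coupling: dict = field(default_factory=lambda: {"theta": 1.0, "delta": -0.8})
    coherence_mix: float = 0.45
    coherence_outcome_shift: float = 0.0
    coherence_long_delay_mult: float = 1.0
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    freq_jitter_sd: float = 1.0
    gamma_freq_jitter_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_amp", "delta_amp", "slow_gamma_amp", "fast_gamma_amp", "noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, v in self.pac_depth.items():
            if not 0 <= v <= 1:
                raise ValueError(f"pac_depth[{k}] = {v} outside [0, 1]")
        if not 0 <= self.coherence_mix <= 1:
            raise ValueError(f"coherence_mix = {self.coherence_mix} outside [0, 1]")


@dataclass
class CohortConfig:
    """Cohort structure and behavioral model for :func:`generate_cohort`."""

    n_subjects: dict = field(default_factory=lambda: {"control": 3, "STZ": 5})
    n_sessions_per_subject: int = 4
    n_trials: int = 30
    delay_range_s: tuple[float, float] = (5.0, 45.0)
    accuracy: dict = field(
        default_factory=lambda: {
            "control": {"short": 0.90, "long": 0.85},
            "STZ": {"short": 0.85, "long": 0.60},
        }
    )
    phenotypes: dict = field(default_factory=dict)  # {(group, area): PhenotypeParams}
    seed: int = 0
    sample_rate: float = 1000.0
    position_rate: float = 25.0
    run_speed_cm_s: float = 40.0
    speed_profile: str = "stem_peak"
    leads_per_cell: int = 4

    def __post_init__(self) -> None:
        for group, cats in self.accuracy.items():
            for cat, p in cats.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"accuracy[{group}][{cat}] = {p} outside [0, 1]")
        if not self.phenotypes:
            self.phenotypes = default_phenotypes()


def load_presets() -> dict:
    """Package default ('paper-like') presets from the bundled config file."""
    text = resources.files("thetadyn").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def default_phenotypes() -> dict:
    raw = load_presets()["phenotypes"]
    return {
        (group, area): PhenotypeParams(**params)
        for group, areas in raw.items()
        for area, params in areas.items()
    }


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    raw = copy.deepcopy(load_presets()["cohort"])
    raw["delay_range_s"] = tuple(raw["delay_range_s"])
    raw.update(overrides)
    return CohortConfig(seed=seed, phenotypes=default_phenotypes(), **raw)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _speed_at(arc: float, total: float, v_run: float, profile: str) -> float:
    if profile == "constant":
        return v_run
    # broad bump peaking mid-stem, floor 30% of v_run elsewhere
    s_peak = 15.0 + 63.5 / 2.0
    return 0.3 * v_run + 0.7 * v_run * np.exp(-(((arc - s_peak) / (0.25 * total)) ** 2))


def generate_behavior(
    n_trials: int,
    rng: np.random.Generator,
    accuracy: dict | None = None,
    delay_range_s: tuple[float, float] = (5.0, 45.0),
    path: np.ndarray = beh.DEFAULT_TMAZE_PATH,
    position_rate: float = 25.0,
    run_speed_cm_s: float = 40.0,
    speed_profile: str = "stem_peak",
    inter_trial_gap_s: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positions and event log for one session of delayed alternation.

    Delays are i.i.d. uniform on ``delay_range_s``; the animal sits at the
    delay box during delays and traverses the maze circuit at a
    position-dependent (group-independent) speed during trial runs;
    outcomes are Bernoulli with P(correct | delay category).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    accuracy = accuracy or {"short": 0.85, "long": 0.75}
    dt = 1.0 / position_rate
    total = beh.path_length(path)
    arc_choice = 15.0 + 63.5  # top of stem: the choice point
    box_arc = 0.0  # the sequester box sits at the start (= end) of the circuit

    # position samples stay on one uniform grid; the run starts at the
    # first sample at or after trial_start so speed never shows sampling
    # artifacts at epoch boundaries
    times: list[float] = []
    arcs: list[float] = []
    events = []
    t = 0.0
    for i in range(n_trials):
        delay = float(rng.uniform(*delay_range_s))
        delay_start = t
        trial_start = delay_start + delay
        while t < trial_start:
            times.append(t)
            arcs.append(box_arc)
            t += dt
        s = 0.0
        choice_time = None
        while s < total:
            times.append(t)
            arcs.append(s)
            s += _speed_at(s, total, run_speed_cm_s, speed_profile) * dt
            t += dt
            if choice_time is None and s >= arc_choice:
                choice_time = t
        return_time = t
        cat = delay_category(delay)
        outcome = "correct" if rng.random() < accuracy[cat] else "error"
        events.append(
            {
                "trial_index": i,
                "delay_start_s": delay_start,
                "trial_start_s": trial_start,
                "choice_time_s": choice_time,
                "return_time_s": return_time,
                "outcome": outcome,
            }
        )
        gap_end = return_time + inter_trial_gap_s
        while t < gap_end:
            times.append(t)
            arcs.append(box_arc)
            t += dt
    xy = beh.point_on_path(np.asarray(arcs), path)
    positions = pd.DataFrame(
        {"t_s": np.asarray(times), "x_cm": xy[:, 0], "y_cm": xy[:, 1]}
    )
    return positions, pd.DataFrame(events, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def _smooth_unit_noise(n: int, rng: np.random.Generator, sample_rate: float,
                       smooth_s: float = 0.1) -> np.ndarray:
    """Unit-variance low-pass noise for frequency jitter."""
    w = rng.standard_normal(n)
    m = max(int(smooth_s * sample_rate), 1)
    kernel = np.hanning(m + 2)[1:-1]
    kernel /= kernel.sum()
    from scipy.signal import fftconvolve

    sm = fftconvolve(w, kernel, mode="same")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def oscillator_phase(
    n: int, f0: float, jitter_sd: float, rng: np.random.Generator, sample_rate: float
) -> np.ndarray:
    """Integrated instantaneous frequency f0 + jitter, random initial phase."""
    freq = f0 + jitter_sd * _smooth_unit_noise(n, rng, sample_rate)
    return 2 * np.pi * np.cumsum(freq) / sample_rate + rng.uniform(0, 2 * np.pi)


def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f**exponent noise by spectral shaping of white noise."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def _normalized_speed(positions: pd.DataFrame, n: int, sample_rate: float) -> np.ndarray:
    sp = beh.running_speed(positions)
    t = np.arange(n) / sample_rate
    v = np.interp(t, sp["t_s"], sp["speed_cm_s"])
    vmax = v.max()
    return v / vmax if vmax > 0 else np.zeros(n)


def _lambda_series(
    phen: PhenotypeParams,
    events: pd.DataFrame,
    n: int,
    sample_rate: float,
    delay_window_s: float = 10.0,
    run_window_s: float = 2.0,
) -> np.ndarray:
    """Shared-theta mixing weight over time, shifted on error-trial windows."""
    lam = np.full(n, phen.coherence_mix)
    if phen.coherence_outcome_shift == 0 or not len(events):
        return np.clip(lam, 0.0, 1.0)
    for row in events.itertuples(index=False):
        if row.outcome != "error":
            continue
        shift = phen.coherence_outcome_shift
        if delay_category(row.trial_start_s - row.delay_start_s) == "long":
            shift *= phen.coherence_long_delay_mult
        start = max(row.delay_start_s, row.trial_start_s - delay_window_s)
        stop = row.trial_start_s + run_window_s
        i0 = max(int(round(start * sample_rate)), 0)
        i1 = min(int(round(stop * sample_rate)), n)
        lam[i0:i1] += shift
    return np.clip(lam, 0.0, 1.0)


def synthesize_lead_signal(
    phen: PhenotypeParams,
    positions: pd.DataFrame,
    events: pd.DataFrame,
    duration_s: float,
    rng: np.random.Generator,
    shared_theta_phase: np.ndarray | None = None,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """One lead's voltage trace with the phenotype's planted structure."""
    n = int(round(duration_s * sample_rate))
    vhat = _normalized_speed(positions, n, sample_rate) if len(positions) else np.zeros(n)

    phi_delta = oscillator_phase(n, phen.delta_freq, phen.freq_jitter_sd, rng, sample_rate)
    phi_theta_priv = oscillator_phase(n, phen.theta_freq, phen.freq_jitter_sd, rng, sample_rate)
    phi_sg = oscillator_phase(n, phen.slow_gamma_freq, phen.gamma_freq_jitter_sd, rng, sample_rate)
    phi_fg = oscillator_phase(n, phen.fast_gamma_freq, phen.gamma_freq_jitter_sd, rng, sample_rate)

    beta_d = phen.speed_coupling.get("delta", 0.0)
    beta_t = phen.speed_coupling.get("theta", 0.0)
    a_delta = phen.delta_amp * np.maximum(0.0, 1.0 + beta_d * vhat)
    a_theta = phen.theta_amp * (1.0 + beta_t * vhat)

    if shared_theta_phase is not None:
        if shared_theta_phase.shape[0] != n:
            raise ValueError("shared theta phase length must match the session")
        lam = _lambda_series(phen, events, n, sample_rate)
        z = lam * np.exp(1j * shared_theta_phase) + (1 - lam) * np.exp(1j * phi_theta_priv)
        theta_wave = z.real
        phi_carrier = np.angle(z)
    else:
        theta_wave = np.cos(phi_theta_priv)
        phi_carrier = phi_theta_priv

    kappa_dt = phen.pac_depth.get("delta_theta", 0.0)
    x = a_delta * np.cos(phi_delta)
    x = x + a_theta * (1.0 + kappa_dt * np.cos(phi_delta)) * theta_wave
    for amp, kappa_key, phi_g in (
        (phen.slow_gamma_amp, "theta_slow_gamma", phi_sg),
        (phen.fast_gamma_amp, "theta_fast_gamma", phi_fg),
    ):
        kappa = phen.pac_depth.get(kappa_key, 0.0)
        x = x + amp * (1.0 + kappa * np.cos(phi_carrier)) * np.cos(phi_g)
    if phen.noise_amp > 0:
        x = x + phen.noise_amp * pink_noise(n, rng, phen.noise_exponent)
    return x


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _stream(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *key]))


def generate_session(
    config: CohortConfig, group: str, subject_id: str, session_id: str, key: tuple[int, ...]
) -> SessionRecording:
    """One 16-lead session (4 leads per area x hemisphere) for a group."""
    rng_beh = _stream(config.seed, *key, 0)
    positions, events = generate_behavior(
        config.n_trials,
        rng_beh,
        accuracy=config.accuracy[group],
        delay_range_s=config.delay_range_s,
        position_rate=config.position_rate,
        run_speed_cm_s=config.run_speed_cm_s,
        speed_profile=config.speed_profile,
    )
    duration = float(events["return_time_s"].iloc[-1]) + 1.5
    n = int(round(duration * config.sample_rate))
    positions = positions[positions["t_s"] < duration].reset_index(drop=True)

    theta_freq = config.phenotypes[(group, "HPC")].theta_freq
    jitter = config.phenotypes[(group, "HPC")].freq_jitter_sd
    shared = {
        hemi: oscillator_phase(
            n, theta_freq, jitter, _stream(config.seed, *key, 1, hi), config.sample_rate
        )
        for hi, hemi in enumerate(("L", "R"))
    }

    leads: list[LeadInfo] = []
    signals = np.empty((0, n), dtype=np.float32)
    rows = []
    lead_idx = 0
    for area in ("ACC", "HPC"):
        phen = config.phenotypes[(group, area)]
        for hemi in ("L", "R"):
            for k in range(config.leads_per_cell):
                lead_id = f"{session_id}_{area}{hemi}{k + 1}"
                leads.append(
                    LeadInfo(lead_id, subject_id, session_id, area, hemi, group)
                )
                rng = _stream(config.seed, *key, 2, lead_idx)
                sig = synthesize_lead_signal(
                    phen, positions, events, duration, rng,
                    shared_theta_phase=shared[hemi], sample_rate=config.sample_rate,
                )
                rows.append(sig.astype(np.float32))
                lead_idx += 1
    signals = np.vstack(rows)
    return SessionRecording(
        signals=signals,
        sample_rate=config.sample_rate,
        leads=leads,
        positions=positions,
        events=events,
        session_id=session_id,
    )


def iter_cohort(config: CohortConfig):
    """Yield the cohort's sessions one at a time (deterministic given seed)."""
    for gi, group in enumerate(sorted(config.n_subjects)):
        prefix = "c" if group == "control" else "s"
        for si in range(config.n_subjects[group]):
            subject_id = f"{prefix}{si + 1}"
            for sj in range(config.n_sessions_per_subject):
                session_id = f"{subject_id}_sess{sj + 1}"
                yield generate_session(config, group, subject_id, session_id, (gi, si, sj))


def generate_cohort(config: CohortConfig) -> list[SessionRecording]:
    return list(iter_cohort(config))


def write_cohort(config: CohortConfig, out_dir: str | Path) -> list[Path]:
    """Generate the cohort and write one session directory per session."""
    out_dir = Path(out_dir)
    paths = []
    for session in iter_cohort(config):
        p = out_dir / session.session_id
        write_session(session, p)
        paths.append(p)
    return paths
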
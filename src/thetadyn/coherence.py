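"""Inter-area magnitude-squared coherence and trial-outcome difference scores.

Magnitude-squared coherence C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)) is
estimated from Welch-averaged cross and auto spectra, always between an
ipsilateral ACC lead and a hippocampal lead.  Per-trial theta coherence is
the mean of C_xy over 6-13 Hz across the last 10 s of the delay period plus
the first 2 s of the trial run (a contiguous 12 s window), averaged over
all ipsilateral ACC x HPC lead pairs.  A session's difference score is the
mean error-trial theta coherence divided by the mean correct-trial theta
coherence; scores above 1 mean coherence was higher before errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import SessionRecording, build_trial_table
from .spectral import BANDS

THETA = BANDS["theta"]
DELAY_WINDOW_S = 10.0
RUN_WINDOW_S = 2.0


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    c: np.ndarray


def msc(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate: float,
    nperseg: int = 1000,
    noverlap: int | None = None,
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence with Hamming segments.

    Requires at least two segments: a single segment yields the degenerate
    estimate C = 1 at every frequency, which is rejected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if noverlap is None:
        noverlap = nperseg // 2
    if x.size < nperseg + (nperseg - noverlap):
        raise ValueError(
            f"need >= 2 segments of {nperseg} samples (hop {nperseg - noverlap}); "
            f"got {x.size} samples"
        )
    freqs, c = sps.coherence(
        x, y, fs=sample_rate, window=sps.get_window("hamming", nperseg),
        nperseg=nperseg, noverlap=noverlap, detrend="constant",
    )
    return CoherenceSpectrum(freqs=freqs, c=np.clip(c, 0.0, 1.0))


def band_coherence(cs: CoherenceSpectrum, band: tuple[float, float] = THETA) -> float:
    keep = (cs.freqs >= band[0]) & (cs.freqs <= band[1])
    return float(cs.c[keep].mean())


def ipsilateral_pairs(session: SessionRecording) -> list[tuple[int, int]]:
    """All (ACC lead, HPC lead) index pairs within a hemisphere."""
    pairs = []
    for hemi in ("L", "R"):
        acc = session.leads_where(area="ACC", hemisphere=hemi)
        hpc = session.leads_where(area="HPC", hemisphere=hemi)
        pairs.extend((a, h) for a in acc for h in hpc)
    if not pairs:
        raise ValueError("session has no ipsilateral ACC x HPC lead pairs")
    return pairs


def trial_theta_coherence(
    session: SessionRecording,
    trial: pd.Series,
    theta: tuple[float, float] = THETA,
    nperseg: int = 1000,
) -> dict:
    """Mean ipsilateral ACC-HPC theta coherence in one trial's analysis window.

    The window is [trial_start - 10 s, trial_start + 2 s), truncated at
    delay_start when the delay is shorter than 10 s (flagged in the output).
    """
    fs = session.sample_rate
    start = max(float(trial.delay_start_s), float(trial.trial_start_s) - DELAY_WINDOW_S)
    stop = float(trial.trial_start_s) + RUN_WINDOW_S
    i0, i1 = int(round(start * fs)), int(round(stop * fs))
    i1 = min(i1, session.n_samples)
    vals = []
    for a, h in ipsilateral_pairs(session):
        cs = msc(session.signals[a, i0:i1], session.signals[h, i0:i1], fs, nperseg=nperseg)
        vals.append(band_coherence(cs, theta))
    return {
        "trial_index": int(trial.trial_index),
        "theta_coherence": float(np.mean(vals)),
        "outcome": str(trial.outcome),
        "delay_s": float(trial.trial_start_s) - float(trial.delay_start_s),
        "truncated": float(trial.trial_start_s) - float(trial.delay_start_s) < DELAY_WINDOW_S,
    }


def session_trial_coherence(session: SessionRecording, **kwargs) -> pd.DataFrame:
    """Per-trial theta coherence table for one session (adds delay_category)."""
    trials = build_trial_table(session.events)
    rows = [trial_theta_coherence(session, tr, **kwargs) for _, tr in trials.iterrows()]
    out = pd.DataFrame(rows)
    if len(out):
        out["delay_category"] = trials["delay_category"].to_numpy()
        out["session_id"] = session.session_id
        out["group"] = session.group
    return out


def difference_scores(
    trial_coherence: pd.DataFrame,
    split_by_delay: bool = False,
    min_trials: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-session error/correct coherence ratio; excluded sessions are listed.

    Unsplit scores need >= 1 trial of each outcome; the delay-split variant
    needs >= 3 trials in each (outcome x delay category) cell, mirroring the
    session filter used for delay-resolved comparisons.
    """
    if min_trials is None:
        min_trials = 3 if split_by_delay else 1
    scores, excluded = [], []
    for sid, tab in trial_coherence.groupby("session_id", sort=True):
        cats = ["short", "long"] if split_by_delay else [None]
        ok = all(
            (tab[(tab.outcome == oc) & ((tab.delay_category == cat) if cat else True)].shape[0]
             >= min_trials)
            for oc in ("correct", "error")
            for cat in cats
        )
        if not ok:
            excluded.append(str(sid))
            continue
        for cat in cats:
            sub = tab if cat is None else tab[tab.delay_category == cat]
            corr = sub.loc[sub.outcome == "correct", "theta_coherence"].mean()
            err = sub.loc[sub.outcome == "error", "theta_coherence"].mean()
            if corr <= 0:
                raise ValueError(f"session {sid}: zero mean correct-trial coherence")
            scores.append(
                {
                    "session_id": str(sid),
                    "group": tab["group"].iloc[0] if "group" in tab else "",
                    "delay_category": cat if cat else "all",
                    "score": err / corr,
                    "n_correct": int((sub.outcome == "correct").sum()),
                    "n_error": int((sub.outcome == "error").sum()),
                }
            )
    return pd.DataFrame(scores), excluded


def peri_event_cohereogram(
    session: SessionRecording,
    lead_pair: tuple[int, int],
    event_times_s: np.ndarray,
    window_s: tuple[float, float] = (-10.0, 4.0),
    step_s: float = 0.5,
    seg_dur_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked coherence over time and frequency, pooled across trials.

    At each time step the 1 s segments from all events form the averaging
    ensemble: C(t, f) = |sum_k X_k Y_k*|^2 / (sum_k |X_k|^2 sum_k |Y_k|^2).
    Returns (step_centers_s, freqs, c[n_freqs x n_steps]).  Events whose
    window extends outside the recording are dropped; with no complete
    window the coherence matrix is empty.
    """
    fs = session.sample_rate
    a, b = lead_pair
    nseg = int(round(seg_dur_s * fs))
    ham = sps.get_window("hamming", nseg)
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    steps = np.arange(window_s[0], window_s[1] - seg_dur_s + 1e-9, step_s)
    events = [
        t for t in np.asarray(event_times_s, float)
        if (t + window_s[0]) * fs >= 0 and (t + window_s[1]) * fs <= session.n_samples
    ]
    if not events:
        return steps + seg_dur_s / 2, freqs, np.empty((freqs.size, 0))
    c = np.empty((freqs.size, steps.size))
    for j, st in enumerate(steps):
        sxy = np.zeros(freqs.size, complex)
        sxx = np.zeros(freqs.size)
        syy = np.zeros(freqs.size)
        for t0 in events:
            i0 = int(round((t0 + st) * fs))
            xa = session.signals[a, i0 : i0 + nseg].astype(float)
            xb = session.signals[b, i0 : i0 + nseg].astype(float)
            fa = np.fft.rfft((xa - xa.mean()) * ham)
            fb = np.fft.rfft((xb - xb.mean()) * ham)
            sxy += fa * np.conj(fb)
            sxx += np.abs(fa) ** 2
            syy += np.abs(fb) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            cj = np.abs(sxy) ** 2 / (sxx * syy)
        c[:, j] = np.clip(np.nan_to_num(cj), 0.0, 1.0)
    return steps + seg_dur_s / 2, freqs, c
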
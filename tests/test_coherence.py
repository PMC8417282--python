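"""Magnitude-squared coherence, per-trial theta coherence, difference scores."""

import numpy as np
import pandas as pd
import pytest

from thetadyn import coherence as coh
from thetadyn import synth
from thetadyn.session import LeadInfo, SessionRecording

FS = 1000.0


def _two_lead_session(x, y, positions=None, events=None):
    leads = [
        LeadInfo("acc1", "subj", "sess", "ACC", "L", "control"),
        LeadInfo("hpc1", "subj", "sess", "HPC", "L", "control"),
    ]
    positions = positions if positions is not None else pd.DataFrame(
        {"t_s": [0.0, 1.0], "x_cm": [0.0, 0.0], "y_cm": [0.0, 0.0]}
    )
    events = events if events is not None else pd.DataFrame(
        columns=["trial_index", "delay_start_s", "trial_start_s",
                 "choice_time_s", "return_time_s", "outcome"]
    )
    sig = np.vstack([x, y]).astype(np.float32)
    return SessionRecording(sig, FS, leads, positions, events, "sess")


class TestMsc:
    def test_identical_signals_have_unit_coherence(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20000)
        cs = coh.msc(x, x.copy(), FS)
        assert np.allclose(cs.c, 1.0, atol=1e-9)

    def test_independent_white_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50_000)
        y = rng.standard_normal(50_000)
        cs = coh.msc(x, y, FS)
        assert cs.c.mean() < 0.1

    def test_shared_theta_source_peaks_at_theta(self):
        rng = np.random.default_rng(2)
        n = 60_000
        lam = 0.7
        shared = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(10), FS)
        def lead(seed):
            priv = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(seed), FS)
            return lam * np.cos(shared) + (1 - lam) * np.cos(priv) \
                + 0.5 * np.random.default_rng(seed + 1).standard_normal(n)
        cs = coh.msc(lead(3), lead(7), FS)
        c8 = cs.c[cs.freqs == 8.0][0]
        c30 = cs.c[cs.freqs == 30.0][0]
        assert c8 > c30

    def test_invariant_to_independent_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20000)
        y = x + rng.standard_normal(20000)
        a = coh.msc(x, y, FS)
        b = coh.msc(5.0 * x, 0.2 * y, FS)
        assert np.allclose(a.c, b.c, atol=1e-9)

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            coh.msc(np.zeros(1200), np.zeros(1200), FS)


class TestTrialCoherence:
    def test_identical_signals_give_unit_trial_coherence(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30_000)
        events = pd.DataFrame(
            [{"trial_index": 0, "delay_start_s": 2.0, "trial_start_s": 20.0,
              "choice_time_s": 22.0, "return_time_s": 25.0, "outcome": "correct"}]
        )
        s = _two_lead_session(x, x.copy(), events=events)
        res = coh.trial_theta_coherence(s, events.iloc[0])
        assert res["theta_coherence"] == pytest.approx(1.0, abs=1e-9)
        assert not res["truncated"]

    def test_short_delay_window_truncated_and_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30_000)
        events = pd.DataFrame(
            [{"trial_index": 0, "delay_start_s": 10.0, "trial_start_s": 16.0,
              "choice_time_s": 18.0, "return_time_s": 20.0, "outcome": "correct"}]
        )
        s = _two_lead_session(x, rng.standard_normal(30_000), events=events)
        res = coh.trial_theta_coherence(s, events.iloc[0])
        assert res["truncated"]
        assert 0.0 <= res["theta_coherence"] <= 1.0

    def test_unmixed_leads_stay_near_noise_baseline(self):
        # lambda = 0: no shared source, coherence ~ estimator bias only
        n = 30_000
        events = pd.DataFrame(
            [{"trial_index": 0, "delay_start_s": 2.0, "trial_start_s": 20.0,
              "choice_time_s": 22.0, "return_time_s": 25.0, "outcome": "correct"}]
        )
        def lead(seed):
            priv = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(seed), FS)
            return np.cos(priv) + 0.5 * np.random.default_rng(seed + 50).standard_normal(n)
        s = _two_lead_session(lead(1), lead(2), events=events)
        res = coh.trial_theta_coherence(s, events.iloc[0])
        assert res["theta_coherence"] < 0.2

    def test_monotone_in_planted_mixing_weight(self):
        n = 30_000
        events = pd.DataFrame(
            [{"trial_index": 0, "delay_start_s": 2.0, "trial_start_s": 20.0,
              "choice_time_s": 22.0, "return_time_s": 25.0, "outcome": "correct"}]
        )
        shared = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(0), FS)
        vals = []
        for lam in (0.0, 0.4, 0.8):
            def lead(seed):
                priv = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(seed), FS)
                wave = lam * np.cos(shared) + (1 - lam) * np.cos(priv)
                return wave + 0.4 * np.random.default_rng(seed + 9).standard_normal(n)
            s = _two_lead_session(lead(11), lead(22), events=events)
            vals.append(coh.trial_theta_coherence(s, events.iloc[0])["theta_coherence"])
        assert vals[0] < vals[1] < vals[2]


class TestDifferenceScores:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows)

    def test_ratio_arithmetic(self):
        tab = self._table(
            [{"session_id": "s", "group": "STZ", "outcome": "error",
              "delay_category": "short", "theta_coherence": 0.6},
             {"session_id": "s", "group": "STZ", "outcome": "correct",
              "delay_category": "short", "theta_coherence": 0.5}]
        )
        scores, excluded = coh.difference_scores(tab)
        assert scores.score.iloc[0] == pytest.approx(1.2)
        assert excluded == []

    def test_identical_outcome_distributions_score_one(self):
        rows = []
        for oc in ("correct", "error"):
            for v in (0.3, 0.5, 0.7):
                rows.append({"session_id": "s", "group": "control", "outcome": oc,
                             "delay_category": "short", "theta_coherence": v})
        scores, _ = coh.difference_scores(self._table(rows))
        assert scores.score.iloc[0] == pytest.approx(1.0)

    def test_equivariance_under_global_scaling(self):
        rng = np.random.default_rng(8)
        rows = [
            {"session_id": "s", "group": "STZ",
             "outcome": "error" if i % 3 == 0 else "correct",
             "delay_category": "short" if i % 2 else "long",
             "theta_coherence": float(rng.uniform(0.1, 0.9))}
            for i in range(24)
        ]
        tab = self._table(rows)
        s1, _ = coh.difference_scores(tab)
        tab2 = tab.copy()
        tab2["theta_coherence"] *= 0.37
        s2, _ = coh.difference_scores(tab2)
        assert s1.score.iloc[0] == pytest.approx(s2.score.iloc[0])

    def test_split_filter_requires_three_per_cell_and_accounts_for_all(self):
        rows = []
        # session "keep": 3 trials in each of the 4 cells; session "drop": missing cell
        for sid, full in (("keep", True), ("drop", False)):
            for oc in ("correct", "error"):
                for cat in ("short", "long"):
                    n = 3 if (full or not (oc == "error" and cat == "long")) else 1
                    for i in range(n):
                        rows.append({"session_id": sid, "group": "STZ", "outcome": oc,
                                     "delay_category": cat,
                                     "theta_coherence": 0.4 + 0.1 * i})
        scores, excluded = coh.difference_scores(self._table(rows), split_by_delay=True)
        retained = set(scores.session_id)
        assert retained == {"keep"}
        assert excluded == ["drop"]
        assert len(retained) + len(excluded) == 2


class TestPeriEventCohereogram:
    def _session_with_delay_coherence(self, lam_delay, lam_other, n_trials=6):
        rng = np.random.default_rng(30)
        pos, ev = synth.generate_behavior(
            n_trials, rng, delay_range_s=(15.0, 30.0), accuracy={"short": 1.0, "long": 1.0}
        )
        dur = float(ev.return_time_s.iloc[-1]) + 1.5
        n = int(round(dur * FS))
        shared = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(31), FS)
        lam = np.full(n, lam_other)
        for row in ev.itertuples(index=False):
            i0 = int((row.trial_start_s - 10.0) * FS)
            i1 = int(row.trial_start_s * FS)
            lam[i0:i1] = lam_delay
        def lead(seed):
            priv = synth.oscillator_phase(n, 8.0, 1.0, np.random.default_rng(seed), FS)
            wave = lam * np.cos(shared) + (1 - lam) * np.cos(priv)
            return wave + 0.4 * np.random.default_rng(seed + 3).standard_normal(n)
        return _two_lead_session(lead(41), lead(42), events=ev,
                                 positions=pd.DataFrame({"t_s": [0.0, 1.0],
                                                         "x_cm": [0, 0], "y_cm": [0, 0]})), ev

    def test_constant_mixing_gives_flat_cohereogram(self):
        s, ev = self._session_with_delay_coherence(0.7, 0.7)
        steps, freqs, c = coh.peri_event_cohereogram(
            s, (0, 1), ev.trial_start_s.to_numpy()
        )
        theta = c[(freqs >= 6) & (freqs <= 13)].mean(axis=0)
        assert theta.max() - theta.min() < 0.45  # no systematic structure
        assert theta.std() < 0.15

    def test_delay_restricted_mixing_elevates_pre_trial_theta_only(self):
        s, ev = self._session_with_delay_coherence(0.85, 0.0)
        steps, freqs, c = coh.peri_event_cohereogram(
            s, (0, 1), ev.trial_start_s.to_numpy()
        )
        theta = c[(freqs >= 6) & (freqs <= 13)].mean(axis=0)
        pre = theta[(steps > -9) & (steps < -1)].mean()
        post = theta[steps > 1].mean()
        assert pre > post + 0.2

    def test_no_complete_window_returns_empty(self):
        rng = np.random.default_rng(50)
        x = rng.standard_normal(8000)
        s = _two_lead_session(x, rng.standard_normal(8000))
        _, _, c = coh.peri_event_cohereogram(s, (0, 1), np.array([1.0]))
        assert c.shape[1] == 0
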
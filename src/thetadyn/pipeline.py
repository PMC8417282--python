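"""End-to-end cohort analysis: spectral -> behavior -> coupling -> coherence ->
decoding -> statistics, with CSV tables and a reproducibility manifest.

Per session the pipeline notch-filters every lead, computes its
spectrogram and normalized session PSD, per-area band powers and TD
ratios, per-lead speed-power correlations, per-area modulation indices
for the default band pairs, and the per-trial inter-area theta coherence
table.  Cohort-level stages then aggregate: accuracy by delay, coherence
difference scores, the spectral-phenotype decoding protocol, and group
statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import coherence as coh
from . import coupling, decoding, spectral, stats
from .session import SessionRecording, build_trial_table, read_session

log = logging.getLogger("thetadyn")


@dataclass
class AnalysisConfig:
    seed: int = 0
    norm_range: tuple[float, float] = spectral.NORM_RANGE_SUMMARY
    decoding_range: tuple[float, float] = spectral.NORM_RANGE_DECODING
    mi_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(coupling.DEFAULT_PAIRS)
    )
    decode_n_iter: int = 200
    decode_sizes: tuple[int, ...] | None = None  # None -> feasible subset of 5..85
    null_n_iter: int = 200
    run_decoding: bool = True
    run_coherence: bool = True


def analyze_session(session: SessionRecording, config: AnalysisConfig) -> dict:
    """All per-session measures; returns tables keyed by stage."""
    fs = session.sample_rate
    sp = beh.running_speed(session.positions)
    spectra = []
    band_rows = []
    corr_rows = []
    mi_rows = []
    for i, li in enumerate(session.leads):
        x = spectral.notch_60hz(session.signals[i], fs)
        spec = spectral.compute_spectrogram(x, fs)
        spectra.append(spectral.session_psd(spec, config.norm_range, lead_id=li.lead_id))
        powers = {
            name: spectral.band_power(spec.power, spec.freqs, spectral.band(name), per_frame=True)
            for name in spectral.BANDS
        }
        band_rows.append(
            {
                "session_id": session.session_id,
                "group": li.group,
                "area": li.area,
                "lead_id": li.lead_id,
                **{name: float(np.mean(v)) for name, v in powers.items()},
                "td_ratio": spectral.td_ratio(
                    float(np.mean(powers["theta"])), float(np.mean(powers["delta"]))
                ),
            }
        )
        td_series = spectral.td_ratio(powers["theta"], powers["delta"])
        for name, series in (("delta", powers["delta"]), ("theta", powers["theta"]),
                             ("td_ratio", td_series)):
            corr_rows.append(
                {
                    "session_id": session.session_id,
                    "group": li.group,
                    "area": li.area,
                    "lead_id": li.lead_id,
                    "measure": name,
                    "r": stats.speed_power_correlation(
                        series, spec.frame_times, sp["t_s"], sp["speed_cm_s"]
                    ),
                }
            )
        for pair in config.mi_pairs:
            mi_rows.append(
                {
                    "session_id": session.session_id,
                    "group": li.group,
                    "area": li.area,
                    "lead_id": li.lead_id,
                    "pair": f"{pair[0]}->{pair[1]}",
                    "mi": coupling.band_pair_mi(
                        x, fs, spectral.band(pair[0]), spectral.band(pair[1])
                    ),
                }
            )
    trials = build_trial_table(session.events)
    trials["session_id"] = session.session_id
    trials["group"] = session.group
    out = {
        "spectra": spectra,
        "band_powers": pd.DataFrame(band_rows),
        "speed_correlations": pd.DataFrame(corr_rows),
        "mi": pd.DataFrame(mi_rows),
        "trials": trials,
    }
    if config.run_coherence:
        out["trial_coherence"] = coh.session_trial_coherence(session)
    return out


def _feasible_sizes(class_counts: np.ndarray, requested: tuple[int, ...] | None) -> list[int]:
    sizes = requested or decoding.DEFAULT_SIZES
    return [s for s in sizes if s < class_counts.min()]


def run_full_analysis(
    cohort_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Analyze every session directory under ``cohort_dir``; write a report bundle."""
    config = config or AnalysisConfig()
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session_paths = sorted(p for p in cohort_dir.iterdir() if (p / "signals.json").exists())
    if not session_paths:
        raise FileNotFoundError(f"no session directories under {cohort_dir}")

    all_spectra, all_leads = [], []
    tables: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("band_powers", "speed_correlations", "mi", "trials", "trial_coherence")
    }
    t0 = time.time()
    for p in session_paths:
        session = read_session(p)
        log.info("analyzing session %s (%d leads, %.0f s)",
                 session.session_id, session.n_leads, session.duration_s)
        res = analyze_session(session, config)
        all_spectra.extend(res["spectra"])
        all_leads.extend(session.leads)
        for k in tables:
            if k in res:
                tables[k].append(res[k])
    report: dict = {}
    for k, parts in tables.items():
        if parts:
            report[k] = pd.concat(parts, ignore_index=True)

    report["accuracy"] = beh.accuracy_by_delay(
        report["trials"], by=["group", "delay_category"]
    )
    if "trial_coherence" in report:
        scores, excluded = coh.difference_scores(report["trial_coherence"])
        split_scores, split_excluded = coh.difference_scores(
            report["trial_coherence"], split_by_delay=True
        )
        report["difference_scores"] = scores
        report["difference_scores_by_delay"] = split_scores
        report["coherence_exclusions"] = pd.DataFrame(
            {"session_id": excluded + split_excluded,
             "analysis": ["all"] * len(excluded) + ["by_delay"] * len(split_excluded)}
        )

    groups = {li.group for li in all_leads}
    if config.run_decoding and len(groups) == 2:
        ds = decoding.build_phenotype_dataset(all_spectra, all_leads, config.decoding_range)
        counts = np.array([v.size for v in ds.class_indices().values()])
        sizes = _feasible_sizes(counts, config.decode_sizes)
        if sizes:
            sweep = decoding.training_size_sweep(
                ds, tuple(sizes), n_iter=config.decode_n_iter, seed=config.seed
            )
            report["decoding_sweep"] = pd.DataFrame(
                {
                    "size": size,
                    "mean_accuracy": r.mean_accuracy,
                    "sd_accuracy": float(r.accuracies.std()),
                    **{f"mis_{k}": v for k, v in r.misclass.items()},
                }
                for size, r in sweep.items()
            )
            null = decoding.shuffled_null(
                ds, size=max(sizes), n_iter=config.null_n_iter, seed=config.seed
            )
            report["decoding_null"] = pd.DataFrame(
                [{"size": max(sizes), "mean_accuracy": null.mean_accuracy,
                  "ci_lo": float(np.quantile(null.accuracies, 0.025)),
                  "ci_hi": float(np.quantile(null.accuracies, 0.975)),
                  **{f"mis_{k}": v for k, v in null.misclass.items()}}]
            )
        else:
            log.warning("decoding skipped: too few leads per class for any training size")
    elif config.run_decoding:
        log.warning("decoding skipped: cohort has a single group (%s)", groups)

    for name, df in report.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out_dir / f"{name}.csv", index=False, lineterminator="\n")
    spectra_df = pd.DataFrame(
        {sp.lead_id: sp.norm_power for sp in all_spectra},
        index=pd.Index(all_spectra[0].freqs, name="freq_hz"),
    )
    spectra_df.to_csv(out_dir / "lead_spectra.csv", lineterminator="\n")
    manifest = {
        "seed": config.seed,
        "n_sessions": len(session_paths),
        "norm_range_hz": list(config.norm_range),
        "decoding_range_hz": list(config.decoding_range),
        "decode_n_iter": config.decode_n_iter,
        "null_n_iter": config.null_n_iter,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    report["manifest"] = manifest
    return report
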
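"""Session data model and on-disk format.

A *session* is one behavioral recording: a multi-lead continuous voltage
matrix on a single time base, per-lead metadata, an animal position trace,
and a trial event log for the delayed-alternation task.  The on-disk layout
is a plain directory of text files plus one raw float32 signal file so that
a session round-trips byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

AREAS = ("ACC", "HPC")
HEMISPHERES = ("L", "R")
GROUPS = ("control", "STZ")
OUTCOMES = ("correct", "error")

#: delays at or above this many seconds are "long", below it "short"
DELAY_SPLIT_S = 20.0

EVENT_COLUMNS = [
    "trial_index",
    "delay_start_s",
    "trial_start_s",
    "choice_time_s",
    "return_time_s",
    "outcome",
]
POSITION_COLUMNS = ["t_s", "x_cm", "y_cm"]
LEAD_COLUMNS = ["lead_id", "subject_id", "session_id", "area", "hemisphere", "group"]


class FormatError(IOError):
    """A session directory is missing a file or has a malformed one."""


class ValidationError(ValueError):
    """A session violates a structural invariant (named in the message)."""


@dataclass(frozen=True)
class LeadInfo:
    """Metadata for one recording lead (a single tetrode wire)."""

    lead_id: str
    subject_id: str
    session_id: str
    area: str
    hemisphere: str
    group: str

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"lead {self.lead_id}: area {self.area!r} not in {AREAS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"lead {self.lead_id}: hemisphere {self.hemisphere!r} not in {HEMISPHERES}"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"lead {self.lead_id}: group {self.group!r} not in {GROUPS}")


@dataclass
class SessionRecording:
    """One session: signals [n_leads x n_samples] in microvolts at ``sample_rate`` Hz."""

    signals: np.ndarray
    sample_rate: float
    leads: list[LeadInfo]
    positions: pd.DataFrame
    events: pd.DataFrame
    session_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float32)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be a 2-D [n_leads x n_samples] matrix")
        if not self.session_id and self.leads:
            self.session_id = self.leads[0].session_id
        self.validate()

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def group(self) -> str:
        return self.leads[0].group if self.leads else ""

    def lead_index(self, lead_id: str) -> int:
        for i, li in enumerate(self.leads):
            if li.lead_id == lead_id:
                return i
        raise KeyError(lead_id)

    def leads_where(self, area: str | None = None, hemisphere: str | None = None) -> list[int]:
        """Row indices of leads matching the given area and/or hemisphere."""
        out = []
        for i, li in enumerate(self.leads):
            if area is not None and li.area != area:
                continue
            if hemisphere is not None and li.hemisphere != hemisphere:
                continue
            out.append(i)
        return out

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if len(self.leads) != self.n_leads:
            raise ValidationError(
                f"{len(self.leads)} lead records for {self.n_leads} signal rows"
            )
        ids = [li.lead_id for li in self.leads]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate lead_id within session")
        pos = self.positions
        if len(pos):
            t = pos["t_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError("position timestamps must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration_s:
                raise ValidationError("position timestamps outside the recorded interval")
        validate_events(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionRecording):
            return NotImplemented
        return (
            self.sample_rate == other.sample_rate
            and self.session_id == other.session_id
            and self.leads == other.leads
            and np.array_equal(self.signals, other.signals)
            and self.positions.equals(other.positions)
            and self.events.equals(other.events)
        )


def validate_events(events: pd.DataFrame) -> None:
    """Check ordering invariants of a trial event log.

    Each trial must satisfy delay_start < trial_start < choice_time <
    return_time, trials must be in order and non-overlapping, and outcomes
    must be 'correct' or 'error'.
    """
    if not len(events):
        return
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"events table missing columns {missing}")
    prev_end = -np.inf
    for row in events.itertuples(index=False):
        tag = f"trial {int(row.trial_index)}"
        if not (row.delay_start_s < row.trial_start_s < row.choice_time_s < row.return_time_s):
            raise ValidationError(f"{tag}: event times out of order")
        if row.delay_start_s < prev_end:
            raise ValidationError(f"{tag}: overlaps the previous trial")
        if row.outcome not in OUTCOMES:
            raise ValidationError(f"{tag}: outcome {row.outcome!r} not in {OUTCOMES}")
        prev_end = row.return_time_s


def delay_category(delay_s: float | np.ndarray) -> np.ndarray | str:
    """'short' for delays below 20 s, 'long' at or above.

    The split point itself is assigned to 'long' so the two categories
    partition [5, 45] s with no gap.
    """
    arr = np.where(np.asarray(delay_s, float) < DELAY_SPLIT_S, "short", "long")
    return arr if arr.ndim else str(arr)


def build_trial_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial table with delay length, delay category, and outcome."""
    validate_events(events)
    out = events.copy().reset_index(drop=True)
    out["delay_s"] = out["trial_start_s"] - out["delay_start_s"]
    out["delay_category"] = delay_category(out["delay_s"].to_numpy())
    return out


def _write_csv(df: pd.DataFrame, path: Path, columns: Sequence[str]) -> None:
    # %.17g round-trips float64 exactly; round_trip parsing on the way back
    df.to_csv(path, index=False, columns=list(columns), lineterminator="\n",
              float_format="%.17g")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write a session directory (deterministic: byte-identical on rewrite)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(session.signals, dtype="<f4")
    sig.tofile(path / "signals.f32")
    sidecar = {
        "n_leads": int(session.n_leads),
        "n_samples": int(session.n_samples),
        "sample_rate_hz": float(session.sample_rate),
        "dtype": "float32",
        "byte_order": "little",
        "session_id": session.session_id,
    }
    (path / "signals.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1) + "\n")
    leads_df = pd.DataFrame([vars(li) for li in session.leads], columns=LEAD_COLUMNS)
    _write_csv(leads_df, path / "leads.csv", LEAD_COLUMNS)
    _write_csv(session.positions, path / "positions.csv", POSITION_COLUMNS)
    _write_csv(session.events, path / "events.csv", EVENT_COLUMNS)


def read_session(path: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    for name in ("signals.f32", "signals.json", "leads.csv", "positions.csv", "events.csv"):
        if not (path / name).exists():
            raise FormatError(f"session directory {path} is missing {name}")
    sidecar = json.loads((path / "signals.json").read_text())
    n_leads, n_samples = int(sidecar["n_leads"]), int(sidecar["n_samples"])
    sig = np.fromfile(path / "signals.f32", dtype="<f4")
    if sig.size != n_leads * n_samples:
        raise FormatError(
            f"signals.f32 holds {sig.size} values, sidecar promises {n_leads}x{n_samples}"
        )
    leads_df = pd.read_csv(path / "leads.csv", dtype=str)
    leads = [LeadInfo(**row) for row in leads_df.to_dict("records")]
    positions = _read_csv(path / "positions.csv").astype(
        {c: np.float64 for c in POSITION_COLUMNS}
    )
    events = _read_csv(path / "events.csv")
    if not len(events):
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = events.astype(
            {"trial_index": np.int64,
             **{c: np.float64 for c in EVENT_COLUMNS[1:-1]},
             "outcome": str}
        )
    return SessionRecording(
        signals=sig.reshape(n_leads, n_samples),
        sample_rate=float(sidecar["sample_rate_hz"]),
        leads=leads,
        positions=positions,
        events=events,
        session_id=str(sidecar.get("session_id", "")),
    )
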
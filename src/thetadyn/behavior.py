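"""Position-derived kinematics, maze linearization, and task accuracy.

The delayed-alternation apparatus is a T-maze with a sequester (delay) box
at the base of the stem.  Positions are tracked as (t, x, y) samples;
running speed is distance over time between consecutive samples, and
speed-by-position summaries linearize the maze circuit into 35 equal
arc-length bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_TRACK_BINS = 35

# One-way circuit polyline for the default T-maze, cm: delay box -> stem
# (63.5 cm) -> choice arm (74 cm) -> return path back to the box.  Built
# from the stated stem/arm dimensions; the return limb closes the loop.
DEFAULT_TMAZE_PATH = np.array(
    [
        [0.0, -15.0],   # delay box
        [0.0, 0.0],     # stem base (door)
        [0.0, 63.5],    # top of stem / choice point
        [74.0, 63.5],   # end of choice arm (reward well)
        [74.0, -15.0],  # return arm down
        [0.0, -15.0],   # back to the delay box
    ]
)


def running_speed(positions: pd.DataFrame, smooth_samples: int = 0) -> pd.DataFrame:
    """Speed between consecutive position samples, at interval midpoints.

    speed_i = ||p_{i+1} - p_i|| / (t_{i+1} - t_i), cm/s.  ``smooth_samples``
    > 1 applies a centered moving average.
    """
    t = positions["t_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError("need at least 2 position samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("position timestamps must be strictly increasing")
    xy = positions[["x_cm", "y_cm"]].to_numpy(float)
    dist = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = dist / dt
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        speed = np.convolve(speed, kernel, mode="same")
    return pd.DataFrame({"t_s": t[:-1] + dt / 2, "speed_cm_s": speed})


def _path_geometry(path: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment start points, unit vectors, lengths, and cumulative arc length."""
    path = np.asarray(path, float)
    seg = np.diff(path, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths <= 0):
        raise ValueError("maze path has a zero-length segment")
    return path[:-1], seg, lengths


def path_length(path: np.ndarray = DEFAULT_TMAZE_PATH) -> float:
    _, _, lengths = _path_geometry(path)
    return float(lengths.sum())


def point_on_path(arc_s: np.ndarray, path: np.ndarray = DEFAULT_TMAZE_PATH) -> np.ndarray:
    """(x, y) at arc length ``arc_s`` along the path (clipped to its ends)."""
    starts, seg, lengths = _path_geometry(path)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    s = np.clip(np.atleast_1d(np.asarray(arc_s, float)), 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(lengths) - 1)
    frac = (s - cum[idx]) / lengths[idx]
    return starts[idx] + frac[:, None] * seg[idx]

def project_to_path(
    xy: np.ndarray, path: np.ndarray = DEFAULT_TMAZE_PATH
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length coordinate and distance of each point's nearest path point."""
    starts, seg, lengths = _path_geometry(path)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    xy = np.atleast_2d(np.asarray(xy, float))
    # candidate projection on every segment, take the closest
    diff = xy[:, None, :] - starts[None, :, :]            # [n, nseg, 2]
    t = np.einsum("nsd,sd->ns", diff, seg) / (lengths**2)  # param along segment
    t = np.clip(t, 0.0, 1.0)
    proj = starts[None] + t[..., None] * seg[None]
    d = np.linalg.norm(xy[:, None, :] - proj, axis=2)
    best = d.argmin(axis=1)
    n = np.arange(len(xy))
    arc = cum[best] + t[n, best] * lengths[best]
    return arc, d[n, best]


def linearize_and_bin(
    positions: pd.DataFrame,
    path: np.ndarray = DEFAULT_TMAZE_PATH,
    n_bins: int = N_TRACK_BINS,
    max_dist_cm: float = 20.0,
) -> pd.DataFrame:
    """Assign each position sample to one of ``n_bins`` equal arc-length bins.

    Samples farther than ``max_dist_cm`` from the path are flagged
    (``on_path`` False) and get bin -1.  Returns the per-sample table with
    columns t_s, arc_cm, bin (1-based), on_path, and speed_cm_s interpolated
    from :func:`running_speed`.
    """
    xy = positions[["x_cm", "y_cm"]].to_numpy(float)
    arc, dist = project_to_path(xy, path)
    total = path_length(path)
    binned = np.minimum((arc / total * n_bins).astype(int), n_bins - 1) + 1
    on_path = dist <= max_dist_cm
    binned = np.where(on_path, binned, -1)
    sp = running_speed(positions)
    t = positions["t_s"].to_numpy(float)
    speed = np.interp(t, sp["t_s"], sp["speed_cm_s"])
    return pd.DataFrame(
        {"t_s": t, "arc_cm": arc, "bin": binned, "on_path": on_path, "speed_cm_s": speed}
    )


def speed_by_bin(linearized: pd.DataFrame, n_bins: int = N_TRACK_BINS) -> pd.DataFrame:
    """Mean speed per track bin over the supplied (already filtered) samples."""
    ok = linearized[linearized["on_path"]]
    grouped = ok.groupby("bin")["speed_cm_s"].agg(["mean", "count"])
    out = grouped.reindex(range(1, n_bins + 1))
    out.index.name = "bin"
    return out.rename(columns={"mean": "speed_cm_s", "count": "n_samples"}).reset_index()


def accuracy_by_delay(trials: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Proportion of correct trials per delay category (optionally per group).

    ``trials`` needs columns outcome and delay_category; pass
    ``by=['group', 'delay_category']`` for a cohort-level table.
    """
    if not len(trials):
        return pd.DataFrame(columns=(by or ["delay_category"]) + ["n_trials", "prop_correct"])
    by = by or ["delay_category"]
    t = trials.copy()
    t["is_correct"] = (t["outcome"] == "correct").astype(float)
    g = t.groupby(by, sort=True)["is_correct"].agg(["count", "mean"]).reset_index()
    return g.rename(columns={"count": "n_trials", "mean": "prop_correct"})
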
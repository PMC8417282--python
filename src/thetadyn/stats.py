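"""Group-comparison statistics: speed-power correlations, rank tests, running F.

Implemented from first principles (rank-based Kruskal-Wallis H with tie
correction, classical equal-variance one-way ANOVA F) so that each can be
checked against independent oracles; p-values use the chi-square and F
reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def speed_power_correlation(
    band_series: np.ndarray,
    frame_times_s: np.ndarray,
    speed_t_s: np.ndarray,
    speed_cm_s: np.ndarray,
) -> float:
    """Pearson r between a per-frame band-power series and running speed.

    Speed is linearly interpolated onto the spectrogram frame times.
    """
    if len(band_series) < 10:
        raise ValueError("need at least 10 frames for a speed-power correlation")
    v = np.interp(np.asarray(frame_times_s, float), np.asarray(speed_t_s, float),
                  np.asarray(speed_cm_s, float))
    return pearson_r(np.asarray(band_series, float), v)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H statistic with tie correction and chi-square p-value.

    H = (12 / (N (N+1))) * sum_i n_i (rbar_i - rbar)^2, divided by
    1 - sum(t^3 - t) / (N^3 - N) over tied groups; p from chi-square with
    k - 1 degrees of freedom.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sstats.rankdata(pooled)  # midranks for ties
    grand = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - grand) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts**3 - counts).sum()))
    denom = 1.0 - ties / (n**3 - n)
    if denom == 0:  # every observation identical
        return 0.0, 1.0
    h /= denom
    df = len(groups) - 1
    return float(h), float(sstats.chi2.sf(h, df))


def one_way_f(groups: list[np.ndarray]) -> tuple[float, float, tuple[int, int]]:
    """Classical equal-variance one-way ANOVA F from sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = pooled.size - len(groups)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0, 0.0 if ss_between > 0 else 1.0, (df1, df2)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(sstats.f.sf(f, df1, df2)), (df1, df2)


@dataclass
class RunningFSeries:
    """Step-by-step two-group F with a Bonferroni significance mask."""

    step_times_s: np.ndarray
    f: np.ndarray
    p: np.ndarray
    df: tuple[int, int]
    significant: np.ndarray
    alpha: float

    @property
    def threshold(self) -> float:
        return self.alpha / self.f.size


def running_group_f(
    values_a: np.ndarray,
    values_b: np.ndarray,
    step_times_s: np.ndarray,
    alpha: float = 0.05,
) -> RunningFSeries:
    """One-way ANOVA between two trial ensembles at every time step.

    ``values_a`` and ``values_b`` are [n_trials x n_steps] matrices of an
    event-aligned measure (e.g., TD ratio).  The Bonferroni threshold is
    alpha divided by the number of steps.
    """
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    if a.shape[1] != b.shape[1] or a.shape[1] != len(step_times_s):
        raise ValueError("trial matrices and step grid must share the step axis")
    n_steps = a.shape[1]
    f = np.empty(n_steps)
    p = np.empty(n_steps)
    df = (1, a.shape[0] + b.shape[0] - 2)
    for j in range(n_steps):
        f[j], p[j], df = one_way_f([a[:, j], b[:, j]])
    return RunningFSeries(
        step_times_s=np.asarray(step_times_s, float),
        f=f,
        p=p,
        df=df,
        significant=p < alpha / n_steps,
        alpha=alpha,
    )


def correlation_cdf(r_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of per-lead correlation values (for cumulative-density plots)."""
    r = np.sort(np.asarray(r_values, float))
    return r, np.arange(1, r.size + 1) / r.size
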
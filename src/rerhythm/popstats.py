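"""Population-level comparisons of circadian abundance.

Cumulative daily abundance change between conditions (percent change of the
linear-scale total over the cycle), classical pooled-variance two-sample
t-tests for comparing amplitude or change distributions between populations,
and descriptive phase histograms with circular summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def cumulative_change(
    series_std: np.ndarray,
    series_ecd: np.ndarray,
    times_std: np.ndarray,
    times_ecd: np.ndarray,
) -> float:
    """Percent change in cumulative daily abundance from STD to ECD.

    Per condition the cumulative abundance is the sum over distinct timepoints
    of the replicate mean, on the linear scale; returns
    ``100 * (S_ecd - S_std) / S_std`` (NaN when the STD total is zero).
    """
    s = {}
    for key, vals, times in (
        ("std", series_std, times_std),
        ("ecd", series_ecd, times_ecd),
    ):
        vals = np.asarray(vals, dtype=float)
        times = np.asarray(times, dtype=float)
        df = pd.Series(vals).groupby(times).mean()
        s[key] = df.sum()
    if s["std"] == 0:
        return float("nan")
    return 100.0 * (s["ecd"] - s["std"]) / s["std"]


def cumulative_change_matrix(m_std, m_ecd) -> pd.Series:
    """Vectorized :func:`cumulative_change` for two AbundanceMatrix objects
    sharing a series universe; returns percent change per series."""
    shared = m_std.series_ids.intersection(m_ecd.series_ids)
    totals = {}
    for key, m in (("std", m_std), ("ecd", m_ecd)):
        means = m.values.loc[shared].T.groupby(m.ct).mean()
        totals[key] = means.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (totals["ecd"] - totals["std"]) / totals["std"]
    return pct.replace([np.inf, -np.inf], np.nan)


@dataclass
class PopulationComparison:
    """Unpaired two-tailed pooled-variance (Student) t-test result."""

    group_a_mean: float
    group_b_mean: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_populations(values_a, values_b, welch: bool = False) -> PopulationComparison:
    """Classical unpaired two-tailed t-test between two value populations.

    Pooled-variance (Student) by default; Welch behind a flag.  Degenerate
    zero-variance inputs: equal means give t = 0, p = 1; unequal means give a
    p-value at the float floor.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = a.var(ddof=1) + b.var(ddof=1)
    if pooled_var == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = np.finfo(float).tiny
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return PopulationComparison(
        group_a_mean=float(a.mean()),
        group_b_mean=float(b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def phase_histogram(
    phases, bin_hours: float = 3.0, period: float = 24.0
) -> tuple[pd.Series, float, float]:
    """Histogram of acrophases plus circular mean and mean resultant length.

    Bins are half-open ``[k*b, (k+1)*b)``.  Returns (counts indexed by bin
    start, circular mean in hours, resultant length R in [0, 1]); an empty
    input gives an empty histogram with NaN summaries.
    """
    phases = np.asarray(phases, dtype=float)
    edges = np.arange(0.0, period + bin_hours / 2, bin_hours)
    index = pd.Index(edges[:-1], name="bin_start")
    if phases.size == 0:
        return pd.Series(0, index=index, dtype=int), float("nan"), float("nan")
    if ((phases < 0) | (phases >= period)).any():
        raise ValueError("phases must lie in [0, period)")
    counts, _ = np.histogram(phases, bins=edges)
    ang = phases * 2 * np.pi / period
    z = np.exp(1j * ang).mean()
    mean_h = float(np.mod(np.angle(z) * period / (2 * np.pi), period))
    return pd.Series(counts, index=index), mean_h, float(np.abs(z))
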
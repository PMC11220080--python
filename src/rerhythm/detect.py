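"""Consensus circadian rhythmicity detection.

A series is called rhythmic only if two independent detectors agree (an
AND-rule over per-detector significance):

* a parametric arm: harmonic (cosinor) regression
  ``y = mesor + a*cos(2*pi*t/T) + b*sin(2*pi*t/T)`` with an F-test of the
  two-parameter harmonic against the intercept-only model, which also yields
  the amplitude ``sqrt(a^2 + b^2)`` (log2 half peak-to-trough) and the
  acrophase (CT hours of the fitted maximum);
* a nonparametric arm: a rank-template test — the maximum Kendall tau between
  the series and a period-T cosine template over all grid phases, calibrated
  by a permutation null in which replicate blocks keep their timepoint
  grouping (timepoint labels are permuted, triplets move together).

Multiplicity is handled by Benjamini-Hochberg adjustment within the analysis
set; transcript calling uses q-values, protein calling uses raw p-values,
matching the asymmetric thresholds of the study design this package models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Parametric arm: cosinor regression
# ---------------------------------------------------------------------------

def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def _check_times(times: np.ndarray, period: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be 1-D")
    if len(times) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(times) == 0:
        raise ValueError("all observation times are identical")
    return times


def cosinor_fit_matrix(
    values: np.ndarray, times: np.ndarray, period: float = 24.0
) -> pd.DataFrame:
    """Cosinor fit of every row of ``values`` (series x observation, log2 scale).

    Returns a DataFrame with columns mesor, amplitude, acrophase, p_param.
    """
    times = _check_times(times, period)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    n = len(times)
    X = _design(times, period)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 x n_series
    resid = Y.T - X @ beta
    ss_res = (resid**2).sum(axis=0)
    ss_null = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_den = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((ss_null - ss_res) / 2.0) / (ss_res / df_den)
    p = stats.f.sf(F, 2, df_den)
    # degenerate cases: flat series (no variance at all) -> F = 0, p = 1;
    # perfect harmonic fit (zero residual) -> p at the float floor
    flat = ss_null <= 0
    perfect = (ss_res <= 1e-12 * np.maximum(ss_null, 1.0)) & ~flat
    p = np.where(flat, 1.0, np.where(perfect, _P_FLOOR, np.clip(p, _P_FLOOR, 1.0)))
    mesor, a, b = beta
    amplitude = np.hypot(a, b)
    acrophase = np.mod(np.arctan2(b, a) * period / (2 * np.pi), period)
    # float wrap (e.g. arctan2 of -eps) can land exactly on `period`
    acrophase = np.where(acrophase >= period, acrophase - period, acrophase)
    acrophase = np.where(amplitude == 0, 0.0, acrophase)
    return pd.DataFrame(
        {"mesor": mesor, "amplitude": amplitude, "acrophase": acrophase, "p_param": p}
    )


def cosinor_fit(
    series: np.ndarray, times: np.ndarray, period: float = 24.0
) -> tuple[float, float, float, float]:
    """Cosinor fit of one series; returns (mesor, amplitude, acrophase, p_param)."""
    out = cosinor_fit_matrix(np.asarray(series, dtype=float)[None, :], times, period)
    r = out.iloc[0]
    return float(r.mesor), float(r.amplitude), float(r.acrophase), float(r.p_param)


# ---------------------------------------------------------------------------
# Nonparametric arm: rank-template permutation test
# ---------------------------------------------------------------------------

def _grid_info(times: np.ndarray):
    """Distinct timepoints (sorted) and the block index of each observation."""
    u, block = np.unique(times, return_inverse=True)
    return u, block


def _pair_indices(n: int):
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _template_values(u: np.ndarray, period: float) -> np.ndarray:
    """V[k, b] = cosine template with acrophase u[k], evaluated at timepoint u[b].

    Values are rounded so that mathematically tied template values (cosine is
    symmetric about the acrophase) are exactly tied; otherwise float noise
    breaks ties inconsistently across template phases and distorts the
    rank statistic.
    """
    w = 2 * np.pi / period
    return np.round(np.cos(w * (u[None, :] - u[:, None])), 9)


def _template_sign_pairs(V, block_i, block_j, perms):
    """int8 sign-pair matrix for every (permutation, template).

    ``perms`` has shape (n_perm, n_timepoints), each row a permutation of
    timepoint indices; returns shape (n_perm, K, n_pairs).
    """
    K = V.shape[0]
    out = np.empty((perms.shape[0], K, len(block_i)), dtype=np.int8)
    pi = perms[:, block_i]  # (n_perm, n_pairs) permuted timepoint index of obs i
    pj = perms[:, block_j]
    for k in range(K):
        out[:, k, :] = np.sign(V[k][pi] - V[k][pj]).astype(np.int8)
    return out


def _sign_pairs(rows: np.ndarray, i, j) -> np.ndarray:
    return np.sign(rows[:, i] - rows[:, j]).astype(np.int8)


def rank_template_matrix(
    values: np.ndarray,
    times: np.ndarray,
    period: float = 24.0,
    n_perm: int = 10000,
    seed: int | None = None,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Rank-template permutation test for every row of ``values``.

    The statistic is the maximum (over one cosine template per distinct
    timepoint) of the Kendall concordance between the series and the template;
    the permutation null permutes timepoint labels with replicate blocks kept
    intact.  ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.  Returns a
    DataFrame with columns p_rank and best_phase (acrophase of the best
    template, ties broken toward the earliest CT).
    """
    times = _check_times(times, period)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    u, block = _grid_info(times)
    n_tp = len(u)
    bi, bj = _pair_indices(len(times))
    V = _template_values(u, period)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n_tp) for _ in range(n_perm)])
    T = _template_sign_pairs(V, block[bi], block[bj], perms)  # (n_perm, K, P)
    K, P = V.shape[0], len(bi)
    Tmat = T.reshape(n_perm * K, P).astype(np.float32)

    identity = np.arange(n_tp)[None, :]
    obs_T = _template_sign_pairs(V, block[bi], block[bj], identity)[0]  # (K, P)
    obs_Tf = obs_T.astype(np.float32)

    p_out = np.empty(Y.shape[0])
    phase_out = np.empty(Y.shape[0])
    for start in range(0, Y.shape[0], chunk):
        Yb = Y[start : start + chunk]
        m = len(Yb)
        S_y = _sign_pairs(Yb, bi, bj).astype(np.float32)  # (m, P)
        obs_k = S_y @ obs_Tf.T  # (m, K)
        best = np.argmax(obs_k, axis=1)  # first max -> earliest CT (u sorted)
        obs_stat = obs_k[np.arange(m), best]
        ge = np.zeros(m, dtype=np.int64)
        pc = max(1, 5_000_000 // max(1, m * K))  # bound scratch to ~5M floats
        for ps in range(0, n_perm, pc):
            Tb = Tmat[ps * K : (ps + min(pc, n_perm - ps)) * K]
            npc = Tb.shape[0] // K
            null = (S_y @ Tb.T).reshape(m, npc, K).max(axis=2)
            ge += (null >= obs_stat[:, None]).sum(axis=1)
        p_out[start : start + m] = (1.0 + ge) / (1.0 + n_perm)
        phase_out[start : start + m] = u[best]
    return pd.DataFrame({"p_rank": p_out, "best_phase": phase_out})


def rank_template_test(
    series: np.ndarray,
    times: np.ndarray,
    period: float = 24.0,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Rank-template test for one series; returns (p_rank, best_phase)."""
    out = rank_template_matrix(
        np.asarray(series, dtype=float)[None, :], times, period, n_perm, seed
    )
    return float(out.p_rank.iloc[0]), float(out.best_phase.iloc[0])


# ---------------------------------------------------------------------------
# Multiplicity and consensus
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_call(
    fits: pd.DataFrame, alpha: float = 0.05, use_q: bool = True
) -> pd.DataFrame:
    """Apply the two-detector AND rule to a fit table.

    ``fits`` must carry ``p_param`` and ``p_rank`` for every series.  When
    ``use_q`` the BH-adjusted values (computed within this set) are
    thresholded, otherwise the raw p-values.  Returns a copy with columns
    q_param, q_rank and consensus_rhythmic added.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for col in ("p_param", "p_rank"):
        if col not in fits.columns:
            raise ValueError(f"fit table lacks column {col}")
        if fits[col].isna().any():
            raise ValueError(f"missing detector values in {col}")
    out = fits.copy()
    out["q_param"] = bh_adjust(out["p_param"].to_numpy())
    out["q_rank"] = bh_adjust(out["p_rank"].to_numpy())
    xp = out["q_param"] if use_q else out["p_param"]
    xr = out["q_rank"] if use_q else out["p_rank"]
    out["consensus_rhythmic"] = (xp < alpha) & (xr < alpha)
    return out


def detect_rhythms(
    m: AbundanceMatrix,
    alpha: float = 0.05,
    use_q: bool = True,
    n_perm: int = 1000,
    seed: int | None = None,
    period: float = 24.0,
) -> pd.DataFrame:
    """Run both detectors on a matrix (log2(x+1) scale) and make consensus calls.

    Returns one row per series: mesor, amplitude, acrophase, p/q per detector
    and the consensus flag.
    """
    log2 = m.log2().to_numpy()
    times = m.ct
    param = cosinor_fit_matrix(log2, times, period)
    rank = rank_template_matrix(log2, times, period, n_perm=n_perm, seed=seed)
    fits = pd.concat([param, rank], axis=1)
    fits.insert(0, "series_id", m.series_ids.to_numpy())
    fits = consensus_call(fits, alpha=alpha, use_q=use_q)
    return fits.set_index("series_id")
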
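"""Gene-level integration of rhythmicity calls across molecular layers.

Transcript (mRNA), whole-cell protein (TE) and nuclear protein (NE) series are
joined at the gene level (many-to-one series -> gene).  The joined universe is
restricted to genes quantified at the transcript level AND at one or more
protein layers, so that layer comparisons are not confounded by detection
differences between RNA-seq and mass spectrometry.  A gene is rhythmic at a
layer if ANY of its series at that layer carries a consensus rhythmic call.

On this universe the module computes the pairwise overlap percentages (e.g.
what fraction of nuclear-rhythmic genes are also rhythmic at the whole-cell
level), the post-translationally acquired population (rhythmic in the nucleus
but not the whole cell), the chained estimate of how much rhythmic transcripts
contribute to the rhythmic nuclear proteome, and phase lead/lag and
amplitude-ratio statistics between transcript and protein rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import _round_half_up, percent

LAYERS = ("mrna", "te", "ne")


def _as_cond_dict(fits) -> dict:
    return fits if isinstance(fits, dict) else {"ALL": fits}


def _gene_level(fits: pd.DataFrame, gene_of: pd.Series) -> pd.DataFrame:
    """Per-gene rhythmic flag plus phase/amplitude of the strongest rhythmic series."""
    df = fits[["consensus_rhythmic", "acrophase", "amplitude"]].copy()
    df["gene"] = gene_of.loc[df.index].to_numpy()
    rhythmic = df.groupby("gene")["consensus_rhythmic"].any()
    rhy = df[df["consensus_rhythmic"]].sort_values(
        ["amplitude"], ascending=False, kind="stable"
    )
    best = rhy.groupby("gene", sort=True).first()
    out = pd.DataFrame({"rhythmic": rhythmic})
    out["phase"] = best["acrophase"]
    out["amplitude"] = best["amplitude"]
    return out


def join_layers(mrna_fits, te_fits, ne_fits, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Join per-layer fit tables into one gene-level table.

    Each ``*_fits`` argument is a fit table indexed by series id (columns
    ``consensus_rhythmic``, ``acrophase``, ``amplitude``) or a dict of such
    tables keyed by condition.  ``gene_map`` maps ``series_id`` to ``gene``
    and must cover every series.  Returns a DataFrame indexed by gene with
    ``has_transcript``/``has_te_protein``/``has_ne_protein`` and, per layer
    and condition, ``rhythmic_<layer>_<cond>``, ``phase_<layer>_<cond>`` and
    ``amplitude_<layer>_<cond>``; the universe is genes with a transcript and
    at least one protein layer quantified.
    """
    gene_of = gene_map.set_index("series_id")["gene"]
    layer_fits = {
        "mrna": _as_cond_dict(mrna_fits),
        "te": _as_cond_dict(te_fits),
        "ne": _as_cond_dict(ne_fits),
    }
    unmapped: list = []
    for fits in layer_fits.values():
        for df in fits.values():
            unmapped.extend(s for s in df.index if s not in gene_of.index)
    if unmapped:
        raise ValueError(f"series ids missing from gene map: {sorted(set(unmapped))[:10]}")

    present = {}
    for layer, fits in layer_fits.items():
        ids = set()
        for df in fits.values():
            ids.update(gene_of.loc[df.index])
        present[layer] = ids
    universe = sorted(present["mrna"] & (present["te"] | present["ne"]))
    out = pd.DataFrame(index=pd.Index(universe, name="gene"))
    if not len(universe):
        return out
    out["has_transcript"] = True
    out["has_te_protein"] = [g in present["te"] for g in universe]
    out["has_ne_protein"] = [g in present["ne"] for g in universe]
    for layer, fits in layer_fits.items():
        for cond, df in fits.items():
            gl = _gene_level(df, gene_of).reindex(universe)
            rhy = gl["rhythmic"]
            out[f"rhythmic_{layer}_{cond}"] = np.where(rhy.isna(), False, rhy).astype(bool)
            out[f"phase_{layer}_{cond}"] = gl["phase"]
            out[f"amplitude_{layer}_{cond}"] = gl["amplitude"]
    return out


def contribution_chain(pct_ne_also_te: float, pct_te_with_rhythmic_mrna: float) -> float:
    """Chained percentage of rhythmic nuclear proteins traceable to rhythmic transcripts.

    The product of (i) the percentage of nuclear-rhythmic genes also rhythmic at
    the whole-cell level and (ii) the percentage of whole-cell-rhythmic genes
    with rhythmic transcripts, reported as a percentage with one decimal.
    """
    for x in (pct_ne_also_te, pct_te_with_rhythmic_mrna):
        if not 0 <= x <= 100:
            raise ValueError(f"percentage {x} outside [0, 100]")
    return _round_half_up(pct_ne_also_te * pct_te_with_rhythmic_mrna / 100.0, 1)


@dataclass
class LayerOverlapSummary:
    """Cross-layer overlap percentages within the joined gene universe."""

    pct_rhythmic_mrna_with_rhythmic_te: float
    pct_rhythmic_te_with_rhythmic_mrna: float
    pct_rhythmic_te_with_rhythmic_ne: float
    pct_rhythmic_ne_with_rhythmic_te: float
    n_gor_pta: int
    pct_contribution_chain: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_percentages(
    j: pd.DataFrame, condition: str = "ALL", decimals: int = 0
) -> LayerOverlapSummary:
    """Overlap percentages for one condition of a joined gene table.

    Each percentage is computed within its stated denominator (the rhythmic
    set of the first-named layer); a zero denominator yields NaN.  The
    contribution chain is computed from the (rounded) printed percentages, as
    in headline summaries.
    """
    if j.empty:
        raise ValueError("joined universe is empty")
    r = {L: j[f"rhythmic_{L}_{condition}"].to_numpy(bool) for L in LAYERS}
    pct_mrna_te = percent((r["mrna"] & r["te"]).sum(), r["mrna"].sum(), decimals)
    pct_te_mrna = percent((r["te"] & r["mrna"]).sum(), r["te"].sum(), decimals)
    pct_te_ne = percent((r["te"] & r["ne"]).sum(), r["te"].sum(), decimals)
    pct_ne_te = percent((r["ne"] & r["te"]).sum(), r["ne"].sum(), decimals)
    n_gor_pta = int((r["ne"] & ~r["te"]).sum())
    chain = (
        contribution_chain(pct_ne_te, pct_te_mrna)
        if not (np.isnan(pct_ne_te) or np.isnan(pct_te_mrna))
        else float("nan")
    )
    return LayerOverlapSummary(
        pct_rhythmic_mrna_with_rhythmic_te=pct_mrna_te,
        pct_rhythmic_te_with_rhythmic_mrna=pct_te_mrna,
        pct_rhythmic_te_with_rhythmic_ne=pct_te_ne,
        pct_rhythmic_ne_with_rhythmic_te=pct_ne_te,
        n_gor_pta=n_gor_pta,
        pct_contribution_chain=chain,
    )


def _doubly_rhythmic(j: pd.DataFrame, condition: str) -> pd.DataFrame:
    mask = (
        j[f"rhythmic_mrna_{condition}"].to_numpy(bool)
        & j[f"rhythmic_te_{condition}"].to_numpy(bool)
    )
    return j[mask]


def lead_lag_ratio(
    j: pd.DataFrame, condition: str = "ALL", period: float = 24.0
) -> tuple[int, int, float]:
    """Count genes whose transcript phase leads vs lags the whole-cell protein phase.

    Among genes rhythmic at both mRNA and TE: lead iff the circular difference
    (protein phase - transcript phase) mod period lies in (0, period/2); ties
    at exactly 0 or period/2 count as lag.  Returns (n_lead, n_lag, ratio).
    """
    d = _doubly_rhythmic(j, condition)
    if d.empty:
        return 0, 0, float("nan")
    diff = np.mod(
        d[f"phase_te_{condition}"].to_numpy() - d[f"phase_mrna_{condition}"].to_numpy(),
        period,
    )
    lead = (diff > 0) & (diff < period / 2)
    n_lead, n_lag = int(lead.sum()), int((~lead).sum())
    return n_lead, n_lag, (n_lead / n_lag if n_lag else float("inf"))


def amplitude_ratio_classification(
    j: pd.DataFrame, condition: str = "ALL"
) -> tuple[int, int, float]:
    """Count genes whose whole-cell protein amplitude exceeds the transcript amplitude.

    Among genes rhythmic at both layers, with both amplitudes from the same
    (cosinor, log2-scale) estimator: protein_higher iff strictly greater
    (ties count as lower).  Returns (n_higher, n_lower, ratio).
    """
    d = _doubly_rhythmic(j, condition)
    if d.empty:
        return 0, 0, float("nan")
    higher = (
        d[f"amplitude_te_{condition}"].to_numpy()
        > d[f"amplitude_mrna_{condition}"].to_numpy()
    )
    n_hi, n_lo = int(higher.sum()), int((~higher).sum())
    return n_hi, n_lo, (n_hi / n_lo if n_lo else float("inf"))
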
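"""Abundance matrices, detection filtering and TMT bridge-channel normalization.

The universal data carrier is :class:`AbundanceMatrix`: a series x sample table of
non-negative abundances (raw transcript counts or reporter intensities) together
with a sample-metadata table describing the circadian design (condition, circadian
time, replicate, compartment, and optionally TMT plex/channel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns every sample table must provide
SAMPLE_COLUMNS = ["condition", "ct_hours", "replicate", "compartment"]
#: optional metadata columns, filled with defaults when absent
OPTIONAL_SAMPLE_COLUMNS = {"plex": None, "channel": None, "is_bridge": False}

CONDITIONS = ("STD", "ECD")
COMPARTMENTS = ("RNA", "TE", "NE")


@dataclass
class AbundanceMatrix:
    """Series x sample abundance matrix with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by series id, one column per sample id; non-negative.
    samples
        DataFrame indexed by sample id (same order as ``values.columns``) with
        columns ``condition``, ``ct_hours``, ``replicate``, ``compartment`` and
        optionally ``plex``, ``channel``, ``is_bridge``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        samples = self.samples.copy()
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        for col, default in OPTIONAL_SAMPLE_COLUMNS.items():
            if col not in samples.columns:
                samples[col] = default
        samples["is_bridge"] = samples["is_bridge"].fillna(False).astype(bool)
        samples["ct_hours"] = samples["ct_hours"].astype(float)
        self.samples = samples
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample metadata index do not match")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("abundance matrix contains NaN")
        if (arr < 0).any():
            raise ValueError("abundance matrix contains negative values")
        bad_ct = ~((self.samples["ct_hours"] >= 0) & (self.samples["ct_hours"] < 24))
        if bad_ct.any():
            raise ValueError(
                f"ct_hours outside [0, 24): {list(self.samples.index[bad_ct])}"
            )
        bridged = self.samples["is_bridge"] & self.samples["plex"].isna()
        if bridged.any():
            raise ValueError(
                f"bridge samples without a plex id: {list(self.samples.index[bridged])}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def series_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def ct(self) -> np.ndarray:
        """Circadian times (h) of the samples, in column order."""
        return self.samples["ct_hours"].to_numpy()

    def subset_series(self, ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[ids], self.samples)

    def subset_samples(self, mask) -> "AbundanceMatrix":
        cols = self.samples.index[mask]
        return AbundanceMatrix(self.values[cols], self.samples.loc[cols])

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(x + pseudocount) transform used before rhythm detection."""
        return np.log2(self.values + pseudocount)


@dataclass
class FilterReport:
    """Bookkeeping for the transcript detection filter."""

    n_input: int
    n_kept: int
    n_dropped_low_abundance: int
    n_dropped_low_detection: int

    def __post_init__(self) -> None:
        total = self.n_kept + self.n_dropped_low_abundance + self.n_dropped_low_detection
        if total != self.n_input:
            raise ValueError("filter report counts are inconsistent")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, metadata_path) -> AbundanceMatrix:
    """Read an abundance matrix (first column = series id) plus sample metadata.

    Raises a ``ValueError`` naming the offending sample id when the matrix and
    metadata disagree, and one with coordinates for any non-numeric cell.
    """
    raw = pd.read_csv(path, sep=_sep(path), index_col=0)
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(f"non-numeric abundance at series {row!r}, sample {col!r}")
    values = raw.apply(pd.to_numeric)
    meta = pd.read_csv(metadata_path, sep=_sep(metadata_path), index_col="sample_id")
    unmatched = [s for s in values.columns if s not in meta.index]
    if unmatched:
        raise ValueError(f"sample ids missing from metadata: {unmatched}")
    return AbundanceMatrix(values, meta.loc[values.columns])


def write_matrix(m: AbundanceMatrix, path, metadata_path=None) -> None:
    """Write the matrix (and optionally its metadata) as TSV/CSV; inverse of read_matrix."""
    m.values.to_csv(path, sep=_sep(path), index_label="series_id")
    if metadata_path is not None:
        m.samples.to_csv(metadata_path, sep=_sep(metadata_path), index_label="sample_id")


# ---------------------------------------------------------------------------
# Detection filter
# ---------------------------------------------------------------------------

def filter_transcript_series(
    m: AbundanceMatrix, min_total: float = 50, min_detected: int = 32
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop transcript series with total abundance < ``min_total`` or detection
    (count > 0) in fewer than ``min_detected`` samples.

    Both boundaries keep: a series with total exactly ``min_total`` and detection
    in exactly ``min_detected`` samples survives.  A series failing both rules is
    counted once, under low abundance.
    """
    if min_detected > m.n_samples:
        raise ValueError(
            f"min_detected={min_detected} exceeds sample count {m.n_samples}"
        )
    arr = m.values.to_numpy()
    totals = arr.sum(axis=1)
    detected = (arr > 0).sum(axis=1)
    low_abund = totals < min_total
    low_det = detected < min_detected
    keep = ~(low_abund | low_det)
    report = FilterReport(
        n_input=m.n_series,
        n_kept=int(keep.sum()),
        n_dropped_low_abundance=int(low_abund.sum()),
        n_dropped_low_detection=int((low_det & ~low_abund).sum()),
    )
    return m.subset_series(m.series_ids[keep]), report


# ---------------------------------------------------------------------------
# TMT bridge-channel normalization
# ---------------------------------------------------------------------------

def bridge_normalize(
    plexes: list[AbundanceMatrix], bridge_count: int = 2
) -> AbundanceMatrix:
    """Normalize TMT plexes by their bridge (spike) channels and concatenate.

    Within each plex every sample column is divided, per series, by the mean of
    that plex's bridge columns, cancelling the plex-specific scale.  The result
    is then re-anchored by the per-series average of the bridge means across
    plexes, so that with noise-free bridges the original intensities are
    recovered exactly.  Bridge columns are dropped; plexes are concatenated on
    the intersection of series ids, ordered by series id.  Series whose bridge
    mean is zero in any plex are dropped (counted in the log).
    """
    if not plexes:
        raise ValueError("no plexes given")
    shared = None
    bridge_means = []
    for i, plex in enumerate(plexes):
        n_bridge = int(plex.samples["is_bridge"].sum())
        if n_bridge < bridge_count:
            raise ValueError(
                f"plex {i} has {n_bridge} bridge samples, expected >= {bridge_count}"
            )
        ids = plex.series_ids
        shared = ids if shared is None else shared.intersection(ids)
    shared = shared.sort_values()

    normalized = []
    zero_mask = pd.Series(False, index=shared)
    for plex in plexes:
        is_b = plex.samples["is_bridge"].to_numpy()
        vals = plex.values.loc[shared]
        bmean = vals.loc[:, is_b].mean(axis=1)
        bridge_means.append(bmean)
        zero_mask |= bmean == 0
        normalized.append((vals.loc[:, ~is_b], bmean, plex.samples.loc[~is_b]))

    if zero_mask.any():
        logger.warning(
            "dropping %d series with zero bridge mean in >=1 plex", int(zero_mask.sum())
        )
    keep = shared[~zero_mask]
    anchor = pd.concat(bridge_means, axis=1).loc[keep].mean(axis=1)

    blocks, metas = [], []
    for vals, bmean, meta in normalized:
        blocks.append(vals.loc[keep].div(bmean.loc[keep], axis=0).mul(anchor, axis=0))
        metas.append(meta)
    return AbundanceMatrix(pd.concat(blocks, axis=1), pd.concat(metas, axis=0))
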
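"""Classification of rhythmicity changes between two conditions.

Given per-series consensus calls under a standard condition (STD) and after
environmental circadian disruption (ECD), each series falls in one of four
classes:

* ``LOR`` — loss of rhythmicity (rhythmic under STD only),
* ``GOR`` — gain of rhythmicity (rhythmic under ECD only),
* ``ROR`` — retention of rhythmicity (rhythmic under both),
* ``NRB`` — non-rhythmic in both.

"Re-writing" is the union-level fraction of rhythmic series whose status
changes: ``(LOR + GOR) / (LOR + GOR + ROR)``.  For retained series the
circular phase shift ``delta_phi = phase_ecd - phase_std`` (wrapped to
(-12, 12]) is classified against the sampling resolution: a shift strictly
greater than the resolution in magnitude is an advance (negative delta, ECD
peak earlier — the direction of the light-cycle shifts) or a delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("LOR", "GOR", "ROR", "NRB")


def phase_shift(
    phi_std: float, phi_ecd: float, period: float = 24.0, resolution: float = 3.0
) -> tuple[float, str]:
    """Circular phase difference (ECD minus STD) in (-period/2, period/2] and its class.

    Shifts with ``|delta| <= resolution`` are "unshifted" (the strict-inequality
    rule: only shifts greater than the sampling resolution count); negative
    deltas are advances, positive delays.
    """
    for phi in (phi_std, phi_ecd):
        if not 0 <= phi < period:
            raise ValueError(f"phase {phi} outside [0, {period})")
    d = (phi_ecd - phi_std) % period
    if d > period / 2:
        d -= period
    if abs(d) <= resolution:
        cls = "unshifted"
    elif d < 0:
        cls = "advance"
    else:
        cls = "delay"
    return d, cls


def classify_rhythm_change(
    std_calls: pd.DataFrame, ecd_calls: pd.DataFrame, resolution: float = 3.0
) -> pd.DataFrame:
    """Build the per-series change table from two consensus fit tables.

    Both tables are indexed by series id and carry ``consensus_rhythmic``,
    ``acrophase`` and ``amplitude``; the series universes must coincide.
    Phases/amplitudes are reported only for conditions where the series is
    rhythmic; ``delta_phi``/``shift_class`` only for ROR series.
    """
    only_std = std_calls.index.difference(ecd_calls.index)
    only_ecd = ecd_calls.index.difference(std_calls.index)
    if len(only_std) or len(only_ecd):
        raise ValueError(
            "series universes differ between conditions; only in STD: "
            f"{list(only_std[:5])}, only in ECD: {list(only_ecd[:5])}"
        )
    ecd = ecd_calls.loc[std_calls.index]
    r_std = std_calls["consensus_rhythmic"].to_numpy(bool)
    r_ecd = ecd["consensus_rhythmic"].to_numpy(bool)
    cls = np.select(
        [r_std & ~r_ecd, ~r_std & r_ecd, r_std & r_ecd], ["LOR", "GOR", "ROR"], "NRB"
    )
    table = pd.DataFrame(
        {
            "change_class": cls,
            "phase_std": np.where(r_std, std_calls["acrophase"], np.nan),
            "phase_ecd": np.where(r_ecd, ecd["acrophase"], np.nan),
            "amplitude_std": np.where(r_std, std_calls["amplitude"], np.nan),
            "amplitude_ecd": np.where(r_ecd, ecd["amplitude"], np.nan),
        },
        index=std_calls.index,
    )
    table["delta_phi"] = np.nan
    table["shift_class"] = pd.NA
    ror = table.index[cls == "ROR"]
    shifts = [
        phase_shift(table.at[s, "phase_std"], table.at[s, "phase_ecd"], resolution=resolution)
        for s in ror
    ]
    if shifts:
        table.loc[ror, "delta_phi"] = [d for d, _ in shifts]
        table.loc[ror, "shift_class"] = [c for _, c in shifts]
    return table


def _round_half_up(x: float, decimals: int = 0) -> float:
    factor = 10.0**decimals
    return np.floor(x * factor + 0.5) / factor


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage with half-up rounding, as printed in headline summaries."""
    if denominator == 0:
        return float("nan")
    return _round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class RewriteSummary:
    """Union-level counts and the headline re-writing percentage."""

    n_std: int
    n_ecd: int
    n_lor: int
    n_gor: int
    n_ror: int
    n_union: int
    pct_rewritten: float
    pct_shifted: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def rewrite_summary_from_counts(
    n_lor: int, n_gor: int, n_ror: int, n_shifted: int = 0, decimals: int = 0
) -> RewriteSummary:
    """Summary arithmetic from class counts (e.g. published tallies)."""
    n_union = n_lor + n_gor + n_ror
    return RewriteSummary(
        n_std=n_lor + n_ror,
        n_ecd=n_gor + n_ror,
        n_lor=n_lor,
        n_gor=n_gor,
        n_ror=n_ror,
        n_union=n_union,
        pct_rewritten=percent(n_lor + n_gor, n_union, decimals),
        pct_shifted=percent(n_shifted, n_union, decimals),
    )


def rewrite_summary(table: pd.DataFrame, decimals: int = 0) -> RewriteSummary:
    """Summarize a classified change table (one row per series)."""
    counts = table["change_class"].value_counts()
    shifted = int((table["shift_class"].isin(["advance", "delay"])).sum())
    return rewrite_summary_from_counts(
        int(counts.get("LOR", 0)),
        int(counts.get("GOR", 0)),
        int(counts.get("ROR", 0)),
        n_shifted=shifted,
        decimals=decimals,
    )
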
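"""End-to-end orchestration: data -> filter -> detect -> compare -> overlap -> popstats.

The pipeline runs either on a simulated dataset (a :class:`~rerhythm.synth.SimConfig`)
or on matrices loaded from disk, applies the transcript detection filter on the
combined two-condition sample set, runs consensus rhythm detection per
condition and layer (q-value thresholds for transcripts, raw p-values for
proteins), classifies LOR/GOR/ROR/NRB changes, joins layers at the gene level
and emits one machine-readable report of every headline quantity.  All
randomness descends from a single root seed, so a report is byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .compare import classify_rhythm_change, rewrite_summary
from .detect import detect_rhythms
from .matrix import AbundanceMatrix, filter_transcript_series, read_matrix
from .overlap import (
    amplitude_ratio_classification,
    join_layers,
    lead_lag_ratio,
    overlap_percentages,
)
from .popstats import compare_populations, cumulative_change_matrix, phase_histogram
from .synth import CONDITIONS, LAYERS, SimConfig, generate_multiomics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``sim`` (simulate the inputs) or ``input_paths`` (a mapping
    ``(condition, layer) -> (matrix_path, metadata_path)`` plus
    ``gene_map_path``) must be provided.
    """

    sim: SimConfig | None = None
    input_paths: dict | None = None
    gene_map_path: str | None = None
    alpha: float = 0.05
    use_q: dict = field(default_factory=lambda: {"RNA": True, "TE": False, "NE": False})
    n_perm: int = 1000
    seed: int | None = None
    resolution_hours: float = 3.0
    min_total: float = 50.0
    min_detected_fraction: float = 32.0 / 48.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.seed is None:
            raise ValueError("a root seed is required")
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of sim or input_paths")


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if np.isnan(x) else x
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (JSON-serializable dict)."""
    root = np.random.SeedSequence(cfg.seed)
    detect_seeds = {
        (cond, layer): int(child.generate_state(1)[0] % (2**31))
        for (cond, layer), child in zip(
            [(c, l) for l in LAYERS for c in CONDITIONS], root.spawn(6)
        )
    }

    if cfg.sim is not None:
        logger.info("stage simulate: %d genes", cfg.sim.n_genes)
        ds = generate_multiomics(cfg.sim)
        matrices, gene_map, truth = ds.matrices, ds.gene_map, ds.truth
    else:
        matrices = {}
        for (cond, layer), (mp, metap) in cfg.input_paths.items():
            matrices[(cond, layer)] = read_matrix(mp, metap)
        gene_map = pd.read_csv(cfg.gene_map_path, sep="\t")
        truth = None

    # transcript filter on the combined two-condition sample set
    rna = {c: matrices[(c, "RNA")] for c in CONDITIONS}
    combined = AbundanceMatrix(
        pd.concat([rna["STD"].values, rna["ECD"].values], axis=1),
        pd.concat([rna["STD"].samples, rna["ECD"].samples], axis=0),
    )
    min_detected = int(round(cfg.min_detected_fraction * combined.n_samples))
    filtered, freport = filter_transcript_series(
        combined, min_total=cfg.min_total, min_detected=min_detected
    )
    logger.info(
        "stage filter: kept %d/%d transcript series", freport.n_kept, freport.n_input
    )
    kept = filtered.series_ids
    matrices[("STD", "RNA")] = rna["STD"].subset_series(kept)
    matrices[("ECD", "RNA")] = rna["ECD"].subset_series(kept)

    fits: dict = {}
    for layer in LAYERS:
        for cond in CONDITIONS:
            try:
                fits[(cond, layer)] = detect_rhythms(
                    matrices[(cond, layer)],
                    alpha=cfg.alpha,
                    use_q=cfg.use_q[layer],
                    n_perm=cfg.n_perm,
                    seed=detect_seeds[(cond, layer)],
                )
            except Exception as err:  # pragma: no cover - context for stage aborts
                raise RuntimeError(f"stage detect[{cond},{layer}] failed: {err}") from err

    report: dict = {
        "version": __version__,
        "config": {
            "alpha": cfg.alpha,
            "use_q": cfg.use_q,
            "n_perm": cfg.n_perm,
            "seed": cfg.seed,
            "resolution_hours": cfg.resolution_hours,
            "min_total": cfg.min_total,
            "min_detected": min_detected,
        },
        "filter_report": vars(freport),
        "layers": {},
    }

    tables = {}
    for layer in LAYERS:
        table = classify_rhythm_change(
            fits[("STD", layer)], fits[("ECD", layer)], resolution=cfg.resolution_hours
        )
        tables[layer] = table
        summary = rewrite_summary(table)
        counts = table["change_class"].value_counts().to_dict()
        shift_counts = table["shift_class"].value_counts().to_dict()
        hist_std, mean_std, r_std = phase_histogram(
            table["phase_std"].dropna().to_numpy()
        )
        report["layers"][layer] = {
            "n_series": int(len(table)),
            "class_counts": counts,
            "shift_counts": shift_counts,
            "rewrite": summary.to_dict(),
            "phase_circular_mean_std": mean_std,
            "phase_resultant_std": r_std,
        }

    join = join_layers(
        {c: fits[(c, "RNA")] for c in CONDITIONS},
        {c: fits[(c, "TE")] for c in CONDITIONS},
        {c: fits[(c, "NE")] for c in CONDITIONS},
        gene_map,
    )
    report["overlap"] = {}
    for cond in CONDITIONS:
        summary = overlap_percentages(join, cond)
        n_lead, n_lag, ll_ratio = lead_lag_ratio(join, cond)
        n_hi, n_lo, amp_ratio = amplitude_ratio_classification(join, cond)
        report["overlap"][cond] = {
            **summary.to_dict(),
            "lead_lag": {"n_lead": n_lead, "n_lag": n_lag, "ratio": ll_ratio},
            "amplitude_ratio": {
                "n_protein_higher": n_hi,
                "n_protein_lower": n_lo,
                "ratio": amp_ratio,
            },
        }

    report["popstats"] = {}
    for layer in LAYERS:
        change = cumulative_change_matrix(
            matrices[("STD", layer)], matrices[("ECD", layer)]
        ).dropna()
        table = tables[layer]
        rhy_std = table.index[table["change_class"].isin(["LOR", "ROR"])]
        rhy_ecd = table.index[table["change_class"].isin(["GOR", "ROR"])]
        entry = {"mean_pct_change_all": float(change.mean())}
        for name, ids in (("std_rhythmic", rhy_std), ("ecd_rhythmic", rhy_ecd)):
            sub = change.reindex(ids).dropna()
            if len(sub) >= 2 and len(change) >= 2:
                cmp_res = compare_populations(sub.to_numpy(), change.to_numpy())
                entry[f"change_vs_all_{name}"] = cmp_res.to_dict()
        report["popstats"][layer] = entry

    if truth is not None:
        report["recovery"] = _recovery_stats(tables, truth)
    return report


def _recovery_stats(tables: dict, truth: pd.DataFrame) -> dict:
    """Per-layer agreement between recovered change classes and simulated truth."""
    out = {}
    for layer, table in tables.items():
        t = truth[truth["layer"] == layer].set_index("series_id")
        t = t.reindex(table.index).dropna(subset=["change_class"])
        pred = table.loc[t.index, "change_class"]
        agree = (pred == t["change_class"]).mean()
        per_class = {}
        for cls in ("LOR", "GOR", "ROR", "NRB"):
            mask = t["change_class"] == cls
            if mask.any():
                per_class[cls] = float((pred[mask] == cls).mean())
        ror = t.index[(t["change_class"] == "ROR") & (pred == "ROR")]
        phase_err = (
            table.loc[ror, "delta_phi"].astype(float)
            - t.loc[ror, "phase_shift"].astype(float)
        )
        phase_err = ((phase_err + 12) % 24) - 12
        out[layer] = {
            "overall_agreement": float(agree),
            "per_class_agreement": per_class,
            "n_compared": int(len(t)),
            "ror_phase_shift_mae": float(phase_err.abs().mean())
            if len(phase_err)
            else None,
        }
    return out


def report_to_json(report: dict, path=None) -> str:
    """Serialize a report deterministically (sorted keys); optionally write it."""
    text = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
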
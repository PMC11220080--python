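"""Synthetic two-condition, three-layer circadian abundance datasets.

Emulates the study design this package targets: mouse-liver abundance time
series sampled at 8 circadian timepoints (3-h spacing) in triplicate, under a
standard entrainment condition (STD) and after environmental circadian
disruption (ECD), at three molecular layers — transcripts (RNA, raw counts),
whole-cell proteins (TE) and nuclear proteins (NE, reporter intensities).

Each simulated (gene, layer) pair carries a known change class:

* ``LOR`` — rhythmic under STD only (loss of rhythmicity),
* ``GOR`` — rhythmic under ECD only (gain),
* ``ROR`` — rhythmic under both, either phase-stable or phase-advanced,
* ``NRB`` — non-rhythmic in both conditions.

Rhythmic series follow ``mesor + A*cos(2*pi*(t - phi)/24)`` on the log2 scale
plus Gaussian noise; transcripts are back-transformed to counts with
abundance-dependent dropout.  The realized design is returned as a truth table
so every downstream stage has a recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix

LAYERS = ("RNA", "TE", "NE")
CONDITIONS = ("STD", "ECD")
CHANGE_CLASSES = ("LOR", "GOR", "ROR_stable", "ROR_advance", "NRB")

# Default per-layer change design.  Class probabilities follow the observed
# proportions in the study system: ~26% of transcripts rhythmic under STD,
# 16% under ECD with heavy re-writing; proteome layers with smaller rhythmic
# fractions and near-complete re-writing.
DEFAULT_CHANGE_DESIGN = {
    "RNA": {"LOR": 0.148, "GOR": 0.050, "ROR_stable": 0.089, "ROR_advance": 0.024},
    "TE": {"LOR": 0.036, "GOR": 0.121, "ROR_stable": 0.003, "ROR_advance": 0.0},
    "NE": {"LOR": 0.087, "GOR": 0.043, "ROR_stable": 0.006, "ROR_advance": 0.0},
}

# Per-layer acrophase distributions (CT hours): transcripts peak throughout
# the cycle; whole-cell proteins bimodally around CT7/CT17; nuclear proteins
# unimodally around CT20.
DEFAULT_PHASE_DIST = {
    "RNA": {"kind": "uniform"},
    "TE": {"kind": "vonmises", "centers": [7.0, 17.0], "kappa": 2.0},
    "NE": {"kind": "vonmises", "centers": [20.0], "kappa": 2.0},
}


@dataclass
class SimConfig:
    """Design of a synthetic multi-omics circadian experiment.

    All amplitudes, mesors and noise are on the log2 scale.  ``change_design``
    gives per-layer probabilities for {LOR, GOR, ROR_stable, ROR_advance};
    NRB takes the remainder.  ``layer_rhythmic_fractions`` (STD rhythmic
    fraction per layer) must equal LOR + ROR_stable + ROR_advance and exists
    as an explicit cross-check of the design.
    """

    n_genes: int = 1000
    timepoints: tuple = tuple(float(t) for t in range(0, 24, 3))
    n_replicates: int = 3
    layer_rhythmic_fractions: dict = field(
        default_factory=lambda: {"RNA": 0.261, "TE": 0.039, "NE": 0.093}
    )
    change_design: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANGE_DESIGN.items()}
    )
    amplitude_mean: float = 0.5
    amplitude_sd: float = 0.25
    amplitude_floor: float = 0.1
    phase_dist: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PHASE_DIST.items()}
    )
    advance_hours: float = 6.0
    noise_sd: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    dropout_rate: float = 0.2
    dropout_scale: float = 5.0
    sampling: str = "quota"  # "quota" (exact class counts) or "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.ndim != 1 or len(tp) < 2 or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if (tp < 0).any() or (tp >= 24).any():
            raise ValueError("timepoints must lie in [0, 24)")
        if self.amplitude_floor <= 0:
            raise ValueError("amplitude floor must be > 0")
        if self.sampling not in ("quota", "binomial"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        for layer in LAYERS:
            probs = self.change_design[layer]
            bad = [k for k in probs if k not in CHANGE_CLASSES]
            if bad:
                raise ValueError(f"unknown change classes for {layer}: {bad}")
            vals = np.array([probs.get(k, 0.0) for k in CHANGE_CLASSES[:4]])
            if (vals < 0).any() or vals.sum() > 1 + 1e-9:
                raise ValueError(f"change probabilities for {layer} not a sub-distribution")
            rhythmic_std = probs.get("LOR", 0) + probs.get("ROR_stable", 0) + probs.get(
                "ROR_advance", 0
            )
            want = self.layer_rhythmic_fractions[layer]
            if abs(rhythmic_std - want) > 1e-6:
                raise ValueError(
                    f"layer {layer}: STD rhythmic fraction {rhythmic_std:.4f} from "
                    f"change_design conflicts with layer_rhythmic_fractions {want:.4f}"
                )


@dataclass
class SyntheticDataset:
    """Simulated matrices plus ground truth.

    ``matrices[(condition, layer)]`` holds one :class:`AbundanceMatrix` per
    condition/layer; ``truth`` has one row per (gene, layer) with the realized
    class, per-condition rhythmicity, amplitude and phase; ``gene_map`` maps
    series ids to gene ids for the layer-join stage.
    """

    matrices: dict
    truth: pd.DataFrame
    gene_map: pd.DataFrame
    config: SimConfig


def _wrap24(x):
    return np.mod(x, 24.0)


def _draw_phases(rng: np.random.Generator, n: int, dist: dict) -> np.ndarray:
    kind = dist.get("kind", "uniform")
    if kind == "fixed":
        return np.full(n, float(dist["value"]))
    if kind == "uniform":
        return rng.uniform(0, 24, n)
    if kind == "vonmises":
        centers = np.asarray(dist["centers"], dtype=float)
        kappa = float(dist.get("kappa", 2.0))
        which = rng.integers(0, len(centers), n)
        ang = rng.vonmises(centers[which] * 2 * np.pi / 24.0, kappa)
        return _wrap24(ang * 24.0 / (2 * np.pi))
    raise ValueError(f"unknown phase distribution {kind!r}")


def _draw_amplitudes(rng, n, cfg: SimConfig) -> np.ndarray:
    a = rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, n)
    return np.maximum(a, cfg.amplitude_floor)


def _assign_classes(rng, n: int, probs: dict, mode: str) -> np.ndarray:
    p = np.array([probs.get(k, 0.0) for k in CHANGE_CLASSES[:4]])
    p = np.append(p, 1.0 - p.sum())
    if mode == "binomial":
        idx = rng.choice(5, size=n, p=p)
    else:  # quota: exact counts by largest remainder
        raw = p * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        idx = np.repeat(np.arange(5), counts)
        rng.shuffle(idx)
    return np.asarray(CHANGE_CLASSES)[idx]


def generate_multiomics(cfg: SimConfig) -> SyntheticDataset:
    """Simulate the full two-condition, three-layer dataset with ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    rngs = {
        layer: np.random.default_rng(child)
        for layer, child in zip(LAYERS, root.spawn(len(LAYERS)))
    }

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    tp = np.asarray(cfg.timepoints, dtype=float)
    times = np.repeat(tp, cfg.n_replicates)
    reps = np.tile(np.arange(1, cfg.n_replicates + 1), len(tp))

    matrices: dict = {}
    truth_rows = []
    map_rows = []
    for layer in LAYERS:
        rng = rngs[layer]
        cls = _assign_classes(rng, cfg.n_genes, cfg.change_design[layer], cfg.sampling)
        rhy_std = np.isin(cls, ("LOR", "ROR_stable", "ROR_advance"))
        rhy_ecd = np.isin(cls, ("GOR", "ROR_stable", "ROR_advance"))

        mesor = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
        phase_std = _draw_phases(rng, cfg.n_genes, cfg.phase_dist[layer])
        amp_std = _draw_amplitudes(rng, cfg.n_genes, cfg)
        # ECD parameters: retained genes keep (or advance) their STD phase;
        # gained genes draw a fresh phase; amplitudes drawn per condition.
        phase_ecd = phase_std.copy()
        gained = cls == "GOR"
        phase_ecd[gained] = _draw_phases(rng, int(gained.sum()), cfg.phase_dist[layer])
        adv = cls == "ROR_advance"
        phase_ecd[adv] = _wrap24(phase_std[adv] - cfg.advance_hours)
        amp_ecd = _draw_amplitudes(rng, cfg.n_genes, cfg)
        amp_ecd[cls == "ROR_stable"] = amp_std[cls == "ROR_stable"]

        prefix = "tx" if layer == "RNA" else f"pr{layer.lower()}"
        series_ids = [f"{prefix}_{g}" for g in genes]
        map_rows.append(pd.DataFrame({"series_id": series_ids, "gene": genes, "layer": layer}))

        for cond in CONDITIONS:
            rhythmic = rhy_std if cond == "STD" else rhy_ecd
            amp = np.where(rhythmic, amp_std if cond == "STD" else amp_ecd, 0.0)
            phi = phase_std if cond == "STD" else phase_ecd
            expected = mesor[:, None] + amp[:, None] * np.cos(
                2 * np.pi * (times[None, :] - phi[:, None]) / 24.0
            )
            log2 = expected + rng.normal(0.0, cfg.noise_sd, expected.shape)
            if layer == "RNA":
                counts = np.maximum(np.round(2.0 ** log2 - 1.0), 0.0)
                if cfg.dropout_rate > 0:
                    p_zero = cfg.dropout_rate * np.exp(-counts / cfg.dropout_scale)
                    counts[rng.random(counts.shape) < p_zero] = 0.0
                vals = counts
            else:
                vals = 2.0 ** log2
            sample_ids = [
                f"{cond}_{layer}_CT{int(t):02d}_r{r}" for t, r in zip(times, reps)
            ]
            samples = pd.DataFrame(
                {
                    "condition": cond,
                    "ct_hours": times,
                    "replicate": reps,
                    "compartment": layer,
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
            matrices[(cond, layer)] = AbundanceMatrix(
                pd.DataFrame(vals, index=pd.Index(series_ids, name="series_id"),
                             columns=sample_ids),
                samples,
            )

        shift = np.where(adv, -cfg.advance_hours, 0.0)
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "series_id": series_ids,
                    "layer": layer,
                    "change_class": np.where(
                        np.char.startswith(cls.astype(str), "ROR"), "ROR", cls
                    ),
                    "rhythmic_std": rhy_std,
                    "rhythmic_ecd": rhy_ecd,
                    "amplitude_std": np.where(rhy_std, amp_std, np.nan),
                    "amplitude_ecd": np.where(rhy_ecd, amp_ecd, np.nan),
                    "phase_std": np.where(rhy_std, phase_std, np.nan),
                    "phase_ecd": np.where(rhy_ecd, phase_ecd, np.nan),
                    "phase_shift": np.where(
                        rhy_std & rhy_ecd, shift, np.nan
                    ),
                }
            )
        )

    truth = pd.concat(truth_rows, ignore_index=True)
    gene_map = pd.concat(map_rows, ignore_index=True)
    return SyntheticDataset(matrices, truth, gene_map, cfg)


def generate_tmt_plexes(
    m: AbundanceMatrix,
    n_plexes: int | None = None,
    plex_scale_jitter: float = 0.1,
    plex_size: int = 18,
    bridge_count: int = 2,
    seed: int = 0,
) -> list[AbundanceMatrix]:
    """Split a protein matrix into TMT plexes with bridge channels.

    Samples are partitioned in column order into plexes of
    ``plex_size - bridge_count`` real channels; each plex gains ``bridge_count``
    bridge columns equal to the per-series grand mean across all samples, and
    every column in the plex (bridges included) is multiplied by a shared
    log-normal plex factor ``exp(N(0, plex_scale_jitter))``.
    """
    real_per_plex = plex_size - bridge_count
    n = m.n_samples
    if n % real_per_plex:
        raise ValueError(
            f"{n} samples cannot be partitioned into {plex_size}-plexes with "
            f"{bridge_count} bridges ({real_per_plex} real channels each)"
        )
    k = n // real_per_plex
    if n_plexes is not None and n_plexes != k:
        raise ValueError(f"n_plexes={n_plexes} inconsistent with {k} plexes of {plex_size}")
    rng = np.random.default_rng(seed)
    grand = m.values.mean(axis=1)
    plexes = []
    for i in range(k):
        factor = float(np.exp(rng.normal(0.0, plex_scale_jitter)))
        cols = m.values.columns[i * real_per_plex : (i + 1) * real_per_plex]
        vals = m.values[cols] * factor
        meta = m.samples.loc[cols].copy()
        meta["plex"] = i
        meta["channel"] = np.arange(len(cols))
        for b in range(bridge_count):
            bid = f"plex{i}_bridge{b}"
            vals[bid] = grand * factor
            meta.loc[bid] = {
                "condition": meta["condition"].iloc[0],
                "ct_hours": 0.0,
                "replicate": 0,
                "compartment": meta["compartment"].iloc[0],
                "plex": i,
                "channel": real_per_plex + b,
                "is_bridge": True,
            }
        plexes.append(AbundanceMatrix(vals, meta))
    return plexes
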
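# rerhythm

Differential circadian rhythmicity analysis across omics layers.

`rerhythm` is for chronobiologists who profile the same tissue at several
molecular layers — transcripts by RNA-seq, whole-cell and nuclear proteins by
TMT mass spectrometry — around the circadian cycle under two environmental
conditions (e.g. standard light entrainment versus an environmental circadian
disruption protocol such as repeated phase advances), and who want to know
*which* rhythms are lost, gained or retained, *where* in the gene-expression
cascade rhythmicity arises, and *how much* of the rhythmic proteome is
traceable to rhythmic transcription. It provides:

* ingestion and filtering of abundance matrices (count/intensity × sample,
  with circadian-design metadata) and TMT bridge-channel normalization;
* consensus rhythmicity detection per series;
* loss / gain / retention-of-rhythmicity (LOR / GOR / ROR) classification
  between conditions, with circular phase-shift analysis;
* gene-level integration of transcript, whole-cell-protein and
  nuclear-protein rhythms (overlap percentages, post-translational
  acquisition, transcript-contribution chain, phase lead/lag and amplitude
  ratios);
* a synthetic-data generator that reproduces the study design
  (8 timepoints × 3 h × 3 replicates × 2 conditions × 3 layers) with known
  ground truth, so every stage has a recovery test.

## The model

Rhythmicity of a log2 abundance series *y(t)* sampled at circadian times *t*
(period *T* = 24 h) is assessed by two independent detectors:

* **Cosinor regression** (parametric): least-squares fit of
  *y = M + a·cos(2πt/T) + b·sin(2πt/T)*, giving mesor *M*, amplitude
  *A = √(a² + b²)* (log2 half peak-to-trough), acrophase
  *φ = (T/2π)·atan2(b, a)*, and a p-value from the F-test of the harmonic
  against the intercept-only model (df = 2, n − 3).
* **Rank-template test** (nonparametric): the maximum Kendall τ between the
  series and a period-24 cosine template, over one template phase per
  distinct timepoint; its p-value comes from a permutation null in which
  timepoint labels are shuffled with replicate triplets kept intact,
  *p = (1 + #{perm ≥ obs}) / (1 + n_perm)*.

A series is **consensus rhythmic** only when *both* detectors are significant
at α = 0.05 — Benjamini–Hochberg q-values for transcripts, raw p-values for
proteins. Between conditions each series is classified LOR (rhythmic under
STD only), GOR (ECD only), ROR (both) or NRB (neither); the **re-writing
percentage** is 100·(LOR + GOR)/(LOR + GOR + ROR). For retained series the
circular phase shift Δφ = φ_ECD − φ_STD ∈ (−12, 12] is an *advance* when
Δφ < −3 h (one sampling interval) and a *delay* when Δφ > 3 h. At the gene
level, the share of nuclear rhythmic proteins attributable to rhythmic
transcripts is chained as
*(% NE-rhythmic also TE-rhythmic) × (% TE-rhythmic with rhythmic mRNA)*.

## Worked example

```sh
python examples/classify_rewriting.py
```

```
class counts: {'NRB': 288, 'LOR': 64, 'ROR': 31, 'GOR': 17}
rhythmic union 112; re-written 81 (72%); phase-shifted beyond 3 h: 8%
published whole-cell tally -> 98% re-written
```

A 400-gene simulated transcript set is detected under both conditions and
classified: 64 series lose their rhythm after the disruption, 17 gain one and
31 retain it, so 72% of the 112-series rhythmic union is re-written; 8% of
the union shifts phase by more than the 3-h sampling resolution. The last
line applies the same summary arithmetic to a published whole-cell proteome
tally (LOR 261, GOR 885, ROR 24), reproducing its headline 98% re-writing.
The other scripts in `examples/` walk through detection
(`simulate_and_detect.py`), TMT normalization (`tmt_normalization.py`),
cross-layer contribution analysis (`layer_contribution.py`) and population
statistics (`population_stats.py`); each prints the numbers it computes and a
line on what they mean.

A thin CLI mirrors the stages
(`rr simulate | filter | normalize | detect | compare | overlap | popstats | run`);
`rr run --seed 1 --out report.json` executes the whole pipeline on a
simulated dataset and writes a machine-readable report.

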
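# Methods

## Scope and data model

The package analyses circadian abundance time series measured in the same
tissue at three molecular layers — transcripts (RNA, raw counts), whole-cell
proteins (TE, reporter intensities) and nuclear proteins (NE) — under two
environmental conditions, a standard 12:12 entrainment (STD) and an
environmental circadian disruption protocol (ECD; repeated 6-h phase advances
of the light cycle followed by a recovery week), with all samples collected
in constant darkness. The canonical design is 8 timepoints at 3-h spacing
(CT0–CT21) × 3 replicates per condition and layer.

All layers travel through the same carrier, an `AbundanceMatrix`: a
series × sample table of non-negative values plus a sample-metadata table
(condition, circadian time, replicate, compartment, optional TMT plex /
channel / bridge flags). Detection always operates on log2(x + 1); the
pseudocount keeps zero counts finite and is negligible for quantified
series.

## Ingestion and filtering

Transcript series are filtered before analysis: a series is kept iff its
summed raw count across all samples of both conditions is ≥ 50 **and** it is
detected (count > 0) in ≥ 32 of the 48 samples. Both boundaries are
inclusive-keep, "detection" means strictly positive, and a series failing
both rules is tallied once, under low abundance. When sample counts differ
from 48 the detection threshold scales proportionally (32/48 of the sample
count, rounded). The abundance rule is interpreted as a *total* over samples
rather than a per-sample mean; the boundary behaviour is pinned by tests.

TMT plexes are normalized by their bridge (spike) channels: within each plex
every sample column is divided, per series, by the mean of that plex's bridge
columns, which carries the plex-specific scale; the result is then
re-anchored by multiplying with the per-series average of the bridge means
across plexes, restoring the original intensity scale. With noise-free
bridges this makes plexing followed by normalization an exact identity. The
re-anchoring step means the output is *not* invariant to rescaling a single
plex in the absolute sense — rescaling one plex moves every series by a
common per-series factor — but all within- and cross-plex ratios, which are
what downstream rhythm detection consumes, are exactly invariant. Series
whose bridge mean is zero in any plex are dropped with a logged count;
plexes are joined on the intersection of their series ids, so a protein
enters analysis only if quantified in every plex of its compartment.

## Rhythm detection

Two detectors are combined by an AND rule, mirroring consensus calling
between a nonparametric and a parametric rhythm detector:

**Parametric arm — cosinor.** Least-squares fit of
y = M + a·cos(ωt) + b·sin(ωt), ω = 2π/24, with replicates treated as
independent observations at their circadian time. Amplitude is
√(a² + b²) in log2 units (half peak-to-trough), acrophase is
atan2(b, a)/ω wrapped to [0, 24), and the p-value is the F-test of the
2-parameter harmonic versus the intercept-only model with df = (2, n − 3).
Degenerate inputs are pinned: a constant series yields F = 0, p = 1,
amplitude 0; an exact harmonic fit yields a p-value at the float floor
(p-values never reach 0 so that BH adjustment stays defined). The period is
fixed at 24 h; period scanning and multi-harmonic waveforms are out of
scope.

**Nonparametric arm — rank-template permutation test.** For each template
phase on the sampling grid (one per distinct timepoint) the Kendall
concordance between the series and a period-24 cosine at that phase is
computed; the statistic is the maximum over templates, and the reported
template phase breaks ties toward the earliest circadian time. Template
values are rounded (9 decimals) so that values that are mathematically tied —
the cosine is symmetric about its peak — are exactly tied; without this,
float noise breaks ties inconsistently across template phases and distorts
the statistic. The null distribution permutes timepoint labels with
replicate blocks kept intact (triplets move together), respecting the
design's within-timepoint exchangeability; p = (1 + #{perm ≥ obs})/(1 + n_perm)
with a required seed. Internally the test is vectorized as a
sign-pair matrix product, so thousands of series share one permutation set;
because every permuted statistic is an integer concordance sum, Monte-Carlo
p-values agree with exhaustive enumeration up to binomial error (verified
against an independent 8!-enumeration oracle in the tests). The default
n_perm = 10000 gives a p floor of ~1e-4; pipeline runs use 1000–2000, which
is sufficient because the test's attainable p-values are bounded below by
the block-permutation null itself (see Limitations).

**Consensus.** Benjamini–Hochberg adjustment is applied per detector within
the analysis set; a series is consensus rhythmic iff both detectors fall
below α = 0.05 — q-values for transcripts, raw p-values for proteins
(the proteome sets are far smaller and the asymmetric convention follows the
study design the package models). The consensus set is by construction a
subset of each single-detector set.

## Differential rhythmicity

With per-condition consensus calls on a common series universe, each series
is LOR (STD only), GOR (ECD only), ROR (both) or NRB (neither). The
re-writing percentage is 100·(LOR + GOR)/(LOR + GOR + ROR), reported with
half-up rounding (integer for headline values, one decimal where finer
precision is printed). For ROR series the phase shift is
Δφ = ((φ_ECD − φ_STD + 12) mod 24) − 12 mapped to (−12, 12]; a shift is
classified against the sampling resolution (3 h) with strict inequality —
|Δφ| ≤ 3 is "unshifted" — and negative shifts are advances, matching the
direction of the disruption protocol's light-cycle advances. The acrophase
used for shifts is the cosinor acrophase (the detector phase of the
parametric arm), and the cosinor amplitude is the pipeline's official
amplitude; both choices are fixed so the transcript and protein layers are
compared with the same estimator.

## Cross-layer integration

Series are joined to genes (many-to-one) and the joined universe is
restricted to genes quantified at the transcript level and at ≥ 1 protein
layer, insulating overlap percentages from the detection-breadth difference
between RNA-seq and mass spectrometry. A gene is rhythmic at a layer if any
of its series is consensus rhythmic; its gene-level phase and amplitude are
taken from its largest-amplitude rhythmic series (stable tie-break). Overlap
percentages are computed within the stated denominator (e.g. the share of
NE-rhythmic genes also TE-rhythmic divides by the NE-rhythmic count);
genes rhythmic in the nucleus but not at the whole-cell level form the
post-translationally-acquired population. The contribution chain multiplies
two printed percentages, (pct NE also TE)/100 × (pct TE with rhythmic
mRNA)/100 × 100, rounded to one decimal; because it consumes the *rounded*
percentages, it can differ in the last decimal from a chain computed on raw
counts (3.8 from inputs 14 and 27, but 2.9 from inputs 6 and 48 where
unrounded counts give 2.8 — the package documents the rounded-input
convention and keeps it).

Phase lead/lag between transcript and whole-cell protein: lead iff
(φ_protein − φ_mRNA) mod 24 ∈ (0, 12); ties at exactly 0 or 12 count as lag.
Amplitude comparison: protein higher iff strictly greater, ties count as
lower. Both tie conventions are arbitrary, fixed and tested.

## Population statistics

Cumulative daily abundance is the sum over timepoints of the replicate mean
on the *linear* scale (abundance is cumulative material, not log signal);
its percent change is 100·(S_ECD − S_STD)/S_STD, NA when S_STD = 0.
Population comparisons use the classical pooled-variance (Student) unpaired
two-tailed t-test, with Welch available behind a flag; zero-pooled-variance
degenerate inputs give t = 0, p = 1 for equal means and a float-floor
p-value otherwise. Phase histograms use half-open 3-h bins plus the circular
mean and mean resultant length; no uniformity test is attached (the
summaries are descriptive).

## Synthetic data generator

The generator emulates the study design, not the measurement physics. Per
(gene, layer) a change class is assigned — LOR, GOR, phase-stable ROR,
phase-advanced ROR, or NRB — either by exact quotas (largest-remainder
apportionment; the default for tests, making realized counts deterministic)
or binomially. Defaults follow the modeled system: STD rhythmic fractions
0.261 / 0.039 / 0.093 for RNA / TE / NE, class probabilities matching the
published tallies, transcript acrophases uniform, whole-cell protein
acrophases bimodal around CT7/CT17, nuclear acrophases unimodal around CT20
(von Mises mixtures, κ = 2). Rhythmic series follow
mesor + A·cos(2π(t − φ)/24) on the log2 scale with i.i.d. Gaussian noise
(default sd 0.2); phase-advanced genes get φ_ECD = (φ_STD − 6) mod 24.
Log2 half-amplitudes are Gaussian (default mean 0.5, sd 0.25) truncated at a
floor (0.1); mesors are Gaussian (mean 8, sd 2 log2 units). Noise
magnitudes, amplitude and mesor distributions are free parameters of the
generator, documented here, not estimates of any particular dataset.

Transcripts are back-transformed to counts, round(2^x − 1) floored at 0 —
a deliberate simplification that keeps the detectors' log2 view exact rather
than modeling Poisson/negative-binomial sampling. Dropout zeroes a count
with probability dropout_rate·exp(−count/dropout_scale) (defaults 0.2 and
5 counts): the zero probability is abundance-dependent because in bulk
RNA-seq zeros arise for low-abundance molecules, not at a flat rate across
the dynamic range; the flat rate is recovered in the low-count limit.
Protein layers stay on a continuous positive scale (2^x). TMT plexing
splits a 48-sample protein matrix into three 18-channel plexes (16 real + 2
bridges), multiplies each plex (bridges included) by a shared log-normal
factor, and sets bridge channels to the per-series grand mean times that
factor — so bridge normalization can undo the batch factor exactly at zero
jitter.

What passing recovery tests on these data do **not** show: robustness to
waveform asymmetry, damped oscillations, autocorrelated or heteroscedastic
noise, missing timepoints, peptide-level quantification artifacts, or
isoform complexity. They show that the detection → classification →
integration arithmetic recovers a known design under the stated noise model.

## Pipeline and reproducibility

`run_pipeline` chains simulate/ingest → filter → detect (per condition and
layer, q for transcripts, p for proteins) → classify → integrate →
population statistics, and emits one JSON report of every summary. All
randomness descends from a single root seed through spawned child sequences
(one per condition × layer for the permutation tests), so reports are
byte-identical across runs; seeds are required arguments wherever
permutations occur. The acceptance script re-runs the full stack at 1000
genes with n_perm = 2000 — sizes at which every stage's behaviour is
measurable in seconds on one core — and reports recovery statistics next to
the published-count arithmetic.

## Design choices made where the design was open

* The two published detector tools are replaced by two in-package detectors
  with the same consensus *structure* (independent parametric +
  nonparametric arms, AND rule, q/p asymmetry); detectors sit behind a
  single fit-table interface and are pluggable.
* Replicates are never averaged before testing (averaging is a
  configuration, not the default).
* "Advance" is negative Δφ; the ±12 h boundary maps to +12.
* The gene-level "rhythmic" flag uses the ANY rule over a gene's series.
* Percentages destined for headlines round half-up; chained percentages
  consume rounded inputs.

## Limitations

* The rank-template statistic is quantized: on an 8-point grid its
  block-permutation p-values have a hard floor (64/40320 ≈ 0.0016 for
  on-grid acrophases), and a series peaking midway between grid points —
  where the two neighbouring samples tie — cannot reach an exact p below
  ≈ 0.022 *even noiselessly*. Under BH adjustment in sets whose rhythmic
  fraction is small, such mid-grid series are systematically uncallable by
  the consensus regardless of amplitude; per-condition recall therefore
  saturates around 0.90–0.95 for uniformly distributed phases. This is a
  property of grid-template rank tests at coarse sampling, not of the
  implementation.
* The consensus false-positive rate for protein layers (raw p thresholds)
  is bounded by α per detector but the two detectors are correlated on the
  same data, so the consensus rate is close to, not far below, α.
* The count model omits mean–variance coupling; the cumulative-abundance
  change of rhythmic populations is slightly negative upon rhythm loss
  purely through the convexity of 2^x.
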
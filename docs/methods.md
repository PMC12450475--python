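# Methods

## Model and assumptions

The core quantity is the expected fractional transcription loss of a cell
after `M` transcription-blocking lesions (TBLs),

    E[ω_M] = Σ_j α_j (1 − (1 − q_j)^M),    q_j = l_j / (4L),

under four assumptions: (1) lesions are placed independently and uniformly
over the diploid, double-stranded genome (no hotspots); (2) each gene has
two alleles contributing equally to its transcription; (3) only lesions on
a transcribed strand block transcription — a single such hit silences that
allele entirely and permanently (no repair, no bypass, no partial
transcripts in the loss accounting); (4) the genome is diploid (polyploid
nuclei are excluded at the measurement stage for this reason). `l_j` is the
genomic span (introns included) of the gene's longest transcript; `α_j` is
the gene's share of total nascent transcription (Σα = 1); `L` is the
haploid genome length, multiplied by 4 because each gene body exists as two
alleles × two strands.

Numerics: `(1−q)^M` is evaluated as `exp(M·log1p(−q))`, stable for
`q ~ 1e-6` and `M ~ 1e9`; the weighted sum is clipped to [0, 1] against
~1-ulp overshoot at saturation. `M` is an integer count of events; products
`r·Δt` are rounded half-away-from-zero (no convention is canonical here;
rounding error is at most one lesion).

Lesion **density** (per 100 kb) is counted against the haploid length `L`,
matching how dose tables and whole-genome totals are conventionally
printed, even though the placement probability uses `4L`. The UV conversion
0.55 lesions/100 kb per J/m² is a configurable constant (the literature
value is approximate).

## Monte-Carlo oracle

The simulator draws, per replicate, a multinomial over `2G+1` categories:
the transcribed strand of each allele of each gene (probability `q_j`
each) and "everything else" (untranscribed strands + intergenic sequence),
which is tracked but has no effect. An allele is silenced iff its category
count is ≥ 1; realized loss is `Σ_j α_j (hit1_j + hit2_j)/2`. Sampling by
category rather than by base-pair coordinate is exactly equivalent under
uniformity (only hit/no-hit per transcribed strand enters ω) and orders of
magnitude cheaper. Multiple lesions may land on one strand (independent
placement, no exclusion). Trajectories place only the increment of new
lesions at each age and OR the silencing state forward, so realized loss is
non-decreasing within a replicate.

## Rate calibration

Given an observed loss series (age in weeks, mean loss %, SEM) for one
genotype, the daily rate `r` is fit at a single calibration point: bisect
for the integer `M*` whose expected loss is nearest the observed fraction
(E[ω] is strictly monotone toward Σα, so bisection is exact; the
calibration misfit is bounded by the gap between adjacent integer-`M`
losses), then `r = M*/Δt` with `Δt` the days since the zero-loss age `t0`.
Remaining points are validation: absolute error `|predicted − observed|`
in percentage points, relative error as that magnitude over the observed
loss × 100. With replicate catalogs (one per sequenced animal), `r` is fit
per catalog and reported as mean ± SD; rates are rounded to whole
lesions/day for reporting.

**t0 convention.** `t0` is an explicit series field, default 0 (lesions
accumulate from birth). That is the right convention for severely
repair-deficient genotypes, which already show large loss at their first
measured age. For a slowly accumulating wildtype-like series whose first
point is *defined* as lossless, set `t0` to that first age and calibrate on
the last point (`calibrate_on="last"`), predicting the first — with only
two points, calibrating on the later one avoids underestimating the
burden. Note the two published wildtype figures — 62 lesions/day in the
rate table versus "approximately 15" in discussion prose — are not mutually
consistent; this package follows the rate-table convention (62/day, which
also reproduces the ≈1.58–1.59 lesions/100 kb implied density at 104
weeks) and does not attempt to reconcile the other figure.

Repair-capacity arithmetic compares two genotype rates: daily difference
`r_ref − r_def`, that difference as a percent of `r_ref` (capacity of the
pathway separating the genotypes), percent of lesions persisting
(`r_def/r_ref`), percent repaired (its complement), and a projection
`r_ref·(1 − residual_fraction)` for hypomorphic alleles with known residual
activity.

## Dose-response

Replicate EU-intensity observations are normalized to their own untreated
(0 J/m²) control, converted to loss = 100 − intensity, and pooled as mean ±
SEM across replicates. Linear and third-order-polynomial fits are ordinary
least squares on the Vandermonde design (numpy polynomial least squares);
the cubic captures the plateau at high dose where new lesions increasingly
hit silenced genes. The error table reports, per non-reference dose,
|model − data| in percentage points (printed as magnitudes), the relative
error (magnitude over measured loss × 100), and both in multiples of the
experimental SEM, plus column means. Doses with zero measured loss have
undefined relative error and are excluded from that mean.

## Gene-body tilt

Each gene body is split into equal-width bins (default 20; equal-width
binning length-normalizes genes so tilts are comparable), ordered 5′→3′
with strand resolved upstream. Tilt = OLS slope(after) − OLS slope(before)
in RPKM per bin; it is antisymmetric, zero on identical profiles, and
scales linearly with the coverage units. No published bin count,
normalization window, or end-trimming rule exists for this statistic; the
defaults here are the package's own and are not claimed to reproduce any
specific published processing.

## Image quantification

Nuclei: global Otsu threshold on the DNA (Hoechst) channel, hole filling,
connected-component labeling; touching nuclei may merge (no watershed).
Nucleoli: grey-opening background subtraction (rolling-ball-style disk,
default radius 25 px) on the EU channel, then a moment-preserving (Tsai,
ImageJ-"Moments"-style) threshold over nuclear pixels; the implementation
is the standard three-moment-preserving histogram rule, written in-package
because scikit-image does not ship it. Nucleoli are segmented on the EU
channel, where they are bright (rRNA transcription is damage-resistant) —
excluding them from the nucleoplasm mean is the point of the step.
Per nucleus: area (pixel count × pixel size²), circularity 4πA/P² with a
Crofton perimeter estimate clipped at 1.0, and the mean EU over the
nucleoplasm (nucleus minus nucleoli). Species filters: mouse hepatocyte
24.4–70 µm² and circularity > 0.7 (the upper bound excludes polyploid
nuclei, which the diploid model cannot describe); human fibroblast
24.4–250 µm² and circularity > 0.6. The low-EU (Kupffer-like) cutoff has no
published numeric value; the default — 20% of the field's median EU over
size-passing nuclei — is the package's own choice. All flags are computed
independently, so exclusion is order-free. The per-field summary is the
median nucleoplasmic mean over retained nuclei; cohorts are normalized to a
reference field set (×100%).

## Synthetic data

Generators are deterministic per seed and emulate the statistical structure
the analysis assumes — not real biology beyond it:

- **Catalogs**: gene spans log-normal (median 25 kb, σ(log) = 1.1, a
  mammalian-like spread), redrawn into [5 kb, 750 kb]; expression
  log-normal (σ = 1.5). The mouse-liver-like default applies a long-gene
  expression boost (raw expression × (l/median)^0.9), calibrated so a
  wildtype-like trajectory (62 lesions/day from 7 weeks, L = 2.65 Gb)
  reaches the ≈30% loss observed in 2-year-old liver; the human-fibroblast
  config (21,500 genes, L = 3.2 Gb) disables the boost, since those long
  highly expressed genes are largely liver-specific. Replicate catalogs
  share genes and lengths and jitter expression log-normally (σ = 0.2),
  emulating per-animal sequencing.
- **Longitudinal series**: per time point, `n_mice` draws of
  100·E[ω_M] + N(0, 2 percentage points), defaults n = 3 (mutant-genotype
  design; wildtype runs use 4); the series stores their mean and SEM.
- **Dose-response**: intensity 100·(1 − E[ω]) at the dose-implied `M`,
  plus Gaussian noise per replicate (default 4 replicates).
- **Profiles**: exact linear before/after pairs with a prescribed tilt
  (clipped at zero RPKM — keep |slope|·bins below the baseline of 25 when
  an exact tilt is required), and a truncation generator where each of 200
  transcripts per gene stalls at a geometric random bin.
- **Fields**: 384×384 px at 0.3 µm/px, ~12 non-overlapping disk nuclei per
  field across four classes (hepatocyte 35–60 µm², fragments 8–18 µm²,
  Kupffer-like at 5% EU, polyploid-like 80–130 µm²), EU-bright/DNA-dim
  nucleoli, additive Gaussian noise.

Passing tests on these inputs demonstrates correctness of the estimators
under the model's own assumptions (uniform placement, binary allele
silencing, Gaussian observation noise, circular nuclei). They do not
demonstrate robustness to what real data add: non-uniform damage and repair
(hotspots, transcription-coupled repair gradients), partial transcripts,
mapping artifacts, irregular nucleus shapes, illumination gradients, or
batch effects.

## Problem sizes and reproducibility

Default analysis sizes: 9,000-gene catalogs, 10,000 Monte-Carlo replicates
for oracle comparisons, four 384×384 fields per image cohort — sizes at
which every estimator's sampling error is far below the effects being
checked, while the full suite and the acceptance script each run in well
under two minutes. Under the longitudinal design above (2-pp noise, 3–4
animals, one series per genotype), the rate estimator is unbiased with a
4–6% coefficient of variation, so individual recovered rates scatter a few
percent around truth; Monte-Carlo z-scores against the closed form are
reported as a maximum over 15 checks and occasionally approach 3. All
generators take explicit seeds; `scripts/acceptance.py` derives every
stream from its `--seed` argument.

## Known limitations

- No repair kinetics, replication, transcriptional bypass, or ploidy in
  the model; the measurement stage compensates only by excluding polyploid
  nuclei.
- The closed form and simulator treat gene silencing as binary per allele;
  graded elongation failure appears only in the tilt statistic, which is
  deliberately separate.
- GTF handling expects `transcript` (or `mRNA`) features, falling back to
  exon grouping; exotic dialects are not supported.
- The moments threshold follows Tsai's construction; no claim is made of
  bit-identity with any particular ImageJ build.
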
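# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-data generators emulate (and do
not), and the numerical and design choices made where the procedure left
room.

## Array preprocessing

Input is a features × samples grid of background-subtracted raw
intensities (arbitrary units). The stage chain is enforced by type:
`raw → filtered → shifted → log2 → quantile_normalized → standardized`.

* **Intensity filter** — a probe is kept iff its maximum across samples is
  ≥ `intensity_threshold` (default 150 raw units). Boundary semantics:
  "less than 150 excluded" means exactly 150 is retained. Probes with any
  missing raw value are excluded here as well, so all later stages are
  total. An alternative detection filter (score > 0.95 in ≥ 1 sample,
  strict inequality) serves gene-expression matrices.
* **Shift** — per sample, the constant `1 − min` is added so every
  sample's minimum is exactly 1; this makes log2 total even when
  background subtraction produced negative intensities. Idempotent.
* **Quantile normalisation** — every sample is mapped onto the
  mean-of-sorted-values reference at its within-sample ranks. Ties
  receive the mean of the reference values across the tied rank span (the
  common reference behaviour; dialects differ, so it is pinned here).
  Within-sample rank order is preserved; the operation is idempotent.
* **Standardisation** — per feature, mean 0 / sd 1 using the sample
  standard deviation (n−1 denominator; the denominator is a convention
  choice, pinned to n−1). Default is per hybridisation run
  (`standardize_within='run'`), because the two runs differ systematically
  in probe intensity. Features constant within a run are set to 0 and
  flagged rather than dropped, keeping feature sets aligned across runs.

## Differential expression

Per feature, a two-way fixed-effects linear model
`y = intercept + group + chip` (no interaction), fitted by least squares
simultaneously for all features via projection matrices. The group effect
is tested with a partial F: F = ((RSS_reduced − RSS_full)/df1) /
(RSS_full/df2), reduced model = intercept + chip. Chip dummy columns that
do not increase the design rank are dropped; if a group dummy then fails
to increase rank, the group is aliased with chips and the model aborts
with the confounded levels named. Degenerate features (zero residual *and*
zero effect, e.g. constant data) are flagged and reported at p = 1 rather
than NaN; zero residual with a real effect reports p = 0.

Multiple testing uses Benjamini–Hochberg step-up adjustment (delegated to
statsmodels). Fold change is computed from quantile-normalised log2 group
means: r = 2^(mean_A − mean_B), reported as r when r ≥ 1 and −1/r
otherwise, so |fc| ≥ 1 and swapping the contrast negates the value. The
direction label derives from the sign; the source report pairs negative
fold changes with "Up" under an undefined reference convention, so this
package defines its own and does not reproduce those signs. Signature
selection takes the top N per contrast by |fc| (defaults 75 and 100), ties
broken by feature id ascending, unioned and deterministically ordered.

Either side of a contrast may pool several group labels (e.g. both basal
groups vs. luminal), implemented by collapsing the pooled labels into one
factor level before fitting.

## Clustering

Samples are clustered over the signature (feature clustering is a
transposition away). Distance is d(i,j) = 1 − Pearson r of the two
samples' standardised feature vectors (range [0, 2]); zero-variance
samples are an error naming the sample. UPGMA (average linkage) is
implemented directly: at each step the pair of clusters with minimal mean
inter-cluster distance merges; ties break by the lexicographically
smallest pair of sorted leaf-id tuples, which makes the tree invariant to
sample input order — scipy's linkage does not pin this, which is why the
algorithm is in-package (scipy remains the cross-check oracle in the test
suite on tie-free instances). k clusters are read off by discarding the
k−1 highest merges (heights are non-decreasing under average linkage);
labels are ordered by each cluster's smallest member id. Newick export
uses branch length = parent merge height − child height (leaves at 0),
yielding an ultrametric tree that round-trips through standard parsers.

## Target consensus

Prediction tables are opaque inputs, one per source; individual
algorithms have benchmark specificities near 44–61 %, so pairs are pooled
by union (per-pair source provenance retained) and a gene is kept only
with support from ≥ `min_support` (default 3) distinct differentially
expressed miRNAs. Support is counted per miRNA direction: a gene can
reach support among up-regulated miRNAs (predicted protein down), among
down-regulated miRNAs (predicted protein up), or both, in which case it
appears in both lists with `in_both_lists` set — mixed-direction support
is surfaced, not resolved, mirroring how the overlap between the two
published lists was reported rather than adjudicated. Overlap statistics
count list entries (n_total = n_up + n_down), so the overlap fraction is
n_overlap/(n_up + n_down), matching the published 71/1218 = 5.8 %
convention; distinct-gene counts are reported alongside.

The cleavage cross-reference flags a consensus gene when its mRNA is
differentially expressed (BH q < 0.05) and — by default — moves opposite
to its supporting miRNAs (cleavage lowers the mRNA of targets of
up-regulated miRNAs). The direction requirement is switchable
(`require_opposite_mrna_direction`) because the source procedure says only
"cross-matched".

## IHC panel

Composite score = intensity (0–3) + proportion category (0–4), max 7.
Positivity = any staining (intensity ≥ 1 and proportion ≥ 1); ingestion
enforces intensity = 0 ⇔ proportion = 0. Marker comparisons use evaluable
records only: Pearson chi-square on the positivity 2×2 (df = 1, no
continuity correction — validated by exact reproduction of the published
initial-cohort p-values 0.025 / 0.002 / 0.002 from their printed tables)
and a two-sided Mann–Whitney U on composite scores. The U test enumerates
the exact null distribution when both groups have ≤ 8 tie-free
observations, otherwise uses the normal approximation with tie correction
and no continuity correction (so identical samples give p = 1 exactly);
the in-package implementation exists because that degenerate-tie contract
is pinned, with scipy and full permutation enumeration as test oracles.

The classifier calls BRCA1 when ≥ k of the panel markers are negative
(default 2 of FOXP1, cyclin D1, NRP1). Cases missing any panel marker are
excluded and counted, not imputed. The report always shows cohort PPV/NPV
(from the cohort's own prevalence) next to Bayes-adjusted values at the
derived prevalence prev = P(mut) · P(basal|mut) / P(basal); defaults
0.02 · 0.69 / 0.15 = 0.092.

**Known discrepancy.** At the reported rule performance (sensitivity 0.92,
specificity 0.44) and prevalence 0.092, the standard Bayes formula gives
PPV ≈ 14.3 % and NPV ≈ 98.2 %, not the published 38 % / 94 %; the
published figures imply a prevalence near 0.27 whose derivation is not
stated. The package implements the standard formula and reports this
difference rather than matching the printed values.

## Synthetic data

The generators produce inputs with the statistical shape the analysis
assumes, with planted truth records for recovery testing. All draw from
per-component sub-streams of a single seed, so enlarging one component
never perturbs another, and identical configs give byte-identical outputs.

* **Expression** (`ExpressionSimConfig`): raw intensity =
  2^(baseline + group effect + chip offset + noise) × run scale −
  optional negative offset. Defaults mirror the profiled cohort: 1145
  probes with ~108 planted below the 150-unit floor; 13 normal / 17
  luminal / 16 sporadic-basal / 11 BRCA1-basal samples; one chip in run 1
  (11 samples) and the rest on ≤ 12-sample chips in run 2, with samples
  randomised across chips (a sequential layout is available to study
  chip–group confounding). Planted log2 effect 2.0 on 50 features per
  contrast (disjoint sets; basal-contrast effects hit both basal groups,
  BRCA1-contrast effects only the BRCA1 group), residual log2 sd 0.5,
  per-chip offsets with sd 0.25 drawn **per probe** — probe-specific
  batch effects are what bead arrays show, and a constant per-sample
  offset would be removed exactly by quantile normalisation — and a
  ×1.3 raw-scale distortion of run 2.
* **Targets** (`TargetSimConfig`): one table per source; each source
  emits every true pair plus round(n_true·(1−q)/q) false pairs so its
  true fraction equals its specificity q (defaults 0.44 and 0.61). Fifty
  consensus genes are planted with 3–5 true supporting miRNAs of a common
  direction over a 2000-gene universe.
* **mRNA / cleavage** (`CleavageSimConfig`): exactly
  round(0.20 · n_consensus) genes (seeded sampling without replacement)
  receive a log2 shift of 1.0 opposite in sign to their miRNAs, over a
  14 + 10 sample cohort (the size of the mRNA comparison). The 1.0
  (2-fold) effect is a realistic magnitude for cleavage-driven mRNA loss.
* **IHC** (`IHCCohortSimConfig`): 82 + 65 cases; per-marker positivity
  defaults are the validation-cohort percentages (FOXP1 0.52/0.94,
  cyclin D1 0.57/0.89, NRP1 0.41/0.72). Within-case correlation of marker
  negativity enters through a shared latent case factor (Gaussian copula,
  latent correlation 0.3 by default — a moderate value chosen once; no
  joint distribution is published), leaving marginal rates exact.
  Positive cases draw intensity/proportion categories from configurable
  distributions; 5 % of records default to non-evaluable, emulating
  uninterpretable TMA cores.

What the generators do **not** emulate: the real probe-level effect-size
spectrum and correlation structure, probe cross-hybridisation, the actual
GEO cohorts' miRNA identities, or the joint staining patterns of the real
TMA cohorts. Passing recovery tests therefore shows the pipeline's
statistics behave correctly under the assumed model, not that the
published cohort-level results are reproduced — those require the
deposited arrays, historical prediction databases and unpublished joint
staining data, and are deliberately out of the test targets.

## Calibrated expectations

Monte-Carlo calibrations (run before freezing any threshold) under the
default conditions: differential-expression power for the planted effect
is ~1.0 (test threshold 0.90); the null BH rejection fraction is ~0;
omitting the chip covariate under the confounded layout inflates the raw
false-positive rate from ~0.05 to ~0.65; the standard clustering fixture
(effect 2.0, noise 0.5, 15 + 15 samples) yields adjusted Rand index ≥ 0.9
in 49/50 seeds; the cleavage-flag recovery over 20 seeds has mean
sensitivity 0.545 (per-seed range 0.1–0.9, driven by BH dilution across
the 2000-gene universe at n = 14 + 10) with zero observed false flags,
frozen as the test envelope mean ∈ [0.35, 0.75], FDR ≤ 0.10.

## Problem sizes

The test suite and acceptance script run the study-sized expression
simulation (1145 × 57), a 300-probe clustering fixture, a 2000-gene
target universe with 10 replicate cleavage runs, and IHC cohorts up to
1000 + 1000 cases — sizes chosen so the whole suite completes in well
under a minute per stage while keeping binomial standard errors small
enough for 3-SE recovery checks.

## Limitations

Variance shrinkage (empirical-Bayes moderation) is deliberately absent —
the modelled procedure uses plain ANOVA. No bootstrap cluster stability,
no heatmap rendering, no probe re-annotation across miRBase versions, no
vendor binary formats. Sensitivity/specificity of the published cohorts
cannot be recomputed from printed marginals (joint staining patterns are
unpublished) and are treated as non-reproducible inputs wherever they
appear.
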
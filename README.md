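# basalmir

Comparative miRNA profiling of sporadic vs. BRCA1 basal-like breast
cancer, as a tested, reusable Python pipeline.

Basal-like breast cancers (ER/PR/HER2-negative, CK5/6- or EGFR-positive)
account for ~15 % of breast cancers, and germline *BRCA1* mutation
carriers develop the basal phenotype far more often than not. Whether a
basal tumour carries a *BRCA1* mutation matters clinically (gene testing,
PARP-inhibitor eligibility), which motivates two linked analyses:

1. **miRNA array profiling** — do BRCA1 basal cancers carry a distinct,
   grade-independent miRNA signature relative to sporadic basal and
   luminal cancers?
2. **Protein-level read-out** — can the predicted protein consequences of
   that signature be detected by immunohistochemistry (IHC) and used as a
   cheap diagnostic triage for *BRCA1* testing?

`basalmir` implements the full analysis chain for both questions, plus a
seeded synthetic-data module that generates inputs with planted,
recoverable structure, so every stage is testable without any download.

## The methods, in brief

**Preprocessing.** Probes with maximum background-subtracted intensity
< 150 units across all samples are excluded; each sample is shifted so its
minimum intensity equals 1; values are log2 transformed and quantile
normalised (every sample is mapped onto the mean-of-sorted-values
reference distribution). For clustering, each feature is standardised to
mean 0 / sd 1 separately per hybridisation run, because runs differ
systematically in probe intensity.

**Differential expression.** Per feature, a two-way fixed-effects linear
model `log2 intensity ~ group + chip` (no interaction) with a partial
F-test for the group factor, i.e. ANOVA with the BeadChip as covariate.
Raw p-values get Benjamini–Hochberg step-up adjustment; fold changes are
anti-logged group-mean differences with the signed convention
fc = r if r ≥ 1 else −1/r. Signatures are the union of the top-N features
per contrast ranked by |fold change| (defaults: 75 for basal vs. luminal,
100 for BRCA1 vs. sporadic basal).

**Clustering.** Samples are clustered over the signature with average
linkage (UPGMA) on Pearson-correlation distance d = 1 − r, with a
deterministic lexicographic tie-break, k-cuts read off the dendrogram, and
Newick export.

**Target consensus.** miRNA→gene predictions from several sources are
pooled by union search; a gene is retained only when ≥ 3 distinct
differentially expressed miRNAs of a common direction target it (targets
of up-regulated miRNAs are the predicted protein-*down* list and vice
versa). Because only ~20 % of miRNA targets undergo RISC-mediated
cleavage, consensus genes are optionally cross-referenced against mRNA
differential expression and flagged when the mRNA itself shifts opposite
to its miRNAs.

**IHC panel.** Staining is scored as intensity (0–3) plus stained-cell
proportion category (0–4), a composite score out of 7; positivity is any
staining. Groups are compared per marker by Pearson chi-square on
positivity (df = 1, no continuity correction) and Mann–Whitney U on the
composite scores. The diagnostic rule calls a case BRCA1 when ≥ k of n
panel markers (default 2 of FOXP1, cyclin D1, NRP1) are negative; besides
cohort PPV/NPV, Bayes-adjusted predictive values are reported at the
BRCA1-among-basal prevalence implied by population assumptions
(P(mut) · P(basal|mut) / P(basal) = 0.02 · 0.69 / 0.15 = 0.092).

## Worked example

Chi-square on a published-style staining table (cyclin D1: 8/22 positive
BRCA1 vs. 30/46 positive sporadic) and the prevalence-adjusted predictive
values at rule sensitivity 0.92 / specificity 0.44:

```python
>>> from basalmir.ihc import chisq_2x2, prevalence_adjusted_pv
>>> chisq_2x2(8, 14, 30, 16)
(5.025615421954096, 0.02497504853930321)
>>> prevalence_adjusted_pv(0.92, 0.44)
(0.1427029943350418, 0.9819111285882817, 0.092)
```

The chi-square statistic 5.03 gives p = 0.025: cyclin D1 positivity
differs between the groups. At the derived prevalence 0.092, a positive
panel call is right ~14 % of the time and a negative call ~98 % — the
asymmetry expected for a sensitive-but-unspecific rule at low prevalence.

An end-to-end run on seeded synthetic inputs:

```bash
basalmir run --seed 1 --out-dir results/
```

writes the simulated raw matrix, normalised/standardised matrices, two
differential-expression tables, the dendrogram (Newick), cluster
composition, consensus-target table with cleavage flags, per-marker IHC
comparisons, the panel report and a manifest with content hashes. On the
default study-sized simulation the two planted basal sub-groups separate
perfectly:

```
cluster  basal_brca1  basal_sporadic  size  majority_group  purity
0        11           0               11    basal_brca1     1.0
1        0            16              16    basal_sporadic  1.0
```

Each stage is also exposed as an sklearn-style estimator
(`ArrayPreprocessor`, `RunStandardizer`, `GroupDifferentialExpression`,
`SignatureClusterer`, `NegativeMarkerPanel`) with `fit`/`transform`/
`predict` and `get_params`/`set_params`, so stages compose with sklearn
pipelines; the module-level functions are thin wrappers over the same
code.

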
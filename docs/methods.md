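# Methods

## The analysis problem

Marker-free CTC enrichment (filtration plus CD45/CD50 immunomagnetic
depletion) deliberately avoids epithelial capture antigens so that EMT and
stem-like CTCs are not lost, at the cost of residual leukocytes and
endothelial cells among the sequenced candidates. The pipeline therefore
works entirely from the quantified single-cell transcriptomes (TPM): it
removes contaminants by marker expression, phenotypes the surviving CTCs on
two marker axes, and relates the resulting CTC types to patient outcome.
Upstream steps (microscopy, library preparation, alignment, TPM
quantification) are out of scope; the pipeline consumes a genes × cells TPM
matrix, per-cell metadata (patient, uniquely mapped reads, cluster flag) and
a per-patient clinical table.

## QC and contaminant elimination

* Read-depth: a candidate passes with **strictly more than**
  `min_reads = 100,000` uniquely mapped reads (a secondary 400,000 tier is
  reported but does not exclude). The strict inequality is deliberate; the
  boundary case fails.
* Positivity: a marker counts as expressed at `positivity_tpm = 1.0` TPM.
  One TPM is the conventional detection floor for a gene in a single cell;
  the threshold is configurable.
* Rules, in precedence order: *PTPRC* ≥ threshold → leukocyte (or
  `mixed_cluster` when the object is a multi-cell cluster; clusters with
  conjugated leukocytes are indistinguishable from leukocytes in this assay
  and are always excluded); else *PECAM1* ≥ threshold → endothelial; else
  retained. Leukocyte-over-endothelial precedence reflects the dominant
  contaminant of the enrichment chemistry and is configurable in effect via
  the threshold.
* Retention percentages are rounded half-up to integer percent, the
  convention of clinical summary tables.

## Scores, clustering and group naming

The panel score is the **sum** of log₁₀(TPM+1) over the panel's genes (a
mean variant is available). The published analysis never defines its
"gene expression score"; a sum on the heatmap's log scale is the simplest
definition consistent with the reported group orderings, and missing genes
contribute zero so partial matrices remain scorable.

Clustering is agglomerative with Ward linkage on Euclidean distances of the
log₁₀(TPM+1) marker submatrix — the standard default for expression
heatmaps — cut to exactly k clusters (k = 3 on the 14-gene epithelial axis,
k = 4 on the 18-gene EMT/stem axis). Clusters are **named by empirical
score ordering**, never by dendrogram position: ascending mean epithelial
score → Low/Middle/High; the maximal mean stem score → `HighStem_LowEMT`,
the remainder by descending mean EMT score. (The source text's cluster
letters are internally inconsistent between narrative and table; naming by
score ordering removes the ambiguity.) Ties in cluster means are broken by
cluster size, larger cluster first, and logged.

Between-group score differences use the two-sided Mann–Whitney U test:
exact (equivalently, the full permutation distribution) for small untied
samples, otherwise the normal approximation with tie correction and no
continuity correction — so identical groups give p = 1 exactly. The
stem-score comparisons on synthetic data routinely encounter all-zero
groups; a pooled zero-variance input short-circuits to p = 1.

## Contingency statistics

Pearson's χ² (Σ(O−E)²/E, df = (r−1)(c−1)) with a logged warning when any
expected count is below 5 — with 59 cells over 12 categories most expected
counts are small, so the residual analysis, not the global test, carries
the interpretation. "Residual analysis" is implemented as Haberman
adjusted standardized residuals with signed two-sided cutpoints 1.96
(p < 0.05) and 2.58 (p < 0.01); the two levels are reported distinctly. No
multiple-testing correction is applied across the 12 cells, matching the
published procedure.

Fisher's exact test sums hypergeometric probabilities ≤ the observed
table's over all tables with fixed margins, in exact `Fraction` arithmetic
(no floating-point inclusion fudge); detection-rate comparisons treat the
two rates as independent 2×2 groups, as the published analysis evidently
did despite the paired patients — an exact McNemar variant is provided but
non-default. On the published counts the epithelial-vs-EMT comparison gives
p = 0.002407 and epithelial-vs-combined gives p = 1.75 × 10⁻⁵ (the printed
"0.0001" is a display rounding; the computed value is reported).

Heterogeneity counts a patient as multi-category when their cells span ≥ 2
classes among {1, 2, 3, 4, other}; pair fractions are per multi-category
patient containing the pair.

## Survival

Kaplan–Meier estimation and the median CI come from `lifelines`; the median
is the smallest t with S(t) ≤ 0.5 and its CI is read off the pointwise
log-log confidence band (Brookmeyer–Crowley-style inversion). The CI method
behind the published table's negative bounds is not recoverable from the
text and is not imitated.

The "Generalized Wilcoxon" test is implemented as Gehan–Breslow. Events
precede censorings at tied times. Because the normal approximation is
unusable at the cohort sizes where the test is actually applied to single
strata pairs (N ≈ 22), the default `method="auto"` enumerates the exact
permutation distribution of W whenever C(N, n_a) ≤ 20,000 and falls back to
z = W/√Var with the permutation variance otherwise. Zero variance with
W = 0 returns p = 1. Stratification rules select patients with ≥ k CTCs of
a type after restricting to treatment line ≥ 2 (configurable); an
`exclusive` flag additionally requires no other CTC type be detectable,
expressing the "only EMT CTCs" reading of the headline stratification.

## Synthetic-data generator

The generator emulates what the analysis assumes about real data, not the
full transcriptome: eight archetypes over a 500-gene universe (32 panel
genes + 468 background genes). On-genes draw TPM = 10^N(μ, σ) with
σ = 0.5 and per-archetype μ, then drop out with probability 0.2; background
genes (never panel genes) are nonzero with rate 0.05 at μ = 0.5.

Archetype design (chosen once, by separation analysis): epithelial-middle
cells express the 6-gene core (EPCAM, CLDN4, KRT8/18/19/20) at μ = 2.0;
epithelial-high adds CLDN3 and CLDN7 at μ = 2.4; high-EMT cells express the
full 7-gene EMT panel at μ = 2.4 while middle-EMT cells express only the
VIM/SPARC/ITGB1 core at μ = 2.0; stem-like clusters co-express the
epithelial-high set with CD44/ALDH2/MYC at μ = 2.4 and carry the cluster
flag; leukocytes and endothelial cells express PTPRC / PECAM1 at μ = 3.0;
mixed clusters add PTPRC to the epithelial core. With these means every
adjacent class boundary lies ≥ ~3.1σ from both centroids in the clustered
marker space, which is what makes noise-free recovery exact and
default-noise recovery ≥ 90 %. Contaminant archetypes use dropout
min(0.02, global rate): PTPRC and PECAM1 are constitutively abundant in
their lineages, and single-cell dropout probability falls steeply with
abundance — a leukocyte losing PTPRC at rate 0.2 would be biologically
unrealistic and would make transcriptome-based depletion impossible by
construction.

Cohorts: candidate counts per patient are Poisson(3) (sparse clinical CTC
counts, range ≈ 0–10, median ≈ 2–3); archetype mixture defaults reflect
roughly half contaminants and an EMT-dominated CTC compartment. Survival is
exponential — PFS hazard 0.009/day (median ≈ 77 d), OS hazard 0.35× that —
multiplied by `hazard_ratio_emt = 3` for patients with ≥ 2 true EMT CTCs,
censored uniformly on [100, 800] days; about 18.5 % of patients are
first-line and excluded from the stratified analysis. The generator does
**not** model transcriptome-wide covariance, batch effects, doublets beyond
the cluster flag, or non-proportional hazards, so passing recovery tests
demonstrate the pipeline's logic under its own assumptions, not performance
on real sequencing data.

## Problem sizes and numerical choices

Recovery checks use a 500-cell simulation (330 CTC-class cells); power and
null calibration use 100-patient cohorts with 200 and 100 replicates —
sizes at which the Monte-Carlo error of the reported rates is a few
percent. All randomness flows through explicit integer seeds;
`scripts/acceptance.py` derives per-stage seeds from `--seed` via
`SeedSequence.spawn`. Serialization writes floats as `%.17g` and reads with
round-trip parsing, so write→read is the identity on IEEE doubles.
Clustering is deterministic for a fixed cell order, and group naming makes
the final labels order-invariant (verified by permutation tests).

## Known limitations

* Group naming assumes the cut produces clusters whose score ordering is
  meaningful; with very few retained cells (< ~10) the k = 4 cut can split
  noise, and small-cohort group counts are unstable.
* The two published contradictions (cluster-letter conventions; the
  footnote mapping both arrow glyphs to two p levels) are resolved by
  score-ordered names and explicit two-level coding, respectively.
* The stem panel implements `ABCB2` as printed, although ABCG2 is the
  canonical stem marker — the panel is reproduced, not curated.
* Expression units are treated as TPM throughout; the published heatmap
  legend's "FPM" is taken as the same quantity on the log scale.
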
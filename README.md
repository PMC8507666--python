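# ctcpheno

Phenotyping of single circulating tumor cells (CTCs) from single-cell TPM
expression profiles, for marker-free CTC enrichment workflows in metastatic
colorectal cancer (mCRC). CTC candidates collected without epithelial or
mesenchymal capture antibodies still contain leukocytes and endothelial
cells; `ctcpheno` eliminates those from the transcriptome, classifies the
remaining CTCs along an epithelial axis and an EMT/stem axis, tests the
cross-classification for structure, and asks whether EMT-CTC burden
stratifies patient survival.

## What it computes

**QC and contaminant elimination.** Candidates need more than 100,000
uniquely mapped reads. A cell with leukocyte marker *PTPRC* ≥ 1 TPM is
eliminated as a leukocyte (as a leukocyte-mixed cluster if it is a
multi-cell cluster); a *PTPRC*-negative cell with endothelial marker
*PECAM1* ≥ 1 TPM is eliminated as endothelial.

**Marker-panel scores and grouping.** Each retained cell gets panel scores

&nbsp;&nbsp;&nbsp;&nbsp;score(cell, panel) = Σ_{g ∈ panel} log₁₀(TPM_g + 1)

over a 12-gene epithelial panel, an 11-gene cancer-stem-cell panel and a
7-gene EMT panel. Cells are clustered twice (Ward linkage, Euclidean
distance on the log scale): the 14-gene epithelial axis is cut into three
groups named Low/Middle/High by mean epithelial score, and the 18-gene
EMT/stem axis into four groups — the highest-stem cluster is
`HighStem_LowEMT`, the rest rank by EMT score into `LowStem_High/Middle/
LowEMT`. Four (epithelial, EMT/stem) pairs define Categories 1–4; other
pairs are "other".

**Contingency statistics.** The 3×4 group cross-tab is tested with Pearson's
χ² and dissected per cell with Haberman adjusted standardized residuals,
r = (O−E)/√(E(1−n_i·/n)(1−n_·j/n)), coded at |r| ≥ 1.96 and ≥ 2.58.
Patient-level detection rates (≥ 1 CTC of a type) are compared with the
exact two-sided Fisher test, computed by hypergeometric enumeration in
rational arithmetic.

**Survival.** Kaplan–Meier curves with Brookmeyer–Crowley-style median CIs
(via `lifelines`), compared between CTC-burden strata with the Gehan
generalized Wilcoxon test: U_i = #{definitely later} − #{definitely
earlier}, W = Σ_{stratum} U_i, Var(W) = n_a n_b ΣU²/(N(N−1)), with an exact
permutation p-value for small samples.

**Synthetic data.** Because the original reads are not redistributable, a
generator draws cells from eight archetypes (epithelial mid/high, EMT
full/core, stem-like cluster, leukocyte, endothelial, mixed cluster) with
log-normal on-gene expression, technical dropout and sparse background, and
cohorts with Poisson CTC counts and exponential survival whose hazard
increases with true EMT-CTC burden.

## Worked example

```sh
python analysis/01_simulate.py          # 27-patient synthetic cohort
python analysis/02_qc_filter.py
python analysis/03_phenotype.py
python analysis/04_crosstab_stats.py
python analysis/05_survival.py
```

With the default seed the drivers print (abridged):

```
simulated 92 CTC candidates across 27 patients (seed 0)
synthetic cohort: retained 43/92 candidates (47%)
reconstructed clinical fixture: 59/110 retained (54%); 109/110 above 400,000 uniquely mapped reads
annotated 43 retained cells
  epithelial groups: {'Low': 20, 'High': 14, 'Middle': 9}
[synthetic] n=43; chi-square 33.0 (df=6, p=1.05e-05); 4 categories enriched, 3 depleted
[published 59-cell table] chi-square 70.3 (p=3.5e-13); 4 enriched / 3 depleted categories
[published detection] epithelial: 30%, emt: 74%, epithelial_or_emt: 89%
survival analysis on 22 second-or-later-line patients
  emt >=1: PFS median 51d (n=12) vs 181d (n=10), Gehan p = 0.066
```

Reading: about half of the simulated candidates are contaminants and are
removed from the TPM profiles alone; the retained cells cross-classify
non-independently (four enriched categories, matching the published 59-cell
table rerun alongside); EMT CTCs are detected in far more patients than
epithelial CTCs; and in this small simulated cohort EMT-positive patients
trend toward shorter progression-free survival. The same steps are
available as a CLI (`ctcpheno simulate|classify|crosstab|survival|run-all`)
or as one call, `ctcpheno.run_pipeline(matrix, clinical, config)`.

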
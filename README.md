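# mercnet

Co-occurrence network and gradient-association analysis for soil microbiomes
sampled along mercury pollution gradients.

## The problem

Long-term mercury (Hg) pollution around historical mining areas reshapes soil
bacterial communities. A standard observational design samples paddy and
upland fields across a wide total-Hg gradient (fractions of a mg kg⁻¹ up to
tens of mg kg⁻¹), profiles the communities by 16S amplicon sequencing, and
asks three questions:

1. How do bacterial abundance (qPCR 16S copies) and diversity (Shannon *H*)
   respond to total Hg (THg) and methylmercury (MeHg)?
2. Which phyla track the gradient — e.g. do fast-growing opportunists such as
   *Firmicutes* and *Bacteroidetes* rise with THg while metal-sensitive
   nitrifiers (*Nitrospirae*) decline with MeHg?
3. Do "ecological clusters" — modules of strongly co-occurring taxa in a
   correlation network — shift their relative abundance along the gradient?

`mercnet` implements this analysis as a tested, seeded, reusable pipeline for
anyone working with an OTU/ASV count table, a taxonomy table and per-sample
metadata. Because such field datasets are rarely public, the package also
ships a synthetic-data generator that emulates the full study design
(47 sites × 3 replicates = 141 samples, planted co-occurrence modules,
taxon- and attribute-level Hg responses), so every stage of the pipeline is
verifiable end to end.

## Methods at a glance

* **Rarefaction** — every sample is subsampled without replacement (exact
  multivariate hypergeometric draw) to a common depth, 30,212 reads by
  default, before any composition or diversity analysis.
* **Shannon diversity** — H = −Σ pᵢ ln pᵢ per sample (base configurable).
* **Dominant-taxon filter** — taxa are ranked by mean relative abundance and
  the smallest prefix jointly covering ≥ 80% of the community is kept.
* **Co-occurrence network** — all pairwise Spearman rank correlations ρ
  across samples (two-sided p from the t approximation with n − 2 df); an
  edge requires ρ > 0.25 **and** p < 0.01, strictly, and only positive
  correlations are used.
* **Ecological clusters** — Louvain modularity maximisation on the unweighted
  graph (seeded, best of several restarts), modules reported in descending
  size; modules with ≥ 10 taxa are "major".
* **Module relative abundance** — per sample, the mean of the z-scored
  relative abundances of a module's member taxa.
* **Gradient associations** — OLS fits (linear or cubic in log₁₀ Hg),
  Pearson/Spearman correlation tables, one-way ANOVA with land use as the
  fixed factor, and PCA of soil covariates into three composite axes.

## Worked example

```bash
mercnet all --seed 1 --out run1
```

runs the whole pipeline in synthetic mode and prints

```
pipeline done: 141 samples, 5 major modules, Q = 0.7437
```

meaning: the generated study has 141 samples (72 paddy, 69 upland); after
rarefaction, the 80% dominance filter and correlation thresholding, Louvain
found exactly the five planted modules (modularity Q ≈ 0.74). `run1/`
contains every intermediate artifact: the rarefied table, per-sample
diversity, the edge list, module membership, the samples × modules profile,
regression/ANOVA/correlation tables, soil PCA scores, and `report.json` with
per-stage counts and seeds. The same can be done from Python:

```python
from mercnet import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1, output_dir="run1"))
report["stages"]["network"]["n_major_modules"]   # 5
```

On the synthetic defaults the association layer reproduces the expected
directions: bacterial abundance declines with log₁₀ THg in both land uses
(slope ≈ −0.5), the MeHg-positive module's profile correlates positively
with MeHg, and the *Nitrospirae* relative abundance correlates negatively
with MeHg.

Individual stages are available as `mercnet simulate`, `mercnet metrics`,
`mercnet network` and `mercnet associate`, and as plain library functions
(`rarefy`, `shannon`, `filter_dominant_taxa`, `spearman_all_pairs`,
`build_network`, `detect_modules`, `module_relative_abundance`,
`fit_gradient`, `land_use_anova`, `soil_pca`, ...).

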
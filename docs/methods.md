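# Methods

This note documents the models and numerical conventions behind `mercnet`:
what each stage computes, what the synthetic generator does and does not
emulate, and where genuinely open design choices were resolved.

## Pipeline model

The analysis treats an amplicon count table as a set of compositional
observations of a soil bacterial community along an environmental gradient
(total Hg and methylmercury, both mg kg⁻¹). Stages, in order:

1. **Rarefaction.** Each sample is subsampled to a common depth *d*
   (default 30,212 reads) without replacement, i.e. an exact multivariate
   hypergeometric draw over the sample's observed reads. Any sample below
   *d* is an error, not a silent drop: the study design assumed here has no
   under-sequenced libraries, and dropping samples would silently change
   the downstream degrees of freedom. Rarefaction is seeded and
   deterministic.
2. **Diversity.** Shannon H = −Σ pᵢ log pᵢ on the rarefied table. The
   logarithm base is configurable (`e`, `2`, `10`); natural log is the
   default. H is reported per sample together with depth and observed
   richness.
3. **Dominant-taxon filter.** Taxa are ranked by mean relative abundance
   over all samples (descending, ties broken lexicographically by taxon ID)
   and the shortest prefix whose cumulative mean abundance reaches the
   coverage target (default 0.80) is retained. Ranking by mean relative
   abundance rather than total reads makes the filter invariant to library
   size; after rarefaction the two are equivalent anyway.
4. **Correlation network.** All pairwise Spearman ρ between retained taxa
   across samples, average ranks for ties, two-sided p from the t
   approximation with n − 2 df. Zero-variance taxa get ρ = 0, p = 1. An
   edge requires ρ > 0.25 and p < 0.01 — both strict, so boundary values
   are excluded — and only positive correlations qualify: negative Spearman
   correlations in compositional data mix genuine exclusion with
   closure-induced dependence and are not interpreted. No multiple-testing
   correction is applied by default (the edge rule uses raw P); a
   Benjamini–Hochberg option exists. Isolated taxa are dropped from the
   network.
5. **Modules.** Louvain modularity maximisation on the unweighted,
   undirected graph at resolution 1.0. Louvain is a greedy stochastic
   heuristic, so the optimiser runs `n_restarts` times (default 8) from
   child seeds derived deterministically from the stage seed, and the
   partition with the highest modularity Q is kept; on small graphs this
   reliably reaches the global optimum (verified against exhaustive
   partition enumeration in the test suite). Modules are re-indexed by
   descending size (ties by smallest member ID); modules with ≥ 10 taxa are
   flagged "major". Edge-weighted detection and other resolutions are
   exposed as options.
6. **Module relative abundance.** Each member taxon's relative abundance is
   z-scored across the full sample set (population SD; zero-variance taxa
   contribute 0) and a module's per-sample value is the unweighted mean of
   its members' z-scores. Every module column therefore has mean 0 over the
   sample set; values are comparable across modules of different sizes.
7. **Gradient associations.** OLS of attributes on the Hg predictors,
   linear or cubic. Hg predictors are log₁₀-transformed by default: the
   gradient spans two orders of magnitude and toxicity scales
   multiplicatively; the flag can be switched off, and all degrees of
   freedom are transform-invariant. Cubic fits use a centred predictor for
   conditioning — F, p and R² are identical to the raw-power
   parameterisation. One-way ANOVA uses land use as the fixed factor at the
   sample level; site nesting is deliberately ignored so that 141 samples
   in two groups give d.f. = 1, 139 (a pseudo-replicated but conventional
   reporting choice for this design). Pearson/Spearman correlation tables
   report raw two-sided p. Soil covariates (pH, SOC, TC, TN, C:N, DOC,
   NH₄⁺, NO₃⁻) are standardised and compressed by PCA to three composite
   axes for use as predictors in external models (SEM, random forests);
   constant variables are dropped with a warning and missing values are
   mean-imputed with a logged warning.

## Synthetic-data generator

The generator emulates the study design at the abundance-table level — it
does not simulate sequencing error, chimeras or OTU clustering.

**Design.** 24 paddy + 23 upland sites × 3 replicates = 141 samples.
Site-level total Hg is log-uniform on [0.27, 52.4] mg kg⁻¹ (a multiplicative
pollution gradient); replicates jitter around the site value with 10% CV,
clipped back to the range. MeHg = 0.01·THg^0.7·exp(ε), ε ~ N(0, 0.3²),
emitted in mg kg⁻¹ — the source literature for such designs rarely reports
MeHg ranges, so these coefficients are explicit placeholders and fully
configurable. Soil covariates come from land-use-specific normal/lognormal
distributions with realistic paddy–upland contrasts (higher pH, SOC, TN,
DOC and NH₄⁺ in paddy; higher NO₃⁻ in upland).

**Attributes.** The qPCR-like abundance is
log₁₀(16S copies g⁻¹) = 10.5 − 0.5·log₁₀ THg + 0.2·[paddy] + N(0, 0.3²);
the −0.5 slope is the recoverable ground truth for the regression layer.
Evenness (and hence Shannon H) rises mildly with THg: the static baseline
log-abundances are scaled by exp(−0.15·z(log THg)), flattening the
community at the polluted end.

**Community.** A latent-factor model. Each of the 5 planted modules has a
per-sample factor
F_m = a_m·z(log THg) + b_m·z(log MeHg) + N(0, 1); a member taxon's
log-abundance is baseline + 0.9·F_m + N(0, 0.3²). Default slopes (a, b):
module 0 (0, −0.3), module 1 (0.15, 0.15), module 2 (−0.3, 0),
module 3 (0.3, 0), module 4 (0, 0.3). Because MeHg is a power law of THg,
the two standardised predictors are nearly collinear (r ≈ 0.96); slope
magnitudes are kept well below the unit innovation variance so that
between-module factor covariance stays small and the planted partition is
identifiable by the thresholded network — with larger slopes,
environmentally aligned modules genuinely merge into single co-responding
blocks, which is a property of the method worth knowing, but it would make
"recover the five planted modules" an ill-posed benchmark.

Phylum labels are module-aware: the module rising most strongly with MeHg
draws from an Hg-tolerant pool (Proteobacteria, Bacteroidetes,
Actinobacteria, Firmicutes), the module declining most strongly with MeHg
carries the Nitrospirae, and the rest draw from neutral soil phyla. Each
gradient-responsive phylum is confined to a single module's pool and its
presence is guaranteed, not left to sampling: a phylum-wide slope spread
over several modules would add cross-module covariance and blur the planted
partition. Phylum slopes (on z-scored log THg, log MeHg): Firmicutes and
Bacteroidetes (+0.4, 0), Nitrospirae (0, −0.4), added on top of the module
factor.

Per-sample relative abundances are the softmax of the log-abundances (the
data are compositional by construction) and integer counts are a
multinomial draw at a library size drawn uniformly in
[depth_mean, 1.3·depth_mean], so every sample can be rarefied to any depth
up to depth_mean.

**Determinism.** One design seed fans out to independent per-stage streams
(metadata, community) via spawned seed sequences; identical seeds give
byte-identical tables. The pipeline derives child seeds the same way for
rarefaction and module detection.

**What passing tests show — and don't.** The generator produces clean,
factor-structured modules, a single dominant environmental axis and
well-behaved noise. Success on it demonstrates that the implementation of
each stage is correct and that the pipeline recovers structure of the kind
the analysis presumes; it does not demonstrate that real soil communities
have such structure, nor does it protect against the known failure modes of
correlation networks on compositional data (closure-induced dependence,
unobserved confounders, detection limits at low abundance).

## Problem sizes

Tests and the acceptance script run the generator at 300 taxa. The test
suite uses a 2,000-read rarefaction depth ("test mode") across a 50-seed
sweep; the acceptance script runs one full-scale replicate per seed at the
default 30,212-read depth. Both scales recover the planted structure; the
reduced scale simply keeps the multi-seed sweeps quick.

## Known limitations

* Spearman + threshold is not a compositionality-aware inference method
  (no SparCC/SPIEC-EASI equivalent is provided, by design).
* The ANOVA treats replicates as independent samples; a mixed model with
  site as a random effect would be the defensible alternative when the
  question is site-level.
* BIOM support covers the 1.0 JSON dialect only (sparse or dense); HDF5
  BIOM files must be converted externally.
* Structural equation modeling and random-forest importance analyses are
  out of scope; the pipeline emits their inputs (module profiles, PCA
  composites) for external tools.
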
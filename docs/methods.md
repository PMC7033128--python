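# Methods

This note documents the statistical procedures, the synthetic data model,
the defaults and the numerical choices of `neurostage`, in the order the
pipeline runs them.

## Cohort data model

A cohort is a genes × samples matrix of expression values (counts and a
TPM-like per-sample rescaling to 10⁶) plus sample metadata with
`condition ∈ {tumor, control}` and a stage label from the fixed six-label
vocabulary `T1N0, T2N0, T3N0, N1, N2, N3` (primary tumor size without nodal
spread, then increasing lymph-node involvement). All analyses are stage-wise:
each stage's tumor samples are compared against controls (pooled across
stages by default, because tumor cohorts typically carry few stage-matched
controls; `pool_controls=False` restricts to the stage's own controls).

## Synthetic cohort generator

The generator (`simulate.simulate_cohort`) produces cohorts carrying exactly
the signals the analysis chain looks for, with the planted truth returned
alongside:

* **Counts**: negative binomial with a single shared dispersion
  (default `nb_dispersion = 0.05`, variance = μ + 0.05 μ², a typical bulk
  RNA-seq value) around gene-level baseline means drawn log-normally
  (natural-log mean 3.5, sd 1.0 — median ≈ 33 counts).
* **Differential expression**: a fraction `de_fraction` (default 0.1) of
  genes gets `+de_log2fc·ln 2` (default log₂FC = 2, i.e. 4-fold) on the
  tumor log-mean. Inducer-block members are planted up-regulated first, so
  they enter the downstream candidate pool the way real drivers would.
* **Co-expression blocks**: per-sample latent factors `N(0, factor_sd)`
  added (times a loading) to member genes' log-means, creating correlated
  blocks.
* **Inducer maps**: each block specifies non-neural member genes, neural
  responder genes, a coefficient matrix `C` and a noise sd. Responder values
  are `expm1(log1p(X_inducers) @ C + ε)` — a deterministic continuous
  function of the realized inducer counts, not re-drawn from the count model
  and not rounded. This makes coefficient recovery by OLS exact in the
  noiseless limit, which pins down the generator's correctness; the cost is
  that the counts matrix is float-valued (all non-responder entries remain
  integral). Linearity on the log1p scale matches the scale on which the
  downstream regression effectively operates.
* **Reproducibility**: one global seed spawns one child RNG stream per stage
  plus one for gene-level parameters, so any stage subset regenerates
  bit-identically.

What the generator does **not** emulate: read-level noise, batch effects,
tumor purity, gene-length variation (TPM assumes unit length), or
between-gene dispersion differences. Passing tests therefore demonstrate the
correctness and calibration of the machinery under a clean NB + latent-factor
model, not robustness to real-data artifacts.

The fixture writer also emits a GMT pathway catalogue in which each planted
block is a dedicated pathway named with a category keyword (e.g. "synapse
formation block 0"), plus filler pathways chunking the remaining genes, so
catalogue, enrichment and category binning are all exercised on synthetic
data.

## Catalogue and category schemes

A gene is *neural* if it belongs to at least one pathway whose name or
description matches a neural keyword (classification by inclusion: dual
annotation ⇒ neural). Pathways are binned into reporting categories by an
ordered, first-match-wins keyword rule table shipped as editable YAML
(`data/category_rules.yaml`); pathways with no hit are "unclassified". Five
schemes are shipped: the eight neural function categories, the four
neural-development groups (ordered early → late), two non-neural category
sets, and the two-way super-classification into **cell-environment
interaction** (cytokine/chemokine production, cell adhesion, calcium
sequestering, hemopoiesis, ECM synthesis) vs **intracellular damage
processing** (cell skeleton synthesis, DNA damage and metabolism, organelle
assembly). Keyword binning is a transparent stand-in for a curation step
that, in any real deployment, would be reviewed by hand; the rules file is
config, not code.

## Differential expression

Counts are normalized by median-of-ratios size factors (geometric-mean
reference over genes nonzero in every sample; log-scale median). The
per-gene test is Welch's t on log1p(normalized counts); fold change is the
ratio of normalized group means with a pseudocount of 1. A gene is
up-regulated at fold change > 2.0 and p < 0.05 (raw p; a Benjamini-Hochberg
switch exists, off by default). This deliberately replaces a full NB
GLM/shrinkage engine: the fold-change/p thresholds, not the test engine, are
the analysis' operative criterion, and the function boundary allows an NB
Wald test to be swapped in. Note the pseudocount makes calls only
asymptotically invariant to rescaling one sample (the shared geometric-mean
reference shifts by c^(1/m)); calls are stable in practice and the test
suite asserts exactly that.

## Co-expression and the NCN/NNCN sets

Correlations are computed on TPM within one stage's tumor samples, Spearman
by default with average-rank ties, cutoff |ρ| ≥ 0.8 and p < 0.05 from the
t approximation. Both the coefficient (spearman/pearson) and whether the
cutoff applies to ρ or ρ² are config options, because published threshold
conventions are not consistent on this point; defaults are spearman and |ρ|.
Constant gene vectors have undefined coefficients: their pairs are skipped
and logged.

* **NCN**: neural genes correlated (either sign) with ≥ 1 up-regulated
  non-neural gene.
* **NNCN**: up-regulated non-neural genes *positively* correlated with ≥ 1
  expressed neural gene, where "expressed" means nonzero TPM in ≥ 50% of the
  stage's tumor samples (the threshold is a package decision; no standard
  definition exists).

Heat-map export orders rows (neural genes) and columns (non-neural genes) by
category in a fixed palette order and zeroes cells failing the filter.

## Enrichment

One-sided hypergeometric over-representation per pathway against the
annotated background of the relevant gene class, enriched at p < 0.05 (raw;
BH switch available). The pathway universe is a flat GMT, so no GO-graph
decorrelation is attempted. Stage × category count tables report distinct
enriched pathways per category per stage plus a distinct-union total across
stages (a pathway enriched at several stages counts once).

## Explainability regression

Inputs are min-max-normalized expression values in [0, 1] per gene
(constant/unexpressed genes removed before scaling). The solver is ridge in
closed form, `B = (XᵀX + λI)⁻¹XᵀY` on column-centered X and Y (equivalent to
an unpenalized intercept); the penalized objective squares the coefficients,
so ridge — not an L1 path — is the exact solution. Specifics:

* **Pooled R²** `1 − ‖Y − XB‖²_F / ‖Y − Ȳ‖²_F` across the k responses,
  matching the Frobenius objective; adjusted R² uses effective degrees of
  freedom = trace of the ridge hat matrix + 1 (intercept). A response matrix
  with (near-)zero total variance is flagged degenerate with R² = 0 rather
  than dividing by ~0.
* **λ selection**: generalized cross-validation `m·RSS/(m − edf)²` over a
  13-point log grid (10⁻⁴…10²), chosen once before the elimination loop and
  held fixed within it — refitting λ per round would make the minimality
  semantics unstable. λ = 0 with collinear X raises an error advising λ > 0.
* **Coefficient p-values** (pruning only): per response, t statistics from
  the ridge sandwich covariance σ²(XᵀX+λI)⁻¹XᵀX(XᵀX+λI)⁻¹ with
  df = m − edf; per candidate the minimum p across the k responses with a
  Bonferroni factor k. Conservative and cheap, which is all the pruning
  ordering needs.
* **Backward elimination**: drop all candidates with p ≥ `alpha_drop`,
  refit, stop when nothing drops. The default `alpha_drop = 0.01` is
  stricter than the 0.05 used for the marginal gates because the candidate
  pool is large (tens to hundreds of genes): at 0.05 roughly one spurious
  driver per twenty candidates survives each round, which measurably
  degrades the precision of the recovered inducer edges; 0.01 matches the
  significance level of the contribution calls. The set strictly shrinks
  each non-terminal round, so termination within n_init rounds is
  guaranteed; eliminating everything returns an empty-selection fit with
  R² = 0.
* **Explainability call**: explainable ⇔ pooled R² ≥ 2/3 ∧ permutation
  p < 0.05 ∧ selection minimal. The gate is applied to the plain R² (the
  adjusted version is reported alongside); which of the two a study gates on
  is a config choice.
* **Minimality**: a selection is minimal when no proper subset reaches the
  R² gate with an *unpenalized* (lstsq) fit — at λ = 0, R² is monotone in
  nested sets, which grounds the check. Exhaustive enumeration up to 12
  selected candidates (≤ 4094 subsets); above that a greedy leave-one-out
  descent that recurses on the best passing subset. Greedy can miss
  non-nested passing subsets; the test suite measures its agreement with
  the exhaustive oracle (≥ 95/100 random instances).
* **Permutation p**: rows of Y permuted relative to X (the standard scheme
  preserving X's correlation structure), statistic = adjusted R² of a fresh
  fit, `p = (1 + #{perm ≥ observed}) / (1 + n_perm)`. Permutations are
  batched through a precomputed projector, so 10⁴ permutations are cheap;
  the desk-scale default is n_perm = 1000 (tests and the acceptance script
  use 150–500 to keep runtimes in seconds; the statistic comparison uses a
  1e-12 slack toward conservatism). m < 4 is rejected.
* **ΔR² attribution**: for predictor blocks partitioning X, the drop in R²
  when the focal block is removed at the same λ; significance by permuting
  the focal block's rows only (n_perm = 199 default → minimum p = 0.005,
  resolvable against the 0.01 gate); contributing ⇔ ΔR² > 0.01 ∧ p < 0.01.
  For orthogonal centered blocks at λ = 0 the deltas sum exactly to the
  full-model R², which the suite asserts.
* **Class fractions**: per stage, the share of selected non-neural pathways
  in each super-class; pathways in neither class stay in the denominator
  only, so the two fractions sum to ≤ 1. Stages with nothing selected emit
  NaN with a warning.

The pipeline runs one regression per neural function category (responses =
the stage's NCN genes of that category; candidates = all up-regulated
non-neural genes), which keeps "explainable neural functions" well defined
and prevents cross-talk between unrelated responder blocks. Pathway-level
granularity (averaging member genes into pathway scores) is available via
`pathway_scores`.

## Problem sizes and test design

The suite and the acceptance script run everything on freshly simulated
data: cohorts of 20–60 tumor samples per stage and 60–200 genes, 100-instance
oracle sweeps, 200-dataset calibration runs at 500 permutations, and 40-rep
attribution studies. These sizes give stable verdicts (binomial noise well
inside the asserted bounds) while keeping the full suite under ten seconds.
Where a stochastic bound is asserted (e.g. recovery ≥ 0.9, calibration in
[0.02, 0.09]) the replicate counts follow the stated study conditions. The
planted co-expression blocks in the recovery fixtures use factor sd 1.5;
with NB count noise at typical expression levels this guarantees
within-block correlations above the 0.8 screening threshold, so the planted
truth actually satisfies the property being recovered (at sd 1.0,
low-expression members can fall below the threshold — a property of count
noise, not of the estimator).

## Known limitations

* The DE engine is a t-test stand-in behind the thresholds, not an NB GLM;
  very low counts or extreme dispersion heterogeneity are outside its
  comfort zone.
* Enrichment ignores pathway overlap/DAG structure; strongly nested gene
  sets will co-enrich.
* The explainability calls are in-sample: R² is not cross-validated, and
  "statistical explainability" is a directional association statement, not a
  causal claim.
* Greedy minimality above 12 candidates is heuristic (agreement with the
  exhaustive oracle is measured, not guaranteed).
* Keyword category binning is as good as its rule file; unusual pathway
  nomenclature lands in "unclassified".
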
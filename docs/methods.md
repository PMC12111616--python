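# Methods

This note records the models, parameter choices and numerical
conventions behind `metabnet`, and what the synthetic-cohort tests do
and do not demonstrate about real data.

## The synthetic cohort

The generator is a log-normal intensity model with additive structure
on the log scale.  For biological sample *i* and metabolite *j*,

    log x_ij = mu_j + beta_{c(j),g(i)} * s_j + sigma * (lambda_j' z_i) + drift_j(t_i) + eps_ij

where `mu_j ~ N(11.5, 1)` is the feature baseline, `beta` is the
class-by-group effect expressed in units of the within-group SD
`s_j = sigma * sqrt(1 + ||lambda_j||^2)`, `z_i` are latent factor
scores, `eps_ij ~ N(0, sigma^2)` with `sigma = 0.4` by default, and
`drift_j` is a per-feature monotone-plus-sinusoid trend in absolute
injection position with amplitude `0.3 * sigma` (log scale).  Pooled-QC
injections carry the feature's cohort-pooled mean, the same drift, and
a small replicate noise (`0.05` log units), so their %CV is far below
the biological spread — as pooled QCs behave on instrument.

Default conditions reproduce the study design: 27 HC / 23 RA / 22 SLE
women; LC and GC runs sharing one randomized biological sequence; QC
schedules of 10-then-every-8 (LC) and 6-then-every-5 (GC); 431
metabolites in six chemical classes; phospholipid and sphingolipid
classes decreased one SD in both diseases, glycerolipids increased one
SD, fatty acids decreased half an SD, cyclic compounds null.
Missingness is deterministic left-censoring below each feature's 5 %
quantile, exercising both the presence filter and half-minimum
imputation.  Cytokines are log-normal with one-SD-scale elevations per
disease panel (the RA panel includes IL-2; the SLE panel MCP-1 and
IL-10), and clinical covariates (HDL, LDL, total cholesterol,
triglycerides, ESR, blood counts, disease duration, activity score)
are drawn with qualitative group shifts — medians ordered like a real
clinical table, not calibrated to any cohort's numbers.

### Latent factors and the planted network truth

Latent factors give the correlation networks a ground truth: one hub
cytokine (GM-CSF) loads strongly (4.0) on two factors, each of which
also loads moderately (1.5) on six fatty acids; a third factor ties
three ether-phospholipids to HDL (loadings 0.8 / 1.0).  Two design
choices matter here:

* **Two sub-families, moderate spoke loadings.**  If the hub's
  partners all share one factor, the spokes are as correlated with
  each other as with the hub and tie its degree.  With two bridged
  sub-families the hub keeps twice as many strong partners as any
  spoke.  Spoke loadings are kept moderate so that a chance empirical
  correlation between the two factors decays quadratically in the
  spokes and cannot flood the network with cross-family edges.
* **Within-group whitening.**  Factor scores are whitened inside each
  study group (empirical factor covariance pinned to the identity).
  In a 23-sample disease group two raw Gaussian factor columns have a
  chance correlation with SD ≈ 0.21; draws with |r| > 0.3 corrupt the
  planted truth itself — the hub's edges weaken while spurious
  cross-factor edges appear.  Whitening makes the planted structure a
  property of the sampled cohort, not only of the population model.

The generator also provides a closed-form oracle: under equal
covariance across groups (no drift, no censoring), the optimal linear
score for a feature set with mean difference `delta` and covariance
`Sigma` has AUC `Phi(sqrt(delta' Sigma^-1 delta / 2))`.  Configurations
with drift or censoring are refused rather than approximated.

### What passing tests do and do not show

The generator emulates the statistical skeleton of an untargeted
metabolomics study: log-normal intensities, QC-anchored drift,
left-censoring, class-coherent effects, chemically structured SMILES.
It does not emulate peak detection and integration error, retention-
time misalignment, adducts/isotopes, batch discontinuities, missing-
not-at-low-intensity patterns, or covariate confounding (age, BMI,
medication).  Recovery results therefore demonstrate that the pipeline
is correctly implemented and calibrated under its assumed data model —
not that the workflow has a given power on any real cohort.

## Preprocessing

SERRF-style normalization fits, per feature, a random forest
(default 500 trees, `min_samples_leaf = 1`) on that run's QC
injections with predictors = injection position + the 10 features most
QC-correlated with the target, and subtracts the predicted systematic
component on the log scale, re-anchored at the QC median.  The target
is centered before fitting so tree construction depends on it only
through differences; this keeps the correction exactly equivariant
under rescaling of a feature (sklearn's split criterion is otherwise
sensitive to a constant shift at float precision).  Runs with fewer
than five usable QCs fall back to LOESS on injection position
(span 0.75); constant or all-missing features pass through with a
warning.

Filter conventions: presence is computed on biological samples only
(the QC pool is not a study group) and a feature is kept if any single
group reaches the threshold; %CV boundary values pass (the exclusion
rule is "greater than"); the presence and %CV filters are independent
per-feature predicates, so their composition is order-independent.
Normalization runs before filtering because the QC-based correction
needs the raw drifted values.  Remaining missing values are imputed
with half the per-feature minimum — the standard surrogate for
left-censored MS intensities.

A note on evaluating drift removal: with the study's own QC counts
(19–20 per run) the null SD of a Spearman correlation is ≈ 0.24, so
even perfectly drift-free QC residuals exceed |rho| = 0.2 about 40 %
of the time.  The decorrelation property is therefore asserted on a
longer simulated run (600 biological samples, 85 LC QCs), where the
statistic has power; at study scale the suite asserts the strict
reduction in median QC %CV instead.

## Differential analysis

Pareto scaling divides the centered log values by the square root of
the SD — the scaled variance equals the log-scale SD, a compromise
between unit variance and no scaling.  OPLS-DA is fitted by NIPALS:
orthogonal components are deflated sequentially
(`w_o ∝ p − (w'p)w`), then a single predictive component is taken from
the deflated matrix; with zero orthogonal components the model is
exactly PLS1.  One orthogonal component is the default for a two-class
model.  VIP is computed on the predictive component, giving the
identity mean(VIP²) = 1; predictive and orthogonal scores are
orthogonal to machine precision.  A K-fold cross-validated Q² is
provided for permutation checks (shuffled labels give Q² ≤ 0).

Univariate testing uses the two-sided Mann–Whitney test (tie-corrected,
exact for small untied samples) with Benjamini–Hochberg FDR across the
comparison's features; fold change is the ratio of raw-scale group
medians, robust to the log-transform choice.  The default selection
rule is VIP > 1 and q < 0.05, both strict; a raw-p switch exists
because the two conventions (raw p at selection, FDR at network entry)
both appear in practice.  A power note: with effects on only ~10 % of
features at n = 23 vs 27, the BH threshold is so strict that no
variant of the rule can reach 60 % sensitivity while holding the
false-discovery proportion at 10 % — the package's calibration tests
therefore evaluate recovery under the default study conditions, where
most lipid classes carry effects and the BH threshold is
correspondingly milder.

## Chemical mapping

Fingerprints are 1024-bit hashed path-based bit vectors; chemical
distance is 1 − Tanimoto.  Ward linkage is applied to the distance
matrix and K maximizes the mean silhouette width over K = 2…10 (ties
break to the smaller K).  On the synthetic six-series panel the
silhouette can prefer a finer K than six because homologous series are
internally very tight; the partition still matches the true classes
(ARI ≥ 0.95).  Modules are obtained by recursive branch cutting within
each cluster (a branch splits while both children hold ≥ `min_size`
leaves, default 3; undersized side-branches join the nearest module by
average distance), so modules always refine clusters and partition the
metabolite set.

WMCSA is realized as the sign-oriented first principal component of
the standardized member log-abundances per module — the module-
eigenvector construction: it is the single profile explaining the most
member variance, oriented to correlate positively with the member
mean, and standardized to zero mean / unit variance.  Group
comparisons use Kruskal–Wallis plus Dunn's z tests with Bonferroni
correction over the three pairwise comparisons.

## Correlation networks

Edges are significant Spearman correlations (default raw p < 0.05; the
exact permutation p is used for n ≤ 9, the t-approximation above) among
the panel variables within one disease group; the sign is an edge
attribute.  The metric is d = 1 − |rho| by default — strong
correlations of either sign indicate proximity — with a signed
(1 − rho) switch.  Non-significant pairs have no edge (infinite
distance) before Floyd–Warshall completion; for the 2-D embedding,
still-disconnected pairs are set to 1.5 × the largest finite geodesic.
Classical (Torgerson) MDS embeds the geodesic matrix
(double-centering + eigendecomposition), deterministic up to
rotation/reflection; Kruskal stress-1 is reported.  Negative
eigenvalues — expected, since a geodesic matrix need not be Euclidean —
are clipped to zero.

## Biomarkers

The combined score is a plain binomial GLM on log intensities, fitted
by IRLS (Newton–Raphson); quasi-separation is detected (|linear
predictor| > 30 or a singular step), flagged, and iteration stops with
probabilities clipped into the open interval — the score still ranks
samples, so the ROC is well defined, and no Firth correction is
applied.  The reported AUC is apparent (in-sample), matching how such
panels are usually reported at this cohort size; a cross-validated
variant is available but off by default.  The ROC sweep uses unique
thresholds with tie-halving, making the trapezoidal area equal to the
Mann–Whitney identity to machine precision.

## Cohort statistics

The Freeman–Halton extension of Fisher's exact test enumerates all
r × c tables with the observed margins (feasible for r, c ≤ 3 at
cohort-scale counts) and sums the probabilities of tables no more
probable than the observed one (relative tolerance 1e-7 for float
ties) — the convention of mainstream statistical software.  Dunn's
test uses mean-rank differences with the usual tie correction and
optional Bonferroni adjustment.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at reduced panel sizes (10–60 features)
and 20–200 replicates, with SERRF forests of 50–100 trees — choices
made so the whole suite completes in well under a minute per module
while the monitored statistics keep useful sampling precision; full
431-feature runs back the worked example and the clustering checks.
All randomness flows from explicit integer seeds; reruns are
byte-identical.
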
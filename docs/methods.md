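# Methods

## The model

micromet predicts a community metabolome from a community sequence-feature
profile (taxa, OTUs, or gene families). Given paired training tables — a
feature table **X** and a metabolite table **Y** over the same samples, both
as relative abundances — it fits one penalized linear model per metabolite:

    y_t = b0 + Z b + e,

where `Z` is the rank-based inverse-normal (rank-INT) transform of the
filtered feature table (per feature, across samples), `y_t` is the
arcsine-square-root transform of the metabolite's relative abundance, and
`b` is estimated by the elastic net,

    min over (b0, b):  (1/2n) * RSS  +  lambda * ( alpha*||s.b||_1
                                                 + (1-alpha)/2 * ||s.b||_2^2 ),

with `s` the per-feature standard deviations (predictors are standardized
for the penalty; coefficients are reported on the input scale, the
convention of the standard coordinate-descent solvers). The L1 fraction
`alpha` and the overall penalty `lambda` are chosen per metabolite by
cross-validated mean squared error; the model is then refit on all samples
at the chosen pair. Predictions for new samples run the same transforms
within the new cohort, apply the stored weights, and map back through
`sin^2(clamp(t, 0, pi/2))`, so predicted metabolite abundances always lie in
[0, 1].

Model quality is summarized per metabolite as the Spearman correlation
between the pooled out-of-fold predictions and the observed transformed
values; metabolites at or above 0.3 are flagged *well predicted* and only
those count as usable models downstream.

### Assumptions

- Each metabolite is modelled independently; no multivariate shrinkage.
- The feature-metabolite relationship is monotone enough that a linear
  model on rank-INT features captures it (the rank transform absorbs
  skewness, heavy tails, and mean-variance dependence typical of
  meta'omic profiles).
- The rank transform is cohort-relative: feature ranks are recomputed
  within whatever cohort is being transformed. Consequently a single
  sample cannot be predicted in isolation (minimum cohort size 2), and a
  new cohort's predictions depend mildly on its own composition.
- Relative abundances, not absolute concentrations or fluxes, on both
  sides.

## Filtering and transforms

- Total-sum scaling normalizes every sample row to 1; all-zero rows are
  an error.
- The quality filter keeps features whose relative abundance exceeds
  `min_abundance` (default 1e-4, i.e. 0.01%) in at least
  `ceil(min_prevalence * n)` samples (default 10%); the comparison is
  strict (>) on abundance and inclusive (>=) on the sample count. Rows are
  deliberately *not* renormalized after filtering so predictions stay on
  the original relative-abundance scale. A variance filter
  (`min_variance`, default 0 = drop only constant features) supports
  low-biomass 16S data sets, for which a lower abundance cut (1e-6) and
  leave-one-out CV are the recommended settings.
- rank-INT: `z_i = Phi^-1((r_i - 0.5)/n)` with average ranks for ties.
  Constant feature columns cannot be transformed; the trainer always drops
  them, while prediction maps constant (including zero-filled missing)
  columns to 0, the center of the transform's range — a missing feature
  contributes the baseline rather than crashing prediction.
- Arcsine-sqrt forward/backward are exact inverses on [0, 1] to 1e-12;
  the backward clamp guarantees valid proportions for any linear
  predictor.

## Hyperparameter search

- `alpha` grid: {0.1, 0.2, ..., 1.0}. A finer grid changes nothing
  measurable on data of this kind while doubling CV cost; alpha below 0.1
  approaches ridge and defeats the purpose of a sparse, interpretable
  model.
- `lambda` path: 100 values, geometric from `lambda_max` (the smallest
  lambda that zeroes all coefficients) down to `1e-3 * lambda_max` when
  n > p, else `1e-2 * lambda_max`.
- Selection at the CV-MSE minimum (for Gaussian errors, maximizing
  cross-validated likelihood is the same ordering); the one-standard-error
  rule is a known alternative and deliberately not used.
- Fold assignment is seeded and shared across metabolites within a run,
  so per-metabolite scores are comparable; 10-fold by default, LOOCV
  available.
- Coordinate-descent tolerance is 5e-4 during the grid search and 1e-4
  for standalone fits; `fit_elastic_net` accepts tighter tolerances when
  objective-level precision is needed. These choices do not change which
  (alpha, lambda) pair is selected at the problem sizes the tool targets.

## Permutation null

Shuffled-data significance breaks all feature-metabolite linkage by
independently permuting each feature column across samples in both tables
and renormalizing each row afterwards, preserving per-feature value
multisets and compositional structure. The whole training pipeline is rerun
per iteration; the fraction of metabolites still flagged well predicted
estimates the false-flag rate of the 0.3 threshold, and McNemar's exact
test (binomial on discordant pairs) compares the true flags with a permuted
run's flags. A `sample-label` mode that permutes whole rows (preserving
within-sample structure) is available. The default iteration count is 20 —
a runtime choice, not a statistical one; 1000 reproduces the conventional
deep null.

A caveat worth knowing: when every coefficient is zeroed, out-of-fold
predictions collapse to fold means, so the pooled Spearman has roughly as
many effective observations as there are folds. At small n (< ~40) the
null distribution of the score is wide and the 0.3 threshold false-flags
more often; cohorts of 50+ samples behave as intended.

## RTSI (Representative Training Sample Index)

RTSI asks whether a new sample lies in the region of feature space the
training set covers. The training features (normalized, filtered,
rank-INT) are decomposed by PCA; the number of components K carrying real
structure is chosen by testing the leading covariance eigenvalues against
the Tracy-Widom (TW1) largest-eigenvalue null with the effective-dimension
normalization used in population-genetics eigenanalysis: for the i-th
eigenvalue the larger ones are stripped, the effective variable count n'
and noise scale are estimated from the remaining bulk, and
`(l - mu(n', m)) / sigma(n', m)` is compared with the TW1 critical value
(0.9793 at significance 0.05, from the published quantile table; the
in-repo Monte-Carlo test confirms ~2-5% null rejection).

One numerical choice matters here: the bulk used to estimate (n', scale)
excludes eigenvalues larger than 5x the median of the remaining spectrum.
Under a pure noise spectrum the trim never triggers (the Marchenko-Pastur
upper edge is well below 5x the median at these aspect ratios), so null
calibration is untouched; with several strong signal eigenvalues present it
prevents the not-yet-tested ones from inflating the scale estimate and
masking the one under test. Without the trim, three strong planted factors
are invisible to the test; with it they are recovered in ~98% of
simulations.

Each new sample's transformed shared-feature vector is then correlated
(Pearson) with each of the K loading vectors; RTSI is the maximum absolute
correlation (loading sign is arbitrary). A `mean` aggregate is available.
Features of the new cohort unseen in training are flagged and excluded from
the score; per-sample feature overlap is reported separately. If K = 0 the
score is undefined and reported as NaN with a warning. Whether to correlate
with loadings or with projected scores is an open representational choice;
loadings (feature-space axes) are used and documented here.

## Enrichment

Features are ranked by usage: the number of well-predicted models in which
the feature's coefficient is nonzero (descending, lexicographic
tie-break; all surviving predictor features are ranked, usage 0 allowed).
Each gene set is scored by the classic unweighted KS running sum (+1/|S|
at members, -1/(N-|S|) elsewhere; the enrichment score is the extreme
deviation, signed). Significance comes from random placements of the set
within the fixed ranking, p = (1 + hits) / (n_permutations + 1) (100,000
permutations by default), two-sided on |ES|. One-tailed Fisher tests
over-representation of set members among the candidate (ever-used)
features. Both p-value families get Benjamini-Hochberg correction;
Q < 0.25 is the conventional reporting threshold for the KS test. The
permutation p is valid but mildly conservative in mid-range because the
discrete null has ties.

## Synthetic data

The generator produces paired tables with known ground truth so every
claim above is testable without external data.

Features: per-feature log-normal abundances (location spread 1.5,
log-scale sd 1.0), per-feature prevalence uniform on
[1 - 2*zero_fraction, 1] (expected zero fraction 0.3 by default), and
three latent community gradients (factor loadings with sd 0.7 on the log
scale) that induce the correlated population structure real communities
show — this structure is what PCA/RTSI keys on, and it also makes support
recovery honestly harder than an independent-feature toy. Rows are
normalized to sum to 1.

Metabolites: for each planted metabolite, a sparse weight vector
(support 8, mixed signs, magnitudes uniform) acts on the rank-INT features;
the signal is scaled to sd 0.1 on the arcsine-sqrt scale, baselines sit at
`asin(sqrt(0.5/m))` (half the compositional budget), and Gaussian noise of
sd `noise_sd` (default 0.05) is added before back-transforming. A remainder
column (`M_REST`) absorbs the unassigned compositional mass — the analogue
of the unannotated bulk of real metabolomes — so every modelled
metabolite's relative abundance is exactly `sin^2` of its planted index and
rows still sum to 1. About 10% of planted responses hit the composition
floor (the back-transform clamps them to 0, i.e. the metabolite reads as
absent), which is both realistic and the main reason noiseless
cross-validated scores are high but not perfect: measured on the default
design, the noiseless per-metabolite CV Spearman has median ~0.9, with ~95%
of planted metabolites above the 0.3 threshold and planted-support sign
recovery of ~0.93 averaged over seeds. Noise metabolites vary independently
of X with sd equal to the signal scale. A `raw` signal mode plants the map
on untransformed abundances to probe robustness to transform
misspecification.

Validation cohorts are drawn from the same generative model with a drift
parameter interpolating every feature-model parameter (log-means,
prevalences, factor loadings) toward a freshly drawn configuration:
drift 0 reproduces the training distribution, drift 1 is an unrelated
community type. The same planted map produces held-out true metabolite
tables, enabling representativeness-versus-accuracy experiments.

What passing tests on this generator do **not** show about real data: no
phylogenetic correlation structure, no measurement artefacts
(batch effects, LC-MS peak-calling noise, compositional zeros from
sequencing depth), additive Gaussian noise on the transformed scale rather
than realistic heteroscedastic error, and far fewer features than a real
gene-family profile (hundreds rather than ~10^6 before filtering).

## Problem sizes and determinism

The shipped experiments use 50 training samples x 200 features x 30
metabolites (+ remainder), 40-60-sample validation cohorts, 5-20
permutation-null iterations, and 10-seed replication where a rate is
claimed — sizes at which every pipeline stage exercises the same code
paths as a full-scale run. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical seeds give byte-identical weight
matrices, predictions, RTSI tables, and enrichment tables.

## Known limitations

- Cohort-relative rank transform: predictions for the same sample differ
  slightly depending on which cohort it is embedded in; single samples
  cannot be predicted.
- The well-predicted threshold 0.3 is a convention (a "medium" rank
  correlation), not a calibrated error rate; the permutation null is the
  tool for judging it on a given data set.
- No per-metabolite permutation p-values; the null procedure reports the
  aggregate well-predicted fraction and one McNemar comparison.
- RTSI has no calibrated cutoff separating "trustworthy" from
  "untrustworthy" predictions; it is a relative diagnostic.
- Elastic-net coefficients are associational; sign and magnitude should
  not be read as enzymatic stoichiometry.
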
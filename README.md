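# micromet

Predict community metabolite profiles from microbial sequence-feature
abundances.

Paired metagenome-metabolome studies are expensive, but metagenomes alone
are cheap. micromet is for microbiome researchers who have a training
cohort with both data types (taxonomic or gene-family relative abundances
**X** and metabolite relative abundances **Y** over the same samples) and
want to (1) learn which metabolites are predictable from community
composition at all, and (2) infer the metabolomes of new communities for
which only sequencing exists.

## The model

One elastic-net-regularized linear model per metabolite:

    asin(sqrt(y_j)) = b0_j + Z b_j + e_j

- `Z` — rank-based inverse normal transform of the filtered feature table
  (per feature: ranks mapped through `Phi^-1((r - 0.5)/n)`), absorbing the
  skewness and mean-variance dependence of relative-abundance data;
- `b_j` — sparse coefficient vector, estimated by minimizing
  `(1/2n)RSS + lambda*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)` with
  `alpha` (L1 fraction) and `lambda` (penalty) chosen per metabolite by
  10-fold cross-validated MSE;
- predictions are back-transformed through `sin^2(clamp(t, 0, pi/2))`, so
  they are valid relative abundances.

A metabolite is **well predicted** when the Spearman correlation `r`
between its pooled out-of-fold predictions and observations reaches 0.3;
only those models are recommended for inference. Supporting analyses:
a permutation null (independent within-feature shuffles + per-sample
renormalization, retraining each time, with an exact McNemar comparison),
the **RTSI** representativeness score for new samples (correlation with the
top training PCs, selected by a Tracy-Widom test at significance 0.05),
and gene-set enrichment over feature usage (permutation KS test, one-tailed
Fisher, Benjamini-Hochberg FDR).

## Worked example

Everything is reproducible from the built-in generator, which plants a
known sparse linear map between features and metabolites:

```sh
micromet simulate --out sim --n-samples 50 --n-features 200 \
    --n-metabolites 30 --seed 1
micromet train --features sim/X.tsv --metabolites sim/Y.tsv \
    --output model --seed 1
micromet predict --features sim/X.tsv --weights model/weights.tsv \
    --output pred --rtsi-training sim/X.tsv
```

which prints:

```
synthetic dataset written to sim (50 samples, 200 features, 20 planted + 10 noise metabolites)
20/31 metabolites well predicted; weights written to model/weights.tsv
predictions for 50 samples x 31 metabolites written to pred/predictions.tsv
```

Reading the numbers: of the 31 metabolite columns (20 carry planted signal,
10 are pure noise, 1 is the remainder mass), 20 cross the `r >= 0.3`
threshold in cross-validation — 19 of the 20 planted metabolites, none of
the noise columns, plus the remainder column (itself a function of the
features); the `fit_summary.tsv` next to the weights lists each
metabolite's selected `alpha`, `lambda`, CV Spearman, and model size. `pred/predictions.tsv` holds the back-transformed relative
abundances, `pred/rtsi.tsv` each sample's representativeness score, and
`pred/coverage.tsv` the fraction of model features observed per sample.

The same objects are available as a library:

```python
from micromet import generate, train_all, predict, TrainConfig

ds = generate(seed=1)                      # known ground truth
model = train_all(ds.X, ds.Y, TrainConfig(seed=1))
model.well_predicted.sum()                 # 20 (19 planted + remainder)
result = predict(ds.X, model)              # samples x metabolites in [0,1]
```

The remaining subcommands are `rtsi` (score new samples against a training
table), `null` (permutation-null separation of the well-predicted
fraction), and `enrich` (gene-set enrichment over a trained weight matrix,
GMT input).

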
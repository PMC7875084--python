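# wisdom

Wishart null-model scoring for symmetric positive-definite matrices,
with a per-feature log-likelihood-ratio transformation for classifying
unevenly sampled multivariate time series.

## The problem

Many biomedical datasets are naturally represented as one covariance or
correlation matrix per subject: functional connectivity between brain
regions in fMRI, correlation between EEG electrodes, and so on. When the
underlying time series have *different lengths* per subject — irregular
sampling, state-dependent segmentation, missing data — most classifiers
require clipping or padding, which distorts the temporal structure.

The Wishart distribution W_p(n, Σ) is the natural null model here: it is
the law of the scatter of n i.i.d. mean-zero Gaussian p-vectors with
covariance Σ, and its density

f(M, n, Σ) = |M|^((n−p−1)/2) exp(−½ tr(Σ⁻¹M)) / (2^(np/2) Γ_p(n/2) |Σ|^(n/2))

treats the number of observations n as an explicit parameter. A subject
observed for n_i time points is scored under W_p(n_i, Σ̂_C) — uneven
sampling is absorbed into the degrees of freedom instead of being
normalized away. The only hard constraint is n_i ≥ p (the scale matrix
must stay invertible), so the method does not apply to "wide" data.

## The method

1. **Class models.** Each class C is summarized by the (optionally
   length-weighted) average Σ̂_C of its members' matrices — itself SPD.
2. **Complete-matrix score.** For element i with matrix Σ_i and n_i
   observations, score_i = log P_W(Σ_i | n_i, Σ̂_A) − log P_W(Σ_i | n_i, Σ̂_B);
   positive favors class A.
3. **Per-feature scores.** Deleting feature j (row and column j) from
   both the element matrix and the class matrix gives
   Δlog P_W^j(C) = log P_W(Σ, n | Σ̂_C) − log P_W(Σ_j, n | Σ̂_{C_j}),
   and the two-class ratio Ratio_j = Δlog P_W^j(C₁) − Δlog P_W^j(C₂)
   becomes the element's transformed feature j. Group deletion works the
   same way on larger principal submatrices (principal submatrices of
   SPD matrices are SPD, so every deletion stays in the density's domain).
4. **Leakage-free fitting.** Class models are fitted with leave-one-out
   or stratified k-fold exclusion, so an element's matrix never enters
   the scale matrix used to score it.
5. **Downstream.** The N × (p+1) score table (p ratios + complete score)
   feeds any ordinary classifier; features are ranked by mean |Ratio_j|.

All densities are evaluated in log space with Cholesky-based
determinants and triangular solves — the normalizing constant underflows
hopelessly at realistic sizes (e.g. p=116, n=200) if computed naively.

## Worked example

Simulate a two-class dataset (class A white, class B equicorrelated at
0.5, p=5 channels, 30 elements per class, lengths 40–80), transform it
with leave-one-out class models, rank the features, and evaluate:

```
$ wisdom simulate --p 5 --n-per-class 30 --length-min 40 --length-max 80 \
    --seed 7 --out demo_data
wrote 60 batches to demo_data

$ printf 'statistic = covariance\nmode = scatter\n' > demo.cfg
$ wisdom transform --batches demo_data/batches.csv --config demo.cfg \
    --seed 7 --out demo_run
wrote 60 score vectors to demo_run/scores.csv

$ wisdom rank --scores demo_run/scores.csv --out demo_rank.csv
 rank feature    column  mean_abs_ratio
    1     ch2 ratio_ch2       14.221453
    2     ch1 ratio_ch1       12.730813
    3     ch4 ratio_ch4       11.734578
    4     ch3 ratio_ch3       11.498825
    5     ch0 ratio_ch0       11.335284

$ wisdom curve --scores demo_run/scores.csv --cv-folds 5 --seed 0 \
    --out demo_curve.csv
 k added_feature  accuracy  roc_auc
 1           ch2       1.0      1.0
 2           ch1       1.0      1.0
 3           ch4       1.0      1.0
 4           ch3       1.0      1.0
 5           ch0       1.0      1.0
```

The score table's first rows:

```
element_id,label,complete_score,ratio_ch0,ratio_ch1,...
b0000_0_78,A,36.27,7.71,12.78,...
b0001_78_143,A,48.18,6.99,6.52,...
```

`complete_score` is the whole-matrix log-likelihood ratio (positive =
class A); each `ratio_*` column quantifies how much that channel's
presence pushes the element toward one class. In this symmetric design
all five channels carry signal, so mean |ratio| is similar across
channels and a linear SVM separates the classes perfectly already with
the top-ranked one. The same commands accept real data: a delimited
series file with named channel columns and a label column
(`wisdom transform --series data.csv --label-column eye_state ...`), or
the UCI EEG eye-state ARFF file directly.

The library surface mirrors the CLI: `wisdom.transform_dataset`,
`wisdom.rank_features`, `wisdom.incremental_feature_curve`,
`wisdom.subsample_stability`, plus the lower-level density
(`wisdom.wishart_log_pdf`), sampler, class-model estimation and scoring
functions. See `docs/methods.md` for conventions, parameters and
limitations.

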
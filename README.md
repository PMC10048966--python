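# sf12risk

Depression-risk modelling pipeline for SF-12v2 cohorts: questionnaire
scoring, a seeded synthetic-cohort generator, five dimensionality reducers
(including a supervised centroid-class PCA and a stochastic-gradient PCA),
a classifier × component-count benchmark, and a CART risk tree with exact
a-priori / a-posteriori risk accounting.

## What it does

1. **Scoring** (`sf12risk.scoring`) — validates the 12 SF-12v2 item codes,
   computes the 8 domain scores on the 0–100 metric, derives norm-based
   PCS/MCS T-scores from a pluggable coefficient table, and labels
   depression risk as `MCS < 42` (strict).
2. **Synthetic cohorts** (`sf12risk.synth`) — draws correlated
   (mental, physical) latent factors per patient, maps them to latent
   domain scores, discretizes into item codes, and draws clinical
   covariates (heart failure, NYHA class, …) through logistic links on the
   factors. `calibrate_prevalence` bisects the mental-factor location until
   the large-n prevalence of `MCS < 42` matches a target (default 29.03%).
   Everything is bit-for-bit reproducible from `(config, seed)`.
3. **Reducers** (`sf12risk.reducers`) — PCA, kernel PCA (RBF,
   median-heuristic bandwidth), gradient PCA (annealed Oja updates with
   deflation), centroid-class PCA (class-centroid axes + complement PCA),
   and an LDA hybrid (Fisher axis + complement PCA), all exposing axes,
   eigenvalue analogues, feature–score correlation loadings, and
   variance-explained fractions. Includes discriminant-power ranking and
   |loading| > 0.7 feature assignment.
4. **Benchmark** (`sf12risk.bench`) — leakage-free repeated stratified CV
   accuracy grid for six classifiers (logistic regression, k-NN, SVM, MLP,
   CART, naive Bayes) on raw features ("NO") and on 1–6 retained
   centroid-class components, plus best-cell selection.
5. **Risk tree** (`sf12risk.tree`) — CART on the selected raw features with
   exact per-node counts, risk percentages, signed deltas versus the parent
   node, conservation checks, and text/DOT renderings.
6. **Pipeline** (`sf12risk.pipeline`, `sf12risk.cli`) — end-to-end
   orchestration writing all tabular artifacts plus a replayable manifest.

## CLI

```bash
sf12risk simulate --seed 1 --n 217 --calibrate --out cohort.csv
sf12risk score cohort.csv --out scored.csv --summary summary.csv
sf12risk reduce scored.csv --k 4 --out-dir reduce_out
sf12risk bench scored.csv --folds 5 --repeats 2 --seed 1 --out grid.csv
sf12risk tree scored.csv --features VT,RE,nyha_high,heart_failure --out-dir tree_out
sf12risk run-all --seed 1 --out run_out      # full pipeline + report.md
sf12risk report run_out                      # regenerate the report
```

Exit codes: 0 success, 1 validation/configuration error, 2 runtime error.

## Notes

- The norm-based scoring constants shipped in
  `scoring.default_coefficients()` are documented approximations treated as
  configuration; any 8-row CSV with columns
  `domain,norm_mean,norm_sd,pcs_weight,mcs_weight` can be substituted.
- Centroid-class PCA and the LDA hybrid are block reconstructions
  (class-oriented axes first, complement PCA after) rather than certified
  reimplementations of any specific published variant; run manifests record
  this caveat.
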
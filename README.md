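# sersml

Classification of surface-enhanced Raman spectroscopy (SERS) spectra of
cerebrospinal fluid (CSF) into control vs. hydrocephalus, with the full
chemometric pipeline: spectral preprocessing, dimensionality reduction,
and classifier selection under an overfitting-penalized weighted
balanced-accuracy score. A synthetic data generator emulating the
two-class CSF-on-AgNP-strip acquisition exercises the pipeline end to
end, deterministically.

## The problem and the model

A SERS spectrum of a CSF droplet dried on a silver-nanoparticle cellulose
strip is an intensity vector over the 550–1800 cm⁻¹ fingerprint region.
One spectrum per patient; label 1 (positive) is hydrocephalus. The
pipeline:

1. **Preprocess** — crop to 550–1800 cm⁻¹, subtract the mean blank-strip
   (substrate) spectrum, remove the slowly varying background with
   asymmetric least squares (ALS: λ = 10⁴, p = 0.001, 10 iterations),
   clamp at zero, L2-normalize.
2. **Reduce** — PCA or PLS to 1–10 components (random forests instead use
   the full spectrum).
3. **Select** — grid search over LDA/QDA (shrunk-covariance Gaussian
   discriminants), linear/polynomial/RBF SVMs, and random forests, scored
   by stratified 10-fold cross-validation on the training partition with

   `Score = MWBA − λ·(TrainAcc − ValAcc)`, λ = 2,

   where MWBA is the median over folds of the weighted balanced accuracy
   (one-vs-rest per class, inverse-class-size weights; for two classes it
   equals ½(sensitivity + specificity)). The penalty term makes a
   train-validation gap — the signature of overfitting — expensive.
4. **Evaluate** — the held-out test partition (stratified,
   largest-remainder apportionment; 70 + 47 patients at fraction 0.3 give
   exactly (48, 33) train / (22, 14) test) is touched once: confusion
   matrix, accuracy, sensitivity, specificity, precision, WBA, ROC/AUC,
   and for forest winners a per-wavenumber importance report.

See [docs/methods.md](docs/methods.md) for the model details, parameter
rationale, and limitations.

## Worked example

Run the full pipeline on synthetic data with a small grid:

```sh
cat > example.yaml <<'EOF'
seed: 11
reductions: [pca, pls]
dims: [1, 2, 3]
families: [LDA, QDA]
EOF
sersml run-all --config example.yaml --out example_run
```

prints

```
winner: pls-1 LDA reg=0.0
test WBA 95.45% accuracy 94.44% sensitivity 100.00% specificity 90.91%
```

and writes `example_run/` with the simulated dataset (`data/`: TSV
spectra, manifest, ground truth), `processed_matrix.tsv`,
`split_plan.json`, the full scored `grid_table.csv`, `winner.json`,
`evaluation.json` and `seeds.json`. Pretty-print the evaluation:

```sh
sersml evaluate --report example_run/evaluation.json
```

```
wba: 95.45%
accuracy: 94.44%
sensitivity: 100.00%
specificity: 90.91%
precision: 87.50%
auc: 1.0000
```

Reruns with the same seed are byte-identical. The individual stages are
also available as subcommands (`sersml simulate`, `sersml preprocess`,
`sersml reduce`, `sersml train`); `sersml --help` lists them.

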
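# pathrobust

Tools for asking two questions about pathway-based transcriptomic
classifiers:

1. **Are pathway-space models more robust to noise than gene-space
   models?** A classifier can be trained on the raw samples × genes
   expression matrix, or on a samples × pathways matrix of *pathway
   scores* (each pathway summarized per sample by the first principal
   component of its member genes, their mean, or a single-sample
   enrichment score). `pathrobust` degrades the gene-level signal in a
   controlled way and measures how gracefully each representation loses
   predictive accuracy.
2. **Is a pathway collection statistically special, or would random gene
   groupings do as well?** Fake collections that preserve the real one's
   set sizes and overlaps (via a single gene-label permutation) provide a
   null; the distribution of PLS-DA regression coefficients — summarized
   by histogram entropy and an area-between-curves statistic — separates
   informative collections from random ones.

Intended users: computational biologists evaluating pathway scoring /
gene-set resources for predictive modelling of bulk or single-cell
transcriptomics, and method developers who need a reproducible noise-
injection benchmark harness.

## The statistics

Let accuracy be cross-validated (leave-one-compound-out, or stratified
k-fold) and let a fraction *u* of genes be destroyed (default: each
selected gene replaced by Normal noise with its own mean and variance;
20 independent realisations per level). With ā<sub>u</sub> the median
accuracy at level *u* and a₀ = ā₀:

- local robustness  r<sub>u</sub> = ā<sub>u</sub> / a₀,
- predictive robustness  **R = ∫₀¹ r<sub>u</sub> du**, evaluated on the
  level grid by the trapezium rule, with a 90% confidence interval from
  the 5th/95th percentiles of per-repeat R values.

For a PLS-DA model with coefficient matrix B (predictors × classes), the
pooled |b<sub>i</sub>| are histogrammed on 50 bins and summarized by
Shannon entropy H(b) = −Σ p<sub>i</sub> ln p<sub>i</sub>; the ABC
statistic is Σ<sub>bins</sub> |p<sub>real</sub> − median
p<sub>fake</sub>|. Lower H and higher ABC than the fakes mean the real
collection yields *simpler* models: few influential pathways, many
near-zero coefficients.

## Worked example

Expression data are samples × genes TSV plus a sample/class/group label
table (`read_expression`), pathway collections are GMT (`read_gmt`); the
built-in simulator generates a multi-class, compound-structured dataset
with pathway-correlated signal so the whole pipeline runs without
external downloads.

```python
import pathrobust as pr
from pathrobust.analysis import PairedRobustnessAnalysis, SignatureAnalysis

expr, coll = pr.generate_synthetic(pr.SyntheticParams(seed=0))
expr, coll = pr.restrict_to_universe(expr, coll)   # 120 × 1837, 100 pathways

fit = PairedRobustnessAnalysis(expr, coll, levels=(0, 0.25, 0.5, 0.75, 1.0),
                               n_repeats=5, candidates=(1, 2, 3, 4, 5)).fit(seed=1)
print(fit.summary())
```

```
Predictive robustness — pathway space
==============================================
classifier      plsda
complexity      2
degradation     gaussian
levels          5
repeats/level   5
baseline a0     1.0000
R               0.8979
90% CI          [0.8921, 0.9000]

Predictive robustness — gene space
==============================================
...
R               0.8667
90% CI          [0.8552, 0.8717]

delta R (pathway - gene)  +0.0312
```

Both models classify the undegraded data perfectly (a₀ = 1.0), but as
genes are destroyed the pathway-space model keeps more of its accuracy:
R = 0.898 versus 0.867, with non-overlapping 90% intervals. The two
spaces are evaluated on *identical* degraded matrices per cell, so the
difference is not Monte-Carlo noise, and `complexity 2` reports the
number of PLS components selected by the sum-of-median-accuracies rule.

```python
sig = SignatureAnalysis(expr, coll, n_comp=3, n_fakes=20).fit(seed=1)
print(sig.summary())
```

```
Coefficient signature — collection
==============================================
fakes                 20
entropy (real)        2.5142
entropy (fake median) 3.0209
entropy percentile    0.0
ABC (real)            0.6417
ABC (fake median)     0.2183
ABC percentile        100.0
```

The true collection's coefficient entropy sits below every one of the 20
permutation fakes (percentile 0) and its ABC above all of them
(percentile 100): models built on the real pathway definitions are
sparser than any size- and overlap-matched random relabelling.

## Command line

```sh
pathrobust simulate   --seed 1 --out-dir data/          # matrix + labels + GMT
pathrobust score      --config cfg.yaml --out-dir out/  # pathway-space TSV
pathrobust robustness --config cfg.yaml --out-dir out/  # paired gene vs pathway
pathrobust fake-compare --config cfg.yaml --out-dir out/
pathrobust db-signature --config cfg.yaml --out-dir out/
```

Configs are YAML (see `pathrobust.workflow` for the schema); one master
seed drives every random stage, reruns reproduce outputs byte-for-byte,
and `--threads` parallelizes over degradation cells without changing any
result.

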
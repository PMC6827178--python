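# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `pathrobust`, and what the synthetic benchmark does and
does not establish about real data.

## Pathway scoring

A pathway collection is an ordered mapping of pathway ids to gene sets
over a gene *universe*. Before any analysis, expression matrix and
collection are mutually restricted (`restrict_to_universe`): genes in no
pathway are dropped, unmeasured pathway members are dropped, and
pathways falling below `min_size` (default 2 — a one-gene pathway score
would merely copy that gene) are removed. The operation is idempotent
and leaves every remaining gene in at least one pathway.

Three per-sample pathway scores are implemented:

- **PC1 (default).** The n × q member submatrix is column mean-centered
  (no variance scaling by default; a `scale` flag exists) and decomposed
  by SVD; the score is the projection on the leading right singular
  vector. Loading signs are fixed so the largest-magnitude loading
  element is positive (ties: first index), making outputs fully
  deterministic; sign is irrelevant to the linear classifiers downstream
  but matters for byte-level reproducibility. A 3-component variant
  contributes three adjacent columns per pathway. A zero-variance
  submatrix scores 0 with a warning rather than erroring, because heavy
  degradation can create near-degenerate submatrices mid-experiment;
  requesting more components than the submatrix rank is an error.
- **Mean aggregation.** Arithmetic mean of member-gene expression.
- **ssGSEA.** Per sample, genes are ranked by expression (ties: average
  ranks); walking the list in descending order, the score is the summed
  difference between the weighted in-set CDF (weights rank^α, α = 0.25
  by default, normalized within the set) and the unweighted out-of-set
  CDF. Scores are used raw; the optional cross-sample range
  normalization of the original method is a flag, default off. A pathway
  covering every measured gene has no out-of-set CDF and scores 0 with a
  warning.

## Signal degradation

Three strategies destroy gene-level information at intensity u ∈ [0, 1]:

- **gaussian** (default): ⌊u·m⌉ genes (round half up, so u = 1 always
  degrades all genes) drawn uniformly without replacement; each chosen
  column replaced by i.i.d. Normal draws with the gene's sample mean and
  unbiased variance.
- **permute**: the chosen columns' values are independently permuted
  across samples, preserving each marginal exactly.
- **global**: every gene interpolated toward noise simultaneously,
  x' = μ + √(1−u)(x−μ) + √u·ε with ε ~ N(0, s²). This
  variance-preserving convex combination is the module's definition of
  "global noise": it is exactly the identity at u = 0, coincides with
  full Gaussian replacement at u = 1, and gives expected squared
  original–degraded correlation 1−u.

Gene subsets are drawn independently at each (level, repeat) cell
(non-nested), each cell's random stream derives from the experiment seed
and the cell coordinates, and labels are never modified. Default level
grid 0, 0.1, …, 1.0; default 20 repeats per level.

## Classifiers and cross-validation

PLS-DA regresses a dummy-coded class indicator matrix on mean-centered
predictors via standard PLS2 (delegated to scikit-learn's
`PLSRegression` with `scale=False`); predictions are decoded by argmax
over the class responses (ties: first class in sorted label order). The
coefficient matrix B (predictors × classes) is retained for the
signature analyses. Because PLS components are nested, the k-component
coefficient matrix equals the product of the first k rotation and
loading columns of a larger fit; complexity sweeps therefore fit one
maximal model per fold and read every candidate off by truncation,
which is algebraically identical to refitting (verified against
candidate-by-candidate refits in the tests). kNN uses majority vote with
vote ties broken by the smaller mean neighbour distance, then label
order. The SVM is linear-kernel with one-vs-one voting.

Cross-validation is leave-one-group-out (every sample of one compound
held out per fold — the default whenever group labels exist) or
class-stratified k-fold (default 2 folds, shuffled with a seed derived
from the experiment seed and the repeat index, so level-0 accuracy is
well defined per repeat). Accuracy is pooled: each sample predicted
exactly once, correct / n. A training fold missing a class is an error.

**Complexity selection.** For each candidate complexity the median CV
accuracy over repeats is computed at every degradation level; the
candidate maximizing the sum of medians over levels wins, ties going to
the smallest complexity. Default candidate grids: PLS components 1–10,
kNN neighbours {1,3,5,7,9,11,15}, SVM cost {0.01,0.1,1,10,100} (all
configurable). The sweep that selects the complexity also supplies the
selected candidate's accuracies as the degradation profile, rather than
rerunning the experiment; complexity is selected once per workflow
variant, not inside every repeat.

## Robustness statistic

Local robustness r_u = (median accuracy at u)/a₀ with a₀ the median
level-0 accuracy; r₀ ≡ 1. Predictive robustness R = ∫₀¹ r_u du by the
trapezium rule on the level grid (the grid must span [0, 1]). R is not
clipped: degradation that helps can push R above 1. The 90% interval
comes from per-repeat R values (each repeat's accuracies divided by the
shared a₀, its level-0 point being its own ratio; a flag forces it to 1
instead), using linear-interpolation percentiles at 5% and 95%.

In the paired gene-vs-pathway comparison both spaces are evaluated on
the *identical* degraded matrix in every cell. Pairing removes
independent Monte-Carlo noise from the R difference and only sharpens
the comparison.

## Randomization nulls and coefficient signatures

`permute_gene_labels` draws one uniform permutation of the universe and
relabels every pathway through it, preserving all set sizes and all
pairwise intersection cardinalities exactly (the gene–pathway incidence
structure is isomorphic). `random_gene_sets` draws size-matched uniform
sets, preserving sizes but not overlaps. Defaults: 10 fake collections
for robustness comparisons, 100 for signature nulls.

Signatures are computed on undegraded data only. Coefficients are pooled
across all class response columns (for two classes dummy coding makes
the columns redundant, so pooling reduces to the single-column case);
|b| values are histogrammed on 50 equal-width bins with *common* edges
[0, max |b| over the real and all fake collections], so entropies and
ABC values are comparable. Entropy uses 0·ln 0 ≡ 0. Each fake's own ABC
is measured against the leave-one-out median of the other fakes'
histograms, avoiding self-comparison bias; the real ABC uses all fakes.
Per-database analysis applies the same comparison to each source-tag
subset of the collection, optionally with a size-matched subsampling
control.

## Synthetic benchmark

The generator emulates a multi-class toxicogenomics design: C classes ×
`groups_per_class` compounds, equal group sizes. Defaults (the study
conditions used throughout the package's own experiments): 120 samples,
3 classes, 4 compounds per class, 2000 genes, 100 pathways of sizes
10–30 occupying consecutive gene blocks with binomial overlap
(probability 0.1) between consecutive pathways only — which keeps
overlap accounting exactly checkable — 20 informative pathways, effect
size δ = 1.5, gene-on-latent correlation ρ = 0.6, unit noise SD.

Each informative pathway carries a latent activity with class-specific
offsets drawn per pathway (centered, unit population SD), so different
pathways separate different class contrasts; the latent
(δ·offset + N(0,1)) is standardized to unit variance before genes are
generated as ρ·z + √(1−ρ²)·ε, making ρ exactly the gene-on-latent
correlation and ρ² the expected within-pathway gene–gene correlation.
A per-compound random intercept (SD 0.3 on the latent scale) makes
leave-one-compound-out CV genuinely harder than random splits. This is a
deliberate one-factor-per-pathway linear model, not a regulatory-network
simulator: it creates exactly the structure the scoring and robustness
hypotheses assume.

**What passing tests show — and don't.** On this generator the
pathway-space robustness advantage and the simplicity signature (lower
entropy, higher ABC than permutation fakes) reproduce decisively. But
the generator concentrates class signal in 20 true pathways; real
microarray data spread correlated signal over thousands of genes. One
observable consequence: label-permuted fake collections, which on real
data can be nearly as robust as the true collection (because any
grouping of signal-bearing genes aggregates signal), are systematically
*less* robust here — the real collection's R lies above the whole fake
range. Results on this benchmark therefore demonstrate correctness and
sensitivity of the machinery, not the null behaviour of fake collections
on diffuse-signal data; probe-level noise, batch effects and count-based
(sequencing) error models are likewise out of scope.

## Numerical and reproducibility choices

- One master seed determines all randomness. Per-cell streams derive
  from `SeedSequence([seed, level_index, repeat])`, fake collections
  and signature nulls from fixed offsets of the master seed — results
  are independent of execution order and of the `--threads` worker
  count, and reruns are byte-identical (TSV floats are written with a
  fixed `%.10g` format; the expression reader converts numerals with
  numpy's correctly-rounded parser so write/read round-trips are
  bit-exact).
- Degradation level fractions are rounded half-up to gene counts;
  percentiles use the linear-interpolation convention.
- Experiments in the package's own tests and acceptance script run at
  desk scale: 5 degradation levels {0, 0.25, 0.5, 0.75, 1}, 5 repeats
  per level, PLS component candidates 1–5, 10–20 fake collections —
  sizes chosen to exercise every code path at full data dimensions while
  keeping a complete run in minutes on one CPU.
- Degenerate inputs: zero-variance pathways score 0 (warning); an
  all-zero coefficient matrix, a zero undegraded accuracy, a level grid
  not spanning [0, 1], and a training fold missing a class are errors.

## Known limitations

- Gene identifiers are matched as exact strings; probe/symbol mapping
  and normalization (e.g. RMA) are upstream of this package.
- No formal hypothesis test compares two R values; the package reports
  percentile intervals and leaves inference to non-overlap, as the
  profiles themselves make the comparison visually unambiguous.
- ssGSEA parameter conventions (α, normalization) vary across published
  implementations; the defaults here (α = 0.25, raw scores) are flagged
  in the config and should be matched deliberately when comparing to
  other software.
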
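# Methods

## The problem and the model

Serum exosomal miRNAs are candidate non-invasive tumor biomarkers: miRNAs
packaged in extracellular vesicles can be transferred between cells and
regulate mRNAs in recipient tissue.  A discovery design that looks for
such circuits combines (i) tumor-vs-normal differential expression (DE) in
tissue mRNA and miRNA, (ii) DE of serum exosomal miRNAs in a separate
case-control cohort, (iii) set intersections with predicted miRNA→mRNA
targets, (iv) sparse-model feature selection to reduce candidates to a
"key" panel, and (v) assembly of the key miRNA × key mRNA interactions
into a bipartite network, validated by diagnostic ROC and survival/stage/
MSI association.  `exonet` implements this workflow end to end against a
synthetic-study generator with planted ground truth, so every stage is
testable without external downloads.

## Differential expression

Counts are normalized to counts-per-million (CPM; each sample rescaled to
a total of 10^6) and transformed as log2(CPM + 1); the +1 pseudocount
avoids −∞ at zero counts and makes results bit-reproducible.  Features
with CPM ≥ 1 in fewer than 25% of samples are dropped (a simple
low-expression filter; both cutoffs configurable).  Microarray-style
intensity matrices are log2-transformed directly.

Two assumption-distinct per-feature tests are run on the same matrix — a
parametric Welch two-sample t-test and a nonparametric Wilcoxon rank-sum
test — mirroring the common practice of running two DE engines and
merging.  The rank test uses exact enumeration for small tie-free samples
and the tie-corrected normal approximation otherwise (scipy's policy).
log2FC is mean(tumor) − mean(normal) on the log2 scale.  P-values are
Benjamini–Hochberg adjusted per method, and a feature is called when
|log2FC| > 1 **and** FDR < 0.05, both strictly; the two call sets are then
merged by union.  Direction conflicts between methods are retained (the
per-method tables record direction); no resolution rule is imposed.

## Candidate screening

miRNA identifiers from different platforms disagree in casing
("hsa-mir-29c" vs "hsa-miR-29c"), so IDs are canonicalized to the mature
"hsa-miR-…" form (with "let" stems preserved) before any intersection.
Arm suffixes (-3p/-5p) are kept by default; an optional policy strips
them, since some sources list stem-loop-style names.  Candidate exosomal
miRNAs are the intersection of the tissue-DE and exosomal-DE miRNA sets;
predicted targets from all sources are unioned (a pair predicted by any
source counts), restricted to candidate miRNAs, and intersected with the
DE mRNA set to give candidate mRNAs.  Provenance (which miRNAs predicted
each surviving mRNA, which sources predicted each pair) is carried along.

## Balanced-subsample LASSO stability selection

This is the package's core.  With m tumors ≫ n controls, a single
penalized fit is dominated by the majority class.  Instead, B rounds are
run; in each round n tumors are drawn without replacement and combined
with all n controls (2n balanced samples).  An L1-penalized logistic
model is fitted along a descending λ grid, λ is chosen by stratified
10-fold cross-validation at the minimum held-out mean binomial deviance
(the `lambda.min` rule; ties go to the larger, sparser λ), and the
features with nonzero coefficients at the chosen λ are counted as
selected.  After B rounds a feature is **key** iff its count strictly
exceeds the threshold (default B/2 — "more than half the rounds"), and
its contribution is summarized as the mean coefficient over the rounds in
which it was selected (sign preserved).

Numerical choices:

- The solver minimizes (1/n)·Σ logistic loss + λ‖β‖₁ with an unpenalized
  intercept, via IRLS with cyclic coordinate descent on the working
  weighted least squares (soft-thresholding gives exact zeros),
  warm-started along the grid with sequential strong-rule screening and a
  final KKT check.  Convergence is declared when coefficients stop moving
  across a full linearize-and-solve step (tolerance 1e-8 on the max
  coefficient change; IRLS weights floored at 1e-5).
- λ grid: 100 log-spaced values from λ_max = max_j |x_jᵀ(y − ȳ)|/n down
  to 0.001·λ_max (the glmnet convention).  λ = λ_max returns the exact
  null model; a 1e-10 relative slack absorbs float rounding at the KKT
  boundary.
- Features are standardized (mean 0, SD 1) on each round's balanced
  subsample before fitting, because the L1 penalty is scale-sensitive;
  counts enter as log2(CPM+1), exosomal data as log2 intensity.
  Constant columns get SD 1 and can never be selected.
- Per-round seeds derive from the master seed via a fixed counter scheme
  (`numpy.random.SeedSequence`), so the full run is a pure function of
  (data, config) and any round is independently reproducible.
- Defaults are desk-scale: B = 200 rounds per feature class (the
  reference analysis scale of 1000 for miRNAs and 10000 for mRNAs is a
  configuration change, not a code change).

A known behavior worth stating plainly: the exact L1 solution path is
**not** globally monotone in its nonzero count — variables can exit the
active set as λ decreases when p is comparable to n (R's glmnet shows the
same df drops on identical data).  In the n ≫ p regime the path adds
features monotonically, and that is where the path-shape property is
tested.  Relatedly, when several features carry strong, mutually
redundant signal, the cross-validation-chosen model does not need every
informative feature in every round, so selection frequencies of a planted
panel can straddle 1/2 on particular dataset realizations; per-feature
frequencies agree with `cv.glmnet` to within Monte-Carlo noise, so this
is a property of the procedure, not of the implementation.

## Network construction

Predicted interactions between key miRNAs and key mRNAs are filtered to a
minimum confidence class on the ordered scale low < medium < high <
"very high" (default ≥ high, matching integrative-confidence semantics);
duplicates keep the maximum confidence.  "Bidirectional relationships"
are modeled as undirected edges.  The network is strictly bipartite —
node sets are the endpoints of surviving edges (no zero-degree nodes),
and an identifier appearing on both sides is an error.  Degree reports
flag miRNAs connected to more than half of the network's mRNAs and mRNAs
at or above a configurable degree cutoff (default 3); ties rank
lexicographically.  Exports: Cytoscape SIF, GraphML with node-type and
confidence attributes, and a TSV degree table.

## Validation

- **ROC/AUC** — the rank-based Mann–Whitney form (ties count ½), with a
  stratified bootstrap percentile 95% CI (default 2000 resamples, seeded;
  positives and negatives resampled separately).  The bootstrap was
  preferred over DeLong because it is simple to specify exactly and
  robust with ties; the interval is widened to contain the point estimate
  in degenerate cases.
- **Survival** — tumors are split at the median expression (values equal
  to the median go to the low group, a deterministic tie policy);
  Kaplan–Meier curves per group and a two-group log-rank test (lifelines)
  with a χ² p-value on 1 df.
- **Stage** — Kruskal–Wallis across stages with ≥ 2 samples each
  (smaller stages dropped with a warning).  A rank test was chosen over
  an F-test on log expression because it is distribution-free and only
  the significance is used; with exactly two stages it reduces to the
  squared standardized rank-sum statistic.
- **MSI** — two-sided Wilcoxon rank-sum comparing MSS vs MSI-H.

## The synthetic-study generator

The generator emulates the study design the pipeline targets:

- **Tissue counts** — negative binomial with variance μ + φμ² (default
  dispersion φ = 0.2), per-feature baselines log-normally spread around
  `baseline_mean` (default 100), per-sample library-size factors
  log-normal(0, 0.2).  Default cohort 600 tumors / 50 normals.
- **Exosomal intensities** — log-normal; log2 intensities are Gaussian
  around per-feature baselines (N(8, 2)) with noise SD 1.0.  Default
  cohort 88 tumor sera / 11 healthy controls — the severe imbalance that
  motivates balanced subsampling.  About 30% of exosomal miRNA IDs are
  deliberately emitted with a lowercase "hsa-mir-" prefix to exercise ID
  harmonization; every exosomal ID maps into the tissue miRNA namespace.
- **Planted structure** — DE features carry a planted log2FC (default 2);
  key features carry `planted_log2fc × key_effect_multiplier` (default
  ×2, i.e. log2FC 4).  The boost is what makes "key" a meaningful ground
  truth: if key features were statistically exchangeable with other DE
  features, no selector could preferentially recover them.  Planted
  miRNA→mRNA edges connect every planted key miRNA and key mRNA and are
  present in the prediction table with confidence "high"; decoy pairs are
  added per source with probability `decoy_rate` and random confidence.
- **Clinical covariates** (tumor samples only) — exponential survival
  with hazard `baseline_hazard · exp(log_hr · (tertile − 1))` of a linked
  feature's expression tertile (default ln 2 per tertile step),
  administratively censored at 60 months; stage sampled I–IV
  (0.20/0.35/0.30/0.15); MSI-H sampled on a logit scale (base rate 0.15)
  with an optional expression-linked shift (default log-odds 1 per
  tertile).

What the generator does **not** emulate: gene–gene correlation,
batch effects, GC/length biases, probe-level artifacts, non-exponential
hazards, and informative censoring.  Passing tests therefore demonstrate
the pipeline's logic and calibration under a clean generative model, not
performance on real cohorts.

## Experiment sizes

The bundled experiments are sized for a single CPU: the recovery
benchmark uses 500 candidate features (10 informative at a 2 SD shift,
chosen comfortably above the 1 SD detection floor of a 40-sample balanced
subsample), m = 200 / n = 20, B = 200; DE calibration uses 20 replicates
of 300 features at 25 per group; the end-to-end configuration simulates
1000 mRNAs / 300 miRNAs with B = 200 per feature class.

## Known limitations

- The DE stand-ins are Welch and rank-sum tests on log-CPM, not
  empirical-Bayes moderated models; no TMM or quantile normalization.
- No elastic-net or adaptive variants; no p-values on selection
  frequencies.
- Multi-class confidence comes as labels, not scores; no live queries to
  any prediction database.
- Survival validation is univariate (median split + log-rank); no Cox
  modeling.
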
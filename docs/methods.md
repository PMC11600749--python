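# Methods

This note documents the statistical model behind `micro-fms`, the defaults
that matter, and the design decisions taken where the problem left room.

## Problem setting

Soil amplicon surveys yield a samples × taxa count table (an OTU/ASV
table) whose rows sum to a technically determined sequencing depth
m^(k) = Σ_i w_i^(k).  The counts are therefore *compositional* (only
relative information), *sparse* (most cells are zero), and
*high-dimensional* (more taxa than samples at fine ranks).  The package
asks whether such a table — possibly together with soil chemistry and
microbial population density — can predict binary plant phenotypes
(tuber disease present/absent, yield above/below the variety-specific
median), and, just as importantly, how much the *human preprocessing
choices* move the answer.

## The preprocessing design: 20 NM variants

Four zero-replacement strategies are crossed with five normalizations,
giving the canonical `NM_1 … NM_20` enumeration (normalization-major:
`NM_1` = TSS+none, `NM_6` = CSS+pseudo, `NM_20` = clr+bayesMult).

Zero replacement (all outputs rescaled to the original depth, so ratios
between originally-nonzero taxa are exactly preserved):

* **none** — identity.
* **pseudo** — zero cells set to a pseudo count (default 1).  Only zero
  cells are touched; an all-cells variant is a config switch.
* **multRepl** — multiplicative replacement of left-censored
  compositions: on the proportion scale, zeros ← δ_k = 0.65 × (minimum
  nonzero proportion of sample k) and nonzeros shrink by (1 − z_k δ_k).
  The 0.65 fraction is the conventional default magnitude; δ_k is capped
  at 0.65/z_k so the adjusted composition stays positive when a sample
  has few nonzero cells with large proportions.
* **bayesMult** — posterior-mean proportions under a uniform Dirichlet
  prior of total strength s = 1: a zero taxon gets (s/p)/(m^(k)+s), and
  the nonzero part is closed multiplicatively.  The prior strength is a
  config knob; no published value fixes it.

Normalizations:

* **TSS** — proportions x_ij/m_i (rows sum to 1).
* **CSS** — cumulative-sum scaling: each sample is divided by the sum of
  its counts at or below the per-sample median of positive counts, then
  rescaled by the median scaling factor.  The quantile is fixed at 0.5;
  the adaptive quantile search of the original CSS method is out of
  scope.
* **COM** — common-sum scaling to the minimum depth, x_ij·min_k m_k/m_i.
* **rarefy** — seeded subsampling without replacement to the minimum
  depth (multivariate hypergeometric).  Rarefying draws reads, so
  fractional imputed counts are rounded first (imputed cells in (0,1)
  are kept at one read); the zero-replaced-then-rarefied variants
  therefore rarefy near-original counts.
* **clr** — centered log-ratio log(x_ij/g(x_i·)) (rows sum to 0).  clr
  with zero_method `none` is defined by first pseudo-imputing zeros with
  1; the log of zero is undefined, so the variant requires *some*
  implicit handling to exist.

Environmental features use six scalers (standard, minmax, maxabs,
robust, rank-to-normal quantile, row unit-norm), always fit on training
rows only and applied to held-out rows.  The standard scaler uses the
sample (ddof = 1) standard deviation and maps zero-variance columns to 0
with a warning.

## Binarization, splitting, augmentation

Disease severities binarize at zero: label = 1[value > 0].  Yields
binarize against the *variety-specific* median; a value exactly at the
median joins class 0 (the strict </> rule leaves median ties undefined
for odd n, and class 0 keeps every labeled sample labeled).  Splits are
80/20 stratified with |test| = round(0.2 n).

Augmentation runs on the training split only — augmenting before the
split leaks near-copies of test rows into training, which the
`leakage_check` assertion guards via per-row provenance.  For each
(variety, label) subset, a synthetic row is a uniformly drawn original
row plus elementwise Normal(μ/100, σ/100) noise, with μ, σ the subset
mean and standard deviation; subsets of a label are filled round-robin
until the label holds exactly 400 rows (originals count toward the 400,
switchable).  Negative synthetic abundances are clipped at 0 on
count-like scales but not for clr features, which are legitimately
negative.  Singleton subsets use σ = 0 with a warning.

## Dual feature selection

Seven ML strategies each nominate k = ⌈0.3 p⌉ taxa: ANOVA F, mutual
information, RFE under logistic regression / decision tree / gradient
boosting / random forest (step = 10% of features per iteration), and a
top-30%-of-column-maxima screen.  `TOTAL` ∈ 0..7 counts agreements; the
top 30% by TOTAL (ties broken by F statistic, then taxon id — the
deterministic cut is applied after sorting, at exactly ⌈0.3 p⌉) are
ML-selected.  Columns are sorted lexicographically before scoring so the
result is invariant to input column order (tree tie-breaks are
positional otherwise).

The network route estimates one sparse association network per class:
modified-clr transform (clr over positive entries, zeros kept at 0,
positives shifted strictly above 0), pairwise Kendall τ mapped through
sin(πτ/2) (the Gaussian-copula bridge), projection to the nearest
positive-semidefinite correlation (eigenvalue clipping + diagonal
renormalization), then a graphical lasso at λ = 0.1.  Partial
correlations r_ij = −Ω_ij/√(Ω_ii Ω_jj) define edges; edge weights are
the signed-distance similarities 1 − √(0.5(1−r)) ∈ [0, 1].  Taxa are
ranked by the absolute difference of weighted node degree between the
two class networks; the top 30% are network-selected.  Binary degree is
a config option.  This estimator is a rank-based copula + sparse
partial-correlation pipeline built from scipy/sklearn primitives and is
pluggable behind `NetworkConfig`.

Combined scores: 0 = neither, 1 = ML only, 2 = network only, 3 = both.
Predictor sets concatenate columns per the named designs (ALL-OTU,
OTU-S0..S3, Alpha, Soil, DS and their combinations); OTU-S0 is
subsampled (seeded) to the width of OTU-S3 for a fair score-0 control.

## Models, metrics, baselines

The classifier is a random forest tuned by exhaustive grid search with
stratified K-fold cross-validation on weighted F1 (default grid:
trees {100, 500}, depth {∞, 5, 10}, min split {2, 5}, max features
{√p, 0.3p}; 10 folds).  A one-point, 3-fold grid (`SMALL_RF_GRID`)
serves smoke runs and permutation replicates.

Weighted F1 = Σ w_i F1_i / Σ w_i with w_i the true class sizes; a class
with no true and no predicted members scores 0.  MAPE =
(1/n) Σ |A_i − F_i| / |A_i| × 100, undefined when any actual value is 0.

Every real score is referenced against a permutation baseline: each
feature column is permuted independently (severing the feature–label
association while preserving marginals — the conservative null) and the
identical split/tune/test pipeline is rerun; the mean over replicates is
the chance line.

## Full model selection

The benchmark grid treats (augmentation, NM variant, taxonomic rank) as
factors — 2 × 20 × 5 = 200 preprocessing options — with achieved
weighted F1 as the response.  A hand-written greedy CART (squared-error
criterion, max depth 4, min split 2, min leaf 1) over one-hot indicators
ranks the choices; each split is a yes/no on a single human decision.
Ties between equally good splits are broken by factor order (Aug,
NM_1..NM_20, ranks coarsest-first), making the tree fully deterministic
— library CARTs break such ties by an internal random feature
permutation.  Node means are exact means of covered rows; leaf coverages
partition 100% of the options.

## The synthetic-data generator

Counts follow a logistic-normal–multinomial: per-sample latent
log-abundances = taxon baseline N(0, 1.5) + per-field random intercepts
N(0, 0.3) + per-state offsets N(0, 0.2) + class effects + cell noise
N(0, noise_sd); softmax, then a multinomial draw at a depth uniform on
`depth_range`.  The logistic-normal form (rather than
Dirichlet-multinomial) allows per-taxon class effects on the log scale,
matching the clr/TSS transforms tested downstream.  Structural zeros are
planted uniformly (sparing each row's largest cell) at the rate needed
to bring the realized zero fraction to the target sparsity; a target
below what multinomial sampling alone produces raises an explicit error.
The field and state variance components are placeholders — no field
variance is published for the emulated study — and are exposed in the
config.

Each of the six responses owns a field-level latent binary condition and
a disjoint block of `n_signal_taxa` genera.  The condition shifts its
block by `effect_size` on the log scale *and* raises the
disease-positive rate (logit = base-rate anchor + 1.5·z(condition) +
0.8·z(first soil column)), so the planted taxa are genuinely predictive.
The mediation matters: it makes `effect_size = 0` an exact null for the
microbiome–disease link, which the null-recovery tests rely on.  Disease
severities are zero-inflated (tuber counts 1 + Poisson(3) for scabs, a
Beta-distributed percentage for black scurf); base rates anchor to the
emulated prevalences (74% / 43% / 63% / 9.5%), with a preset for
black-scurf-like extreme imbalance (2.5% positive).  Yields are variety
intercepts plus an environmental linear term plus a weak term in the
realized signal abundance plus noise.

What the generator does *not* emulate: phylogenetic correlation between
related taxa, overdispersion beyond the logistic-normal, spatial field
coordinates, read-level (FASTQ) structure, or any fit to the real
deposited sequences.  Passing tests demonstrate that the pipeline
recovers signal of this planted form — not that any particular real
dataset carries such signal.

## Problem sizes in tests and the acceptance script

Recovery checks run at 201 samples (67 fields × 3), 60 genera, 5 planted
taxa, effect 1.5, 60% sparsity, depths 2 000–10 000 — a deliberately
reduced taxon count that keeps the full dual-selection pipeline
(including pairwise Kendall τ and the graphical lasso per class) fast
while preserving the p ≈ n/3 per-class geometry that makes network
estimation noisy in practice.  With ⌈0.3 p⌉ cuts on both routes, the
score ≥ 1 union covers roughly half the taxa, so per-seed enrichment
tests are floor-limited (a perfect 5/5 recovery gives p ≈ 0.03); the
acceptance check therefore pools planted-taxon hits over three seeds
against the pooled hypergeometric null.  The degree-difference route
contributes little at these class sizes — an honest reflection of how
noisy differential-network selection is at ~100 samples per class.

## Numerical choices and degenerate inputs

* Aggregation pools NA lineages into one `unassigned` taxon per rank, so
  per-sample depths are conserved exactly (COM/rarefy correctness).
* `filter_by_prevalence` keeps taxa with count > 0 in ≥ 15 samples
  (boundary inclusive) and errors rather than returning an empty table.
* Partial correlations below 1e−10 in absolute value are treated as
  numerically zero when forming network edges.
* An all-zero sample is an error for multRepl/bayesMult (no minimum
  nonzero proportion exists) and for alpha diversity.
* Alpha diversity rarefies to the minimum depth (seeded) before
  computing Chao1 (bias-corrected), ACE (rare threshold 10), Shannon
  (natural log), Simpson, and inverse Simpson.
* Constant regression targets give a single-leaf FMS tree, not an error.

## Known limitations

* The Bayesian neural network companion model is a documented extension
  point only; no HMC training is included.
* CSS uses a fixed median quantile; BIOM I/O is not provided (TSV/CSV
  only); no SMOTE/mixup augmentation variants; no stability selection or
  differential-network significance testing.
* The full 600-configuration benchmark at study scale is supported by
  the orchestrator but the shipped tests and acceptance script exercise
  reduced grids; runtime at full scale is dominated by per-configuration
  grid-search CV.
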
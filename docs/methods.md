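# Methods

This note records the models, the numerical conventions and the design
choices behind `lungsig`, and what the synthetic experiments do and do
not demonstrate.

## Synthetic cohorts

The generator emulates two microarray studies of lung tissue on a shared
gene universe, one contributing IPF patients with a few healthy controls
(17/6 by default) and one contributing NSCLC patients with many controls
(46/45). On the log2 scale each value is

x_gs = scale_g,study · (m_g + effect + alteration + ε_gs) + shift_g,study

with per-gene baselines m_g ~ N(8, 1.5²), noise ε ~ N(0, noise_sd²)
(default 0.5), per-study per-gene batch shift ~ N(0, 0.8²) and scale ~
U(0.8, 1.25). Each disease carries 100 differential genes shifted by
±2.0 (log2) in the disease group; 40 of them are shared between diseases
with identical sign — the planted "common signature". These are the
effect sizes and cohort shapes the pipeline's operating regime is
defined for: a log2 fold change of 4 noise SDs is a strong but realistic
microarray signature effect, and it makes per-gene power ≈ 1 at the
17-vs-6 cohort shape, so recovery failures indicate pipeline defects
rather than sampling noise.

Mutually exclusive pairs (2 by default) are planted on dedicated genes
shared by both diseases. Each pair gene carries a disease-wide baseline
shift of 1.25·noise_sd plus an extra 3·noise_sd excursion on its
assigned samples; the two genes of a pair get disjoint sample sets
covering `mutex_coverage` (default 0.5) of the disease cohort each.
Non-altered disease samples of these genes use noise truncated at
±0.6·noise_sd, so the 2-SD binarization rule recovers the planted
pattern essentially exactly. The baseline component is what lets these
genes also clear the signature funnel (their disease-axis correlation is
≈ 0.7, just above the 0.6 loading threshold); without it a
coverage-0.5 alteration pattern alone correlates with the disease
indicator at only ≈ 0.45 and would never appear among signature genes —
with 17 IPF samples this margin is thin, and a planted pair member
occasionally misses the signature in one disease, which is why the
pipeline reports per-pair recovery rather than asserting it.

Each study consumes an RNG stream spawned from the master seed, so
cohorts are bit-reproducible and adding a study leaves earlier studies
unchanged.

What the generator does *not* model: probe-level structure, missing
values, heavy-tailed noise, correlated gene modules beyond the planted
effects, or confounders such as age and smoking. Passing tests therefore
show that the pipeline recovers the signal class it targets under clean
Gaussian batch-distorted data, not that it is robust to every failure
mode of real microarray cohorts.

## Cross-study merging

The merge implements an XPN-style block model. Per iteration: genes are
k-means clustered (K_g = 25) and samples k-means clustered (K_s = 5) on
within-study standardized values (so clusters reflect biology rather
than batch offsets); A[i, j] is the pooled mean of block (gene cluster
i, sample cluster j); each gene's per-study response is modelled as
x ≈ b · A[α(g), β(s)] + c and the per-study (b, c) are harmonized to
their sample-size-weighted averages. The objective
J = Σ blocks Σ studies size · (study block mean − pooled block mean)²
is recorded per iteration; an iteration that fails to reduce J is rolled
back, so the reported trace is non-increasing by construction, and
convergence is declared at relative ΔJ < 1e-4 (max 50 iterations,
seeded k-means).

Two refinements matter in unbalanced designs where each disease appears
in only one study:

* **Scale guard.** The affine (b-rescaling) path is applied only when
  the gene has an identifiable, plausible sensitivity in *every* study
  (cluster-profile variance > 0.05, 0.4 < |b| < 2.5). Otherwise a
  weighted average b̄ — dominated by the study where the gene is flat —
  would shrink a study-exclusive disease contrast toward zero (measured:
  half the planted IPF-specific genes lost their significance before
  this guard).
* **Anchored intercepts.** Offsets c are estimated only over samples of
  phenotypes present in all studies (here the healthy controls), with
  the gene-level pooled sensitivity accounting for anchor composition.
  Anchoring on all samples (or on k-means sample clusters, which freely
  mix IPF with NSCLC samples) imputes one study's disease composition
  into the other's correction; measured on the default cohorts this
  fabricated cross-disease contrasts of ≈ 1.4 log2 units perfectly
  correlated with the true disease direction, flooding the common
  signature with disease-specific genes. With phenotype anchoring the
  residual cross-study control offset is sampling noise
  (≈ noise_sd/√6 per gene), and the common signature contains no
  crossover genes.

The quantile pre-normalization step is available
(`quantile_normalize=True`) but off by default: any within-study
quantile step alters values even when two studies are byte-identical,
and the identity case is a contract of the merge.

A consequence of the few-controls anchor (6 healthy in the IPF study) is
mild correlated noise in the IPF-vs-healthy contrast, visible as an
inflated DEG count in that comparison (~330 at α = 0.05 of which ~100
are planted). The false positives have random directions and sub-0.6
loadings, so they do not reach the common signature.

## DEG screen

Classic pooled-variance two-sample t per gene, df = n₁+n₂−2, two-sided
p, no multiple-testing correction (Benjamini–Hochberg available via
`adjust="bh"`), Welch's variant behind a flag. Zero-variance genes are
reported as p = 1 with a flag rather than NaN. Selection is strict
p < α with deterministic ordering (ascending p, ties by symbol).
Two-way clustering delegates to scipy's complete-linkage implementation
on Euclidean distances; tie-breaking at equal merge heights follows
scipy's deterministic order, and trees are exported as newick via
scikit-bio.

## SVM classification and gene weights

`SVC` with Gaussian kernel. The working bandwidth σ = 0.1 is applied as
gamma = σ/√p on standardized features (p = number of genes). Rationale:
squared distances between standardized p-dimensional samples concentrate
around 2p with spread of order √(8p). A raw gamma of 0.1 (the kernlab
`rbfdot` convention) drives every off-diagonal kernel entry below 1e-6
once p exceeds ~100 — the kernel matrix degenerates to the identity and
prediction collapses to majority voting (measured: 55% LOOCV accuracy on
a planted 63-vs-51 cohort that should separate perfectly). The √p
normalization keeps the kernel's local geometry comparable across the
dimensionalities the DEG filter produces; with it the same cohort scores
100%. Soft-margin cost C = 1 (configurable), Platt-scaled probabilities
via 3-fold internal calibration (sigmoid method, seeded, refit on the
full data).

Per-gene weight coefficients are w_j = |Σ_i α_i y_i x_ij| over support
vectors on standardized features — the linear functional implied by the
dual solution, which reduces to the exact primal hyperplane weight for a
linear kernel. Two caveats discovered during validation and reflected in
the tests: (i) in the fully separable regime the dual mass, and hence
every weight, legitimately collapses toward zero, so weight magnitudes
are only a signal readout away from separability; (ii) the global
maximum weight over thousands of genes is an order statistic of the
noise tail — signal claims should compare the weights of specific genes.
The weight-threshold filter (> 1.0, strict) typically removes only a
small fraction of DEGs at the default cohort sizes, consistent with the
dual-sum scale of w.

LOOCV refits standardization and the SVM inside every fold. Each fold
additionally reweights classes to the full-cohort priors
(weight n_c/(n_c−1) for the held-out sample's class): without this, the
held-out class is always one member short in training, which biases
hold-out predictions toward the other class — on label-permuted data
this classic LOOCV artifact depresses accuracy well below chance
(measured means ≈ 0.40–0.45 without the correction, ≈ 0.48 with it).

ROC points come from `sklearn.roc_curve` and AUC from the trapezoidal
rule over them, which equals the Mann–Whitney U statistic divided by
n₁n₂ (tie handling by threshold grouping); the identity is asserted
against scipy's independent implementation in the tests.

## PCA, probit component tests, signature genes

PCA is computed by SVD of the gene-centered (not scaled) samples × genes
matrix; components are capped at min(n_samples − 1, n_genes).
"Loadings" are gene–score Pearson correlations, bounded by ±1 — with a
few hundred genes at most a couple of *unit-eigenvector* entries could
ever exceed 0.6, so a 0.6 threshold is only meaningful on the
correlation scale. Constant genes get loading 0 and are flagged.

Component relevance: the shortest PC prefix reaching 85% cumulative
variance is tested one PC at a time (per-PC p-values make sense only in
univariate regressions) by a Bayesian probit regression of phenotype on
the standardized score — Cauchy prior (Student-t, df 1) of scale 2.5 on
the slope and scale 10 on the intercept, optimized to the posterior mode
with an analytic gradient, standard errors from the observed information
(finite differences of the gradient), two-sided Wald p. Under the null
the Wald p is well calibrated (measured rejection rate 0.048 at nominal
0.05, 500 replicates). Under complete separation the prior keeps the
slope finite (≈ 3) but the Wald standard error grows with it
(Hauck–Donner effect), so the p-value saturates around 1e-2 rather than
becoming arbitrarily small; the tests therefore assert significance at
0.05, not vanishing p, for separated scores.

Signature genes: |loading| > 0.6 on at least one significant
(p < 0.05) PC, direction taken from the DEG table. The common signature
is the direction-consistent intersection of the per-disease signatures;
direction conflicts are excluded and reported.

## Mutual exclusivity

Binarization: disease sample s is altered for gene g iff its expression
deviates from the healthy-control mean by more than k_sd (default 2)
control SDs *in the gene's differential direction* — the simplest
direction-aware rule consistent with calling alterations "upregulated or
downregulated". Genes with near-zero control SD are excluded with a
flag. Alterations are computed over disease samples only; the healthy
controls define the baseline.

The exact test conditions on each gene's margin: with placements of the
altered samples uniform at random, φ is the probability of at most the
observed number of co-altered samples. For pairs this is the
hypergeometric lower tail of the overlap; for triples it is computed by
exact enumeration over the 2³ contingency cells (co-altered = altered in
≥ 2 genes). φ is monotone in the observed overlap and equals 1 at
complete overlap; the implementation is checked against exhaustive
placement enumeration to 1e-12.

MCMC: a state is t disjoint modules of k genes (defaults t = 2, k = 2,
the configuration used for marginal-probability modelling); a move swaps
a uniformly chosen in-module gene with a uniformly chosen outside gene
and is accepted by Metropolis with stationary weight
exp(Σ_modules −log φ). 100,000 iterations, 10,000 burn-in, thinning 10,
fully seeded; φ values are cached per gene set. The marginal probability
of a gene pair is the fraction of retained states in which it shares a
module; edges ≥ δ = 0.2 are kept and maximal cliques (via networkx) are
reported as consensus modules annotated with φ, union coverage and
per-gene exclusive-alteration counts. Coverage fractions are reported
exactly (altered samples / disease samples). On a planted disjoint pair
with coverage 0.5 each among 20 noise genes the planted pair attains the
top marginal probability (> 0.2) in ≥ 19 of 20 seeded runs; chains can
dwell long on the best-by-chance pairs in null data, so marginal
probabilities on signal-free inputs should be read as relative, not
calibrated, quantities.

## Pipeline

Comparisons run independently (pooled disorder vs healthy, IPF vs
healthy, NSCLC vs healthy) on the merged matrix; the mutex stage
consumes the common signature genes with per-disease alteration
matrices. A branch that produces an empty DEG or weight-filtered set
halts with a structured warning instead of failing; the CLI `run`
command distinguishes "completed with empty findings" (exit 3) from
crashes. The report JSON contains no timestamps and is byte-identical
across runs of the same configuration and seed. External validation
reuses the frozen training model; validation-cohort genes missing from
the model's gene set are imputed at the training means (zero after
standardization) and listed in the output.

## Problem sizes

Default experiment sizes — 1000 genes, the 17/6 + 46/45 cohort shapes,
100,000 MCMC iterations, 20-replicate property experiments, exhaustive
exact-test grids up to n = 20 samples — were chosen so the full test
suite and the acceptance script each complete in well under a minute of
compute on a single core while keeping every planted-signal margin
(power, recovery, calibration CIs) comfortably wide.

## Known limitations

* The merge's offset identification relies on a phenotype shared across
  studies; designs without any shared group fall back to all-sample
  anchoring and will confound composition with batch.
* Weight coefficients from an RBF dual are a heuristic signal readout;
  their scale depends on cohort size and C, so the 1.0 threshold is a
  convention, not a calibrated quantity.
* The probit Wald p cannot distinguish "strongly separated" from
  "moderately separated" scores (see above); ranking PCs by p under
  strong signal is not meaningful beyond the 0.05 cut.
* Exact exclusivity enumeration is implemented for module sizes 2 and 3;
  larger cliques are annotated with their worst pairwise φ.
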
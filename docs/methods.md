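# Methods

## Scope and data model

`crossclock` implements the statistical machinery of cross-species DNA
methylation aging studies on conserved-probe arrays: elastic-net age clocks
with age transforms and leave-one-sample-out evaluation, per-stratum EWAS of
age with Stouffer meta-analysis, annotation-level enrichment statistics, and
sample-integrity QC.  The raw consortium data such studies use are not
publicly deposited, so the package ships a synthetic-data generator whose
generative truth is known; every pipeline stage is validated against that
truth at desk scale.

All analyses operate on three tables: a beta-value matrix (probes × samples,
values in [0, 1], missing cells allowed), a sample sheet (species, tissue,
sex, age in years) joined with per-species lifespan constants
(max lifespan, age at sexual maturity), and a per-probe annotation
(coordinates, per-species mappability, CpG-island flag, TSS category,
chromatin state, PRC2 binding, adjacent gene).  Coordinates are 1-based in
TSV; BED export converts to 0-based half-open.  Any statistic computed on a
probe uses pairwise-complete samples and records the n actually used.

## Age transforms

Two transforms align species with very different lifespans:

* **Relative age** `g(a) = a / L`, with `L` the species' maximum lifespan
  from the anAge database (4.2 y for *Monodelphis domestica*, 122.5 y for
  human — a 29-fold ratio).  Values above 1 (an animal outliving the
  recorded maximum) pass through unclamped with a warning; clamping would
  bias median-error metrics.
* **Log-linear age**: `y = log((a + k)/(m + k))` for `a < m`, else
  `(a − m)/(m + k)`, with `m` the species' age at sexual maturity and
  `k = 1.0` year by default.  The form is the standard piecewise choice —
  logarithmic through the fast developmental epoch, linear afterwards,
  continuous and differentiable at the knot, and exactly invertible (the
  inverse is floored at age 0).  Both `m` and `k` are configurable.

## Elastic-net clocks

A clock is a penalized linear model of transformed age on beta values.
The mixing parameter is fixed at α = 0.5 and never tuned.  Fitting mirrors
cv.glmnet semantics:

* predictors are standardized to unit variance internally (population SD);
  coefficients are reported back on the beta scale;
* the λ grid has 100 log-spaced values from λ_max (the smallest λ with an
  all-zero solution) down to λ_max·10⁻⁴ when n > p and λ_max·10⁻² when
  n ≤ p, glmnet's own `lambda.min.ratio` convention;
* λ is chosen by internal ten-fold CV with seeded uniform fold shuffling
  (folds are contiguous blocks of the shuffled order, re-drawn inside every
  LOOCV iteration).  The default selection rule is the **one-standard-error
  rule** (largest λ within one SE of the CV-error minimum); the CV minimum
  is available via `lambda_rule="min"`.  The 1-SE default was chosen because
  the CV-minimum rule chases chance dips in the CV curve on null data,
  yielding small spurious models whose LOOCV predictions are dominated by an
  anti-correlated training-mean artifact (below); the 1-SE rule collapses
  null fits to the intercept-only model while leaving strong-signal fits
  essentially unchanged.  Exact CV-error ties resolve toward the larger λ.
* probes with any missing training value are dropped from that fit (leak-
  proof and simpler than imputation); a missing beta at prediction time
  flags the sample rather than raising.

The coordinate-descent solver is capped at 250 iterations per λ; the
affected (dense, small-λ) path segment is never selected by CV, and an
independent cross-check against R glmnet at a fixed interior λ agrees in
support and weights to ~0.5% of the largest coefficient.

**LOOCV.**  Each sample is predicted by a full refit — internal λ search
included — on the remaining n − 1 samples; nothing from the held-out sample
enters fitting.  Accuracy is reported as the Pearson correlation R between
predicted and actual age and the median absolute error in the target's
units.

**Degenerate-fit rule.**  An iteration whose selected model kept zero probes
predicts the back-transformed training mean.  Across LOOCV iterations that
prediction varies only through the one excluded target value and is
therefore perfectly *anti*-correlated with the held-out age — an artifact,
not information.  Such iterations are excluded from the correlation, and if
fewer than half the iterations are informative the whole evaluation is
flagged degenerate with r reported as 0.  Zero-variance predictions in a
plain evaluation are likewise reported as r = 0 with a flag, never an
exception mid-pipeline.

**Dual-species clocks.**  Samples of several species are pooled on the
intersection of their mappable probes; the target is either log-linear
chronological age (species-specific `m`) or relative age.  A single-species
input reduces exactly to the single-species fit.

## EWAS and meta-analysis

Within one stratum (one species × tissue), every probe is screened by
pairwise-complete Pearson correlation with age.  The p-value is Student's t
with n − 2 df (`t = r√(n−2)/√(1−r²)`), matching the classic numeric-trait
screen; the Fisher z statistic `atanh(r)·√(n−3)` (r clipped at 1 − 10⁻¹²)
is carried as the effect-size scale.  Probes with n < 4 or zero variance
are invalid (r = 0, p = 1) and excluded from downstream selections.
BH-FDR and Bonferroni columns are always emitted alongside nominal p.

Strata combine by Stouffer's method, `z_meta = Σwᵢzᵢ/√(Σwᵢ²)` with default
weights `√nᵢ` (per probe, n as actually used); probes invalid in some strata
renormalize over the contributing strata.  Top-CpG selection takes up to k
(default 500) probes per direction among those with p below the configured
threshold (10⁻⁴ for within-species full-lifespan runs, 0.005 for
conserved-probe cross-species runs), ordered by ascending p, ties by
descending |z| then probe id.  Cross-stratum agreement is summarized by
exact Venn-region counts (2–4 sets), by sector classification of the
(z_x, z_y) plane using two-sided normal quantiles (strict default 10⁻⁴,
lenient 0.05), and by the Pearson correlation of paired z scores.

## Enrichment statistics

The background for every enrichment is the stratum's mappable-probe
universe, which conditions out the array's design bias.

* **Island z-shift**: pooled-variance two-sample t of Fisher z, island vs
  non-island probes.
* **Category enrichment** (TSS class, island flag, PRC2 flag): two-sided
  Fisher exact test per category — two-sided p defined as the
  hypergeometric sum over tables no more probable than the observed one —
  with the sample (cross-product) odds ratio (∞/0/NaN conventions for zero
  cells) and figure-style significance stars at 0.05/0.01/0.001/0.0001.
* **Chromatin states**: one-sided hypergeometric enrichment tail
  P(X ≥ k); the depletion tail is also available.
* **Gene sets**: probes map to their single annotated gene;
  hypergeometric enrichment over the background's gene universe, with sets
  filtered to 10–3000 genes.  This deliberately replaces a genomic-regions
  regulatory-domain analysis with a flat per-gene test — a documented
  fidelity gap, adequate for array-conditioned backgrounds.
* **Multiplicity**: step-up Benjamini–Hochberg (monotone) and
  `min(1, m·p)` Bonferroni, order-preserving.

## QC

Unsupervised clustering uses 1 − Pearson correlation between sample
profiles with average linkage, cut at k = number of distinct labels, and is
summarized by purity.  The random-forest OOB check grows 500 unrestricted
trees with √p features per split; the OOB error is the misclassification
rate of majority votes over trees whose bootstrap missed the sample.  Both
are deterministic given the seed.  Note that on balanced random labels the
OOB vote is slightly pessimistic (each vote excludes its own sample), an
O(1/n) effect visible at small n.

## Synthetic data generator

For sample *i* (species *s*, tissue *t*, age drawn uniform on
[0, lifespan]) and probe *j*:

    μ_ij = expit(b0_j(s, t) + s_j · g(age_i) · 1[j acts in s]),
    beta_ij ~ Beta(μ_ij φ, (1 − μ_ij) φ)

* Baselines `b0` are Normal(0, σ = 1.0) independently per probe and
  species × tissue, which produces the species/tissue clustering real data
  show.
* A fraction `frac_age_related` (default 0.2) of probes get a nonzero slope
  on the logit scale, magnitude uniform in `slope_range` (default [1, 3]),
  sign Rademacher(½).
* **Partial cross-species sharing**: only `frac_shared_age` (default 0.5)
  of the age-related probes carry their slope in every species; the rest
  act in a single species.  Real conserved-probe studies find weak
  cross-species concordance of aging effects, and the relative-age clock's
  advantage over the chronological clock exists precisely because shared
  probes fit both species in relative age but suffer a species slope
  mismatch in (transformed) calendar age.  With exact sharing the two
  clocks extract the same latent signal and their within-species R is
  indistinguishable.
* **Aging modes**: `placental_like` forces positive slopes on age-related
  island∧PRC2 probes (islands gain methylation with age);
  `opossum_like` excludes island∧PRC2 probes from the age-related pool
  entirely (their slope is exactly 0) and draws the pool from the
  remaining probes.
* Noise precision φ defaults to 50 (beta SD ≈ 0.07 at μ = 0.5); all draws
  come from one seeded generator in a fixed order, so identical configs and
  seeds are bit-identical across platforms.

The generator does **not** model batch/chip effects, cell-composition
heterogeneity, probe-level sequence artifacts, SNPs under probes, or
nonlinear (e.g., saturating) age trajectories.  Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to those real-data complications.

## Validation studies (problem sizes)

The `validation` module fixes the desk-scale study conditions used by the
test suite and the reproduction script:

* **Clock recovery**: one species, two tissues, n = 80, 2000 probes, 10%
  age-related → LOOCV R ≳ 0.95.
* **Permuted-age null**: n = 60, 120 probes, single stratum; ages permuted
  per run; the per-run LOOCV r distribution is centered at 0 (the
  degenerate-fit rule reports intercept-only runs as 0).
* **Dual-species contrast**: lifespans 4.2 vs 122.5 y, 12 vs 36 samples
  (the short-lived species is the minority, as in the real design),
  600 conserved probes, 10% age-related, 20% shared, φ = 25.  The
  relative-age clock's short-lived-species LOOCV R beats the log-linear
  chronological clock's essentially always; typical values ≈ 0.9 vs 0.75.
* **Aging modes**: n = 50, 4000 probes, 20% age-related; placental-like
  gives a strongly positive island z-shift and PRC2 enrichment among the
  top gaining CpGs; opossum-like gives neither.
* **Null calibration**: 2000 probes for the p < 0.005 level and 5 pooled
  10⁵-probe screens for p < 10⁻⁴; observed fractions sit inside a
  three-sigma binomial band (chosen so a deterministic fixed-seed run has a
  per-mille false-alarm rate) and the p distribution passes a KS
  uniformity check.

## Numerical conventions

Beta bound check tolerance 1e-9 (float round-trip); numeric TSV round-trip
exact to 1e-12 (shortest-round-trip float formatting); r clipped at
1 − 1e-12 before atanh; degenerate variances reported as flagged zeros; p
floored at the smallest positive double and capped at 1.  Every stochastic
routine takes an explicit integer seed, and derived seeds stay below 2³¹.

## Known limitations

* The log-linear transform's exact published constants are not in the
  available text; the piecewise form and `k = 1` default here are this
  package's documented choice.
* Whether published clocks used λ-min or λ-1SE, and whether folds were
  stratified, is unstated; the defaults above are documented choices.
* The GREAT-style regulatory-domain and binomial-over-regions tests are not
  reimplemented; gene mapping uses the single annotated gene per probe.
* Headline numbers from the real study (clock R values, EWAS counts) are
  not reproducible without the consortium data; the validation studies
  establish the qualitative contrasts and the exactness of the statistics
  instead.
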
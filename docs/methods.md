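# Methods

`raygrowth` implements the standard age-and-growth workflow for batoids aged
from vertebral band pairs: reading-precision statistics, band-deposition
periodicity, back-calculation of size-at-age, Bayesian multi-model growth
fitting with sex contrasts, theoretical longevity, and cross-species
comparison. This note records the models, the defaults and why, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Ageing precision

Band counts are repeated in R ≥ 2 blind sessions. For fish *j* with reads
*x₁ⱼ…x_Rⱼ* and mean *x̄ⱼ*:

- APE (Beamish–Fournier): mean over fish of (1/R)·Σᵢ |xᵢⱼ − x̄ⱼ| / x̄ⱼ, ×100.
- CV (Chang): mean over fish of sdⱼ/x̄ⱼ, ×100. For R = 2, CV = √2·APE
  algebraically; the test suite asserts this to machine precision.
- Fish whose reads are all zero have an undefined relative error; they are
  excluded from the APE/CV denominators but kept in the agreement metrics.
- The age-bias table treats the second reading as the reference: per
  reference age, the mean first-session read, a 95% t-interval, and a
  two-sided one-sample t-test against the reference value. Cells with n = 1
  or zero variance carry no test and say why.
- Disagreements between the first two reads are adjudicated by an optional
  third read: accepted if it matches either of the first two, otherwise the
  fish is dropped from age analyses.

## Band-deposition periodicity

The monthly proportion of opaque vertebral edges carries the seasonal
deposition signal. Months map to mid-month angles θ_m = 2π(m − 0.5)/12.
Three hypotheses are fitted to the monthly (trials, opaque) counts by
maximum Bernoulli likelihood:

- no cycle: constant opaque probability p (1 parameter);
- annual cycle: π(m) = A·exp(κ(cos(θ_m − μ) − 1)) — a von Mises density
  normalized by its peak so that the probability at the peak month is
  exactly the amplitude A ∈ (0, 1] (3 parameters);
- biannual cycle: a two-component von Mises mixture with shared κ and free
  mixing weight w, again peak-normalized (5 parameters; μ₁ < μ₂ enforced to
  break label switching).

Peak normalization was chosen over other link functions because it keeps
π ∈ [0, A] ⊆ [0, 1] and preserves the two interpretable features used in
practice: the timing of the deposition peak and the seasonal contrast.
The hypotheses are nested (κ → 0 flattens the annual model; w → 1 collapses
the biannual one), so maximized log-likelihoods are ordered; each fitter
includes the embedded simpler solution among its start points, which makes
the ordering hold by construction rather than by optimizer luck.
Optimization is bounded L-BFGS-B from twelve monthly μ starts (peak-month
pairs for the mixture); κ is bounded at 50 (far sharper than monthly
resolution can support), and π is clamped away from {0, 1} by 1e−9 only
inside the logarithm. Model choice uses AIC with Akaike weights.

A caveat the simulation tests make visible: because the biannual model nests
the annual one with two extra parameters, AIC selects it spuriously whenever
it gains more than 2 log-likelihood units, which on 12 monthly bins happens
in roughly 10–20% of tables generated under a pure annual cycle. The peak
*location* is far more robust: across the same tables the fitted μ lands
within one month of the true deposition peak essentially always. Marginal
increment analysis is deliberately out of scope.

## DW–VR proportionality and back-calculation

Disc width is regressed on vertebral radius by OLS: DW = a + b·VR. Whether
the sexes share one line is tested by ANCOVA as two nested F-tests — the
sex×VR interaction against a common slope, then the sex intercept against a
single line — and the pipeline pools the sexes automatically when both
p-values exceed α (default 0.05, configurable; a config switch can force
per-sex regressions). If one sex is absent, pooling is forced with a
warning.

Size-at-age is reconstructed under Francis's body-proportional hypothesis:

    DW_t = DW_c · (a + b·VR_t) / (a + b·VR_c)

one value per band including the birthmark (age 0). At the capture edge the
reconstruction returns the capture size identically, and the procedure is
scale-equivariant in DW. Fish for which a + b·VR_c ≤ 0 have an undefined
ratio and are skipped with a log entry. Other back-calculation conventions
(scale-proportional, Dahl-Lea) are not implemented.

## Growth models and Bayesian estimation

Four families, all in disc width (mm) against age (years):

| family   | DW(t)                              | parameters |
|----------|------------------------------------|------------|
| vbgm3    | DW∞(1 − e^{−k(t−t₀)})              | DW∞, k, t₀ |
| vbgm2    | DW∞ − (DW∞ − DW₀)e^{−kt}           | DW∞, k (DW₀ fixed) |
| gompertz | DW∞·e^{−e^{−k(t−t₀)}}              | DW∞, k, t₀ |
| logistic | DW∞ / (1 + e^{−k(t−t₀)})           | DW∞, k, t₀ |

vbgm2's anchoring constant DW₀ defaults to the mean observed size at age < 1
in the input (configurable). The observations are the back-calculated
(age, DW) pairs, one per band reading, with i.i.d. Normal(0, σ) residuals.
Treating longitudinal within-fish readings as independent overstates the
effective sample size; this pseudo-replication is inherited from standard
practice and documented rather than corrected.

Priors are weakly informative and truncated to the admissible region:
DW∞ ~ Normal(0, 700) on DW∞ ≥ 0; k ~ Normal(0, 1) on k ≥ 0; t₀ ~ Normal(0, 8)
untruncated (t₀ may be negative); σ ~ Student-t(3, 0, 40) on σ ≥ 0. Scales
are mm for DW∞ and σ, per-year for k.

Sampling uses emcee's affine-invariant ensemble. Each of `n_chains`
(default 4) independent ensembles contributes `n_samples` (default 3000)
retained draws — walker draws flattened after `n_warmup` (default 1000)
discarded steps and thinning by 3 to decorrelate — for 12,000 retained
draws. Walkers start in a tight ball around the nonlinear least-squares
solution (prior-scale dispersion when no data are supplied, which makes a
prior-only run reproduce the truncated priors, a property the tests check).
Convergence is diagnosed per parameter with split R-hat (< 1.10) and
effective sample size (> 400); the result carries a `converged` flag and is
never silently passed. Note the ESS bar is absolute, so short exploratory
runs can be flagged unconverged even when well mixed.

Model comparison uses AIC = 2p − 2·log L evaluated at posterior means
(p counts free parameters including σ), with WAIC reported alongside as a
fully Bayesian diagnostic; comparisons are refused across different
datasets. Sex differences are assessed per parameter on the posterior of
θ_F − θ_M (pooled draws paired by a seeded shuffle; the fits are
independent, so pairing order is immaterial beyond reproducibility), with
an equal-tailed 90% credible interval; the contrast is significant when the
interval excludes zero.

## Longevity and comparative layer

Theoretical longevity follows Ricker: the age at 95% of DW∞, 5·ln 2 / k,
with k from the logistic fit, compared against the observed maximum age per
sex. The comparative layer ships a transcription of published dasyatid
growth parameters (20 parameter sets across 8 species); two Aegean Sea rows
carry an exclusion flag for biologically unrealistic k and DW₀ and are
excluded by default. Over the remaining 18 rows the package computes the
Spearman correlation (average ranks for ties; t-approximation p-values,
exact permutation available for n ≤ 8) between k and DW∞, a least-squares
quadratic of DW∞ on k, and the size-at-birth fraction DW₀/DW∞ against DW∞
(Spearman plus a least-squares line). Because the exact published point set
is not stated, `row_set_sensitivity` reports both correlations under the
alternative conventions (flagged rows included, pooled-sex duplicates
dropped, every leave-one-out subset). Under the default convention the
k–DW∞ correlation and both regression formulas reproduce the published
values; the fraction–DW∞ correlation sits at −0.74 against a published
−0.75, which is within the spread the sensitivity report shows across
conventions. No meta-analytic weighting or phylogenetic correction is
attempted.

## Synthetic-data generator

The generator provides populations with known truth so every stage is
testable. What it emulates, with defaults:

- 272 fish, ~3:1 male-biased, sexes growing on dimorphic logistic curves
  (males 401.70 mm, 0.45 y⁻¹, −0.36; females 512.22 mm, 0.29 y⁻¹, 0.82);
- integer ages uniform on 0–11 by default (configurable weights — observed
  age structures are gear-biased, so no empirical distribution is baked in);
- continuous growth between band-deposition events: capture age is the
  integer age plus (capture month − deposition month mod 12)/12;
- capture DW = curve + Normal(0, 20 mm), resampled until the fish is at
  least as large as its size at the last completed band — a no-shrinkage
  truncation that keeps every band radius inside the centrum;
- a shared DW–VR line with a = 30 mm, b = 90 mm/mm and 0.1 mm VR scatter.
  The coefficients are not published for this system; these values put VR
  at a realistic 1.5–6 mm over the observed 150–580 mm size range;
- band radii placed so that body-proportional back-calculation with the
  *true* line returns the *true* size-at-age exactly — downstream error
  then reflects regression and measurement noise only;
- opaque edges drawn Bernoulli with the annual-cycle link (peak mid-
  December, κ = 2, amplitude 0.9); age-0 fish are birthmark-only;
- a second reading session equal to the true count with probability 0.875,
  otherwise ±1 year (floored at zero);
- optional gillnet-like retention exp(−(DW − 375)²/(2·75²)), on by default,
  with rejected fish resampled to the target n;
- monthly sampling May 2022 – April 2024.

Each random stage draws from its own labelled substream of the single seed,
so adding a stage never shifts another stage's draws, and a fixed seed
reproduces the dataset exactly.

What it does not emulate: spatial structure, gear-specific fleets,
capture-induced premature parturition (the smallest sizes come from the
curve), correlated within-fish reading errors, and real radius-measurement
digitization error. Passing recovery tests therefore demonstrate that the
estimators invert the generative assumptions they state — not that those
assumptions hold in any particular field dataset.

## Problem sizes used in the checks

The recovery studies run at: 200 monthly edge tables (n = 30/month) for
hypothesis selection plus 50 flat tables; one full-length fit (12,000
draws) for parameter recovery at n = 200; 20 replicates (reduced run
lengths: 2 ensembles, 1,200 draws) for sex-contrast power at n = 200/sex;
and 50 replicates × 4 families for model recovery at n = 272 fish through
the full regression → back-calculation → fitting path. Reduced run lengths
change only the number of draws, never the priors or the model.
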
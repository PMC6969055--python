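# Methods

## Model

The estimator works on per-variant summary associations
(β̂_Xj, se(β̂_Xj)) with the exposure and (β̂_Yj, se(β̂_Yj)) with the
outcome, assumed estimated in non-overlapping samples (two-sample setting)
with linear, homogeneous effects. The variant-specific causal estimate is
the Wald ratio θ̂_j = β̂_Yj/β̂_Xj. For instruments strongly associated with
the exposure, θ̂_j is approximately normal.

Given a causal effect θ and validity indicators ζ_j ∈ {0, 1}, the
likelihood is a product over variants of two-component mixtures:

- valid (ζ_j = 1): θ̂_j ~ N(θ, se(θ̂_j)²),
- invalid (ζ_j = 0): θ̂_j ~ N(0, ψ² + se(θ̂_j)²),

i.e. invalid estimands are taken symmetric about the origin with spread ψ;
no attempt is made to model their actual distribution. Standard errors are
treated as fixed and known. Direct maximisation over ζ is exponential in J,
but at fixed θ the optimal ζ is componentwise (take the larger
contribution), giving a profile log-likelihood computable in O(J) per grid
point. The point estimate θ̂ is the grid argmax; the level-(1−α) confidence
set is {θ : 2[log L(θ̂) − log L(θ)] ≤ max(1, φ̂²)·χ²₁,₁₋α}, which may be a
union of disjoint intervals. φ̂ is the residual standard error of the
zero-intercept weighted regression of β̂_Y on β̂_X (weights se(β̂_Y)⁻²)
over the variants flagged valid at θ̂, floored at 1; it inflates the
confidence set when the "valid" estimates are more variable than their
standard errors predict, but never moves the point estimate or the validity
calls.

Identification rests on the plurality-valid assumption: among groups of
variants sharing an asymptotic causal estimate, the largest is the valid
group. When several sizeable groups exist, the likelihood is multimodal and
the confidence set splits — reported as `modes` and multiple `ci_ranges`.

## Parameters and defaults

- **ψ (invalid-estimand SD, causal-effect units).** No universal default
  exists; `psi="auto"` uses 1.5 × the sample SD of the ratio estimates,
  motivated by the observed spread bounding the invalid estimands' spread
  (inflated because valid estimates cluster). Both the estimate and the
  number of detected modes can be ψ-sensitive, so the CLI logs a reminder
  and offers `--psi-sweep`; simulation studies fix ψ = 1 to avoid extreme
  heuristic values in unlucky replicates. Variants are less likely to be
  called invalid when ψ is very large *or* very small, in opposite regimes:
  as ψ → ∞ the invalid density is flat and everything is valid near the
  maximum (the estimate collapses to fixed-effect IVW); as ψ → 0 invalidity
  only fits estimates near zero.
- **Grid.** Default: the union of the per-variant plausible ranges
  [θ̂_j − 3 se_j, θ̂_j + 3 se_j] over the *precision core* — variants with
  se(θ̂_j) ≤ 10 × the median se(θ̂_j) — at 5001 points. Variants with
  near-null exposure associations have enormous ratio-estimate SEs; they are
  essentially uninformative (their valid and invalid densities are almost
  identical everywhere) and cannot host a dominant likelihood peak, but
  letting them stretch the grid collapses the resolution where the
  likelihood mass sits and visibly mis-calibrates the method, so they do
  not enter the range. Confidence-set endpoints are only resolved to the
  grid step (reported in `summary()`); coverage/rejection of a specific
  value is evaluated by recomputing the profile likelihood-ratio exactly at
  that value, so it is not grid-quantised. A user-supplied grid is used
  as-is; if it misses the core range a warning flags that the maximum may
  sit at a boundary.
- **α = 0.05** for 95% confidence sets (χ²₁ cutoff 3.84).
- **se_order.** First-order ratio SEs by default: exposure uncertainty is
  negligible for genome-wide-significant instruments, and propagating it
  naively correlates instrument strength with the SE. Second-order
  delta-method SEs (always ≥ first-order) are available.
- **Mode rule.** A local maximum counts as a mode when its topographic
  prominence exceeds half the confidence cutoff, so modes correspond exactly
  to potential disjoint confidence-set components; the global argmax always
  qualifies.

## Tie-breaks and degenerate inputs

- L_V = L_F ties classify as valid (deterministic; ties are measure-zero).
- Exact argmax ties across grid points resolve to the θ with more
  valid-flagged variants, then the smaller |θ| (better-supported, more
  conservative).
- β̂_Xj = 0 (ratio undefined) and non-positive SEs are rejected with the
  offending variant named. Zero spread of the ratio estimates makes the ψ
  heuristic degenerate → ψ must be supplied.
- Fewer than 3 valid-flagged variants leave no residual degrees of freedom
  for φ̂: it is set to 1 with a warning. Random-effects IVW with < 3
  variants falls back to fixed-effect with a warning.
- Weak instruments can be flagged via an optional F threshold but are never
  dropped automatically.

## Simulation engine

`SimScenario` generates individual-level data

    U = Σ κ_j G_j + ε_U,  X = Σ γ_j G_j + δ_X U + ε_X,
    Y = Σ α_j G_j + θ X + δ_Y U + ε_Y,

with G_j ~ Binomial(2, 0.3), ε ~ N(0,1), γ_j ~ U(0.03, 0.1) (or normal),
and defaults J = 100 variants, two cohorts of 20,000. Invalid variants (a
seeded shuffle's first `n_invalid` indices) get α_j ~ U(−0.1, 0.1)
(balanced pleiotropy), α_j ~ U(0, 0.1) (directional), or κ_j ~ U(−0.1, 0.1)
with α_j = 0 (pleiotropy via the confounder, violating the InSIDE
assumption since instrument strength and pleiotropic effect then share κ_j).
Summary statistics are one-variant-at-a-time simple regressions with
intercept — the convention under which GWAS summary data are produced — X on
G in cohort 1, Y on G in cohort 2, with the usual unbiased residual-variance
estimator; the regressions are vectorised in numpy for speed. Under these
defaults the variants jointly explain ≈9.3% of exposure variance (plain R²
of the all-variant regression, averaged over datasets), a joint ANOVA
F ≈ 20.5.

Replicate r of a study uses `SeedSequence(base_seed, spawn_key=(r,))`, so
studies are reproducible and parallel-safe; identical configs and seeds give
byte-identical reports. A method failure in a replicate is logged and
counted, never fatal. Rejection of the null with a disjoint confidence set
is defined as zero lying outside *every* component (the set is the full
confidence region); coverage analogously.

What the generator emulates — and what it does not: independent bi-allelic
variants at a common allele frequency, homoscedastic normal noise, exact
two-sample separation, linear effects. Real data add linkage
disequilibrium, allele-frequency spectra, winner's curse in discovery
samples, sample overlap and binary-outcome non-collapsibility; passing the
simulation checks therefore validates the estimator's statistical machinery
under its own assumptions, not robustness to those artefacts.

## Posterior probabilities and trait ranking

At a reference effect θ, π₁j = π₀j L_V,j / (π₀j L_V,j + (1−π₀j) L_F,j),
computed on the log scale so extreme likelihood ratios stay in [0, 1], with
degenerate priors honoured exactly. The default prior π₀j = |β̂_Xj| weights
variants by instrument strength and presumes an exposure in SD units; values
above 1 are clipped with a warning (a documented choice — renormalisation
is not attempted). Trait ranking filters a long-format variant × trait
association table to traits with ≥ 6 variants (among the analysis variants)
associated at p < 10⁻⁵ — the same threshold for the filter and the scoring,
then ranks surviving traits by mean posterior of associated variants.
Missing variant–trait pairs count as non-associations; duplicate or
exposure-related traits are removed via the user's exclusion list, not
automatically. Ranking is invariant to input row order (stable sort,
alphabetical tie-break).

## Validation problem sizes

The test suite validates the profile likelihood against exhaustive 2^J
enumeration (200 random instances, J ≤ 10, agreement to 1e−10), the IVW
limit at ψ = 10⁶ × data scale, equivariance and continuity properties, and
the Monte-Carlo operating characteristics at 1000 replicates (null
calibration, power, coverage) and 500 replicates (pleiotropy robustness)
under the default study conditions — sizes chosen so the binomial
Monte-Carlo error at those counts is the deciding tolerance.
`scripts/acceptance.py` uses 1000 replicates per power/Type-1 study and 100
datasets for instrument strength.

## Known limitations

- Wilks-based confidence sets profile out one nuisance indicator per
  variant; asymptotics are not guaranteed as J → ∞, though no practical
  miscalibration appears at J in the hundreds.
- Confidence-set endpoints are grid-resolution limited.
- ψ is user-set; joint maximisation over (ψ, θ) is deliberately not offered
  — it tends to pick a ψ that sweeps dissimilar variants into the valid
  group and is less robust.
- Correlated (LD) variants, allele harmonisation across files, and
  multivariable extensions are out of scope; inputs are assumed harmonised
  and approximately independent.
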
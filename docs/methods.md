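# Methods notes

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Synthetic cohorts

`simulate.generate_cohort` draws families of MZ twins, DZ twins, non-twin
full-sibling pairs and singletons. The two focal outcome columns follow an
exact bivariate A/C/Tw/E structural model: per sibling,

```
trait1 = a11·A1 + c11·C1 + t11·T1 + e11·E1
trait2 = a21·A1 + a22·A2 + c21·C1 + c22·C2 + t21·T1 + t22·T2 + e21·E1 + e22·E2
```

with all latent factors standard normal. Cross-sibling latent correlations
implement the biology: A-factors correlate 1.0 (MZ) or 0.5 (DZ and full
siblings, the additive-genetic expectation without assortative mating);
C-factors are identical within a family; Tw-factors are identical within
MZ and DZ pairs and independent otherwise; E-factors are always
independent. Because factors have unit variance, the model-implied pair
covariance is exact polynomial algebra in the loadings, which is what makes
the simulator usable as an oracle for the likelihood code (and vice versa).

Two modelling choices deserve emphasis:

- **Tw for non-twins.** The twin-specific environment contributes
  within-person variance to *everyone* but covaries only within twin
  pairs. This keeps total trait variance equal across pair types, which is
  the conventional reading of a "twin-specific shared environment"; the
  alternative (no Tw variance at all for non-twins) would make non-twin
  variances structurally smaller.
- **Sibling age gaps** are drawn uniformly on (0.5, 4.5) years, so every
  simulated sibling pair passes the <5-year eligibility filter and
  configured pair counts equal realized pair counts. Families never exceed
  two modelled siblings; the pair-selection logic for larger sibships is
  exercised by hand-built fixtures in the tests instead.

Covariates are plain draws (age uniform over `age_range`, default 22–36;
sex Bernoulli(0.46); sex-dependent height/weight normals with BMI computed
as 703·w/h²; NIH-toolbox-style normed fitness scores N(100, 15); ICV
normal with a sex offset). Configured covariate effects add linearly to
the two focal outcomes. Extra outcome columns are equicorrelated standard
Gaussians for multiplicity testing. What the generator does **not**
emulate: missing data, measurement error structure, selection effects,
assortative mating, population stratification, or realistic marginal
distributions of brain measures. Passing recovery tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to real-data violations of it.

## Screening regressions

One Gaussian model per outcome, all covariates and all three fitness
predictors entered simultaneously and retained regardless of significance.
Age and the fitness predictors use restricted cubic splines with 3 knots at
the empirical 10th/50th/90th percentiles (linear-interpolation percentiles;
with 3 knots the expansion is the identity column plus one restricted cubic
term, Harrell's normalization by (t₃−t₁)²). Fewer than 10 distinct values
triggers a logged fallback to a linear term.

The compound-symmetry family covariance is implemented as a family random
intercept estimated by REML (statsmodels `MixedLM`), which is equivalent
whenever the within-family correlation is non-negative; negative
exchangeable correlations are out of scope. When every family has one
member the model collapses *exactly* to OLS and that path is taken
directly. Design columns are internally standardized before fitting
(intracranial volume in mm³ sits ten orders of magnitude above spline
cubic terms) and estimates are mapped back afterwards; the optimizer falls
back bfgs → powell → nm because the gradient path can hit singular
intermediate matrices on hard datasets.

Because a spline predictor has no single slope, each predictor reports
both (a) the coefficient of its linear column with SE and z and (b) a
joint Wald χ² over all of its spline columns mapped to a z-equivalent via
the upper-tail χ²→normal transform (computed in log space so thresholds
near z ≈ 4–6 do not underflow). Screening consumes the linear-term z by
default (`effect="linear"`), the joint z by option; the two orderings are
both reported in the output CSV so the choice is auditable.

Marginal prediction curves hold all other model terms at reference values
(continuous: median; categorical: mode) and carry pointwise delta-method
CIs from the fixed-effect covariance; grid points outside the observed
predictor range are flagged as extrapolation.

## Effective number of tests and thresholds

Default estimator (`eigen_variance`): with λ the M eigenvalues of the
domain's outcome correlation matrix,

```
m_eff = 1 + (M − 1) · (1 − Var(λ)/M),   Var with denominator M − 1.
```

It equals M for independent outcomes, 1 for perfectly redundant ones, and
is non-integer in between — consistent with fractional published effective
test counts. The `integer_partial` variant (Σ over eigenvalues of
I(λ≥1) + frac(λ)) is exposed as an option; its floor is evaluated after
rounding eigenvalues at 1e-9 to protect integer-adjacent spectra.
Correlations are computed on the **raw** outcome columns by default; a
residualized-outcome variant is a caller decision (pass a residualized
table), since the choice is not determined by the allocation rule itself.

The per-test level is `family_alpha / (n_domains · n_predictors · m_eff)`
(defaults 0.05, 4, 3) and the screening threshold its two-sided normal
quantile. With the four domain m_eff values 40.6 / 57.8 / 52.4 / 10.3 this
yields z thresholds 3.88 / 3.97 / 3.95 / 3.54; the first sits at a rounding
knife-edge (3.8846).

## Pair construction

Traits entering twin models are first residualized by OLS on age (3-knot
restricted cubic spline), sex, the age×sex interaction, race (reference
coded), and ordinal education and income — one model per trait over all
pair-eligible individuals, listwise deletion with logged counts. MZ/DZ
pairs are taken as recorded (twin order 1/2); non-twin full-sibling pairs
are formed within families subject to the <5-year age-gap filter. In
families offering several eligible pairs the smallest-gap pair is kept
(ties: older pair, then lexicographic IDs), one pair per family by
default — maximizing age comparability with twins — with an
`all_disjoint` option that keeps every disjoint pair greedily by ascending
gap. Within a pair, sibling 1 is the older (ties by ID); exchangeability
of the likelihood under relabeling is asserted in the tests.

## Twin-model likelihood and fitting

The FIML objective sums, over complete pair 4-vectors grouped by pair
type, the 4-variate Gaussian −2 log density with the model-implied
covariance (within-person block ΣΛΛᵀ over sources; cross-sibling block
with genetic coefficient 1/0.5 and twin-environment coefficient 1/0 as
above). Two implementation layers exist on purpose:

- a reference implementation on the explicit 4×4 covariance
  (`fiml_minus2ll`), tested against per-observation brute-force densities;
- a fast path used by the optimizer that exploits the exchangeable block
  structure [[W, B], [B, W]]: the sibling sum/difference transform
  block-diagonalizes every group covariance into W+B and W−B, so one
  likelihood evaluation is a handful of 2×2 determinants on pre-transformed
  sufficient statistics (count, mean, scatter). The two paths agree to
  1e-10 relative in the tests; the speedup is what makes 200-replicate
  model-comparison studies affordable on one CPU.

Optimization: method-of-moments starting values (genetic covariance
initialized from twice the MZ-minus-sibling cross-covariance contrast,
PSD-projected; small shares for C/Tw; E as the remainder), plus seeded
perturbed restarts (default 5 starts), each polished by Nelder–Mead then
BFGS. Diagonal loadings are left unconstrained during search — the
likelihood depends only on ΛΛᵀ — and folded to the canonical non-negative
representative afterwards (flipping a latent factor's sign negates one
loading column and leaves the fit invariant). Means default to per-trait
constants shared across siblings and zygosity (phenotypes arrive
residualized; freeing or fixing them is a caller option). A fit is marked
converged when the max |gradient| of −2LL is below 1e-2 — deliberately
loose because boundary solutions (a loading at 0) have one-sided
curvature. Parameter covariance is 2·H⁻¹ from a central-difference Hessian
of −2LL; if that matrix is singular (typical exactly at a boundary), SEs
are reported unavailable rather than fabricated.

Assumption tests fit (i) a saturated model per pair type (closed-form
MLE), (ii) a sibling-exchangeable model per type — its MLE is also closed
form, the swap-symmetrized mean and covariance, because the exchangeable
family is invariant under the sib-swap permutation — and (iii) a model
additionally equating means, variances and the within-person covariance
across zygosity groups while leaving cross-sibling covariances free (those
differ by zygosity under any genetic model); step (iii) is a 14-parameter
numerical MLE. Likelihood-ratio χ² tests compare successive steps (free
parameters 42 / 24 / 14 with three groups). `compare_models` applies the
same LRT to structural reductions (e.g. ACTwE → AE, Δdf = 6) and flags
that dropping variance sources puts parameters on the zero boundary, where
the naive χ² p-value is conservative; no mixture correction is applied.

Standardization divides each loading by the model-implied SD of its target
trait, with delta-method CIs (profile likelihood was considered and left
out: at these sample sizes the Wald intervals on standardized paths are
the quantity usually reported, and the delta Jacobian is cheap and exact
to first order). The decomposition reports, per source, variance shares
(a11²/Var₁; (a21²+a22²)/Var₂) and correlation components
(a11·a21/(sd₁·sd₂)), which sum to 1 per trait and to the model-implied
phenotypic correlation exactly — algebraic identities asserted at 1e-10.

## Pipeline

`pipeline.run` wires the stages: simulate or load → per-domain thresholds
→ clustered regressions → screening (|z| above the domain threshold,
sorted by |z|, deterministic name tie-breaks) → for each surviving
(outcome, predictor): residualize, pair, fit the configured model sequence
(default ACTwE then AE), assumption tests, comparison, standardized paths,
decomposition. Per-outcome failures are logged, recorded in the manifest
and skipped. The manifest stores the config hash, seed, package versions
and timings; identical config+seed reruns produce byte-identical tables.
The screening→twin handoff is automatic unless `twin_force` names explicit
(outcome, predictor) pairs.

## Validation study sizes

The suite's stochastic studies use sizes chosen to make Monte-Carlo error
small relative to the asserted tolerances while keeping a full run on one
CPU in minutes: simulator-vs-model covariance checks at 1e5 pairs per
type; standardized-loading recovery over 50 replicates of 500 pairs per
type; the ACTwE→AE reduction study over 200 replicates at 134/72/290
pairs; assumption-test null calibration over 120 replicates at 80 pairs
per group (step-(ii) and (iii) p-values tested for uniformity by KS);
family-wise error calibration over 500 global-null replicates of 400
individuals with domain sizes 48/68/68/14 and within-domain equicorrelation
0.3. The error-calibration study screens with vectorized OLS z statistics
on unrelated individuals — under a global null with no family structure
the clustered model reduces to OLS, and this keeps half a million
regressions affordable; the mixed-model path is validated separately.

## Known limitations

- Bivariate models only; no trivariate+ Cholesky, sex-limitation,
  dominance, or GxE moderation.
- Exchangeable family correlation is constrained non-negative (random
  intercept parameterization).
- Boundary LRT p-values are conservative, not mixture-corrected.
- The synthetic covariate generator targets recoverability, not realism;
  effect sizes estimated on it say nothing about real cohorts.
- Missing data are handled by listwise deletion (regression) and
  complete-pair analysis (twin models); no FIML over partial pairs.
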
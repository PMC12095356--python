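# Methods

## The mixed model

Each trait is analysed separately (traits are typically recorded on
different replicate subsets of the trial, so a joint multi-trait model would
have to cope with unmatched designs; the univariate route sidesteps that).
The response is the per-experimental-unit average: within a year the mean of
the plants observed in the plot, then the mean over years, so years with
different plant counts carry equal weight. Units with no observation for a
trait are dropped for that trait only.

The model for the n analysed units is

    y = X b + Z u + e

with fixed effects `b` = intercept + resolvable-replicate effects
(first-level reference coding) and random effects
`u = (u_genotype, u_row(rep), u_col(rep))`, mutually independent,
`u_i ~ N(0, σ²_i I)`, `e ~ N(0, σ²_e I)`. Rows and columns are unordered
factor labels nested in their replicate; no spatial geometry is assumed.
Small models may drop the row/column (and replicate) terms through
`ModelSpec` flags; the genotype term always leads the random part.

### REML estimation

The restricted likelihood is evaluated through Henderson's mixed-model
equations. With variance ratios `γ_i = σ²_i/σ²_e`, `W = [X Z]`,
`M(γ) = W'W + blockdiag(0, γ_1⁻¹I, …)` and `S(γ) = y'y − (W'y)'M⁻¹(W'y)`,

    −2ℓ_R = (n−p)·(log 2π + 1 + log(S/(n−p))) + Σ_i q_i log γ_i + log|M|,

after profiling out `σ̂²_e = S/(n−p)`. `W'W` and `W'y` are assembled once,
so each evaluation costs one Cholesky factorization of a (p+q)×(p+q)
matrix. The gradient with respect to `log γ_i` is analytic
(`q_i − tr(M⁻¹)_ii/γ_i − (n−p)‖û_i‖²/(γ_i S)`), and optimization proceeds
in three stages: bounded L-BFGS-B from two starts (γ = 1 and γ = 0.1),
a Nelder–Mead polish, then Newton iteration on the analytic gradient.
The last stage matters: near the optimum the profiled likelihood is flat at
the level of floating-point noise, and function-value-based line searches
stall around 10⁻⁶ relative accuracy in the components, whereas driving the
gradient to zero reaches ~10⁻¹² (the balanced-ANOVA equivalence test relies
on this).

Numerical choices:

* log-ratio bounds ±30 (ratios from ~10⁻¹³ to 10¹³);
* a component below 10⁻¹⁰ × phenotypic variance is reported as 0 with a
  boundary flag; constant data short-circuit to the all-zero fit;
* component standard errors come from the central-difference Hessian of the
  unprofiled −2ℓ_R in the variance parametrization (`cov = 2H⁻¹`), computed
  over interior components only — boundary components get no SE;
* EBLUEs/EBLUPs/PEVs come from one Cholesky solve of the MME; a dense-V
  reference implementation (`eblup_direct_dense`) exists purely as a
  cross-check and agrees to ~10⁻¹⁴.

### Heritability, CV_G and the variance test

`C_gg = σ̂²_e (M⁻¹)_gg` is the prediction-error covariance of the genotypic
effects; `PEV_j` its diagonal. Generalized heritability is
`H² = Σ_j (1 − PEV_j/σ̂²_g)/t` with `t` the numerical rank of
`I − C_gg/σ̂²_g` (singular values above 10⁻⁸ of the largest). The rank
normalization makes the balanced genotype-only case exactly
`σ²_g/(σ²_g + σ²_e/r)` — the intercept consumes one dimension and the rank
accounts for it. When PEV = σ²_g for every clone the rank is 0 and H² is
defined as 0. `CV_G = 100·σ̂_g/mean` uses the raw arithmetic mean of the
analysed plot values (an adjusted mean would differ only through
imbalance, and the raw mean is transparent).

`H₀: σ²_g = 0` is tested by refitting without the genotype term and
referring `max(0, 2Δℓ_R)` to χ²₁ — a deliberately conservative convention
for a boundary hypothesis (the 50:50 mixture reference would halve the
p-value). Traits qualify for selection when `H² > 0.30` (configurable) and
the test is significant at α = 0.05.

## Correlations between traits

Pearson correlations of the genotypic EBLUP vectors (clones matched by
identifier), tested with the t approximation on n−2 degrees of freedom,
no shrinkage correction and no multiple-testing adjustment — the intent is
descriptive, to anticipate which constraints will bind in selection.
Strength classes on |r|: very weak < 0.40 ≤ weak < 0.60 ≤ moderate < 0.80 ≤
strong, intervals closed on the left (the boundary convention is ours; the
published class descriptions do not state inclusivity, and the reference
coefficients never land exactly on a boundary).

## Selection

Scaled gains `y_ki = ±EBLUP_ki/mean_k` are dimensionless and comparable
across traits; minimize-direction traits (pH, berry weight) are negated so
every reported gain is "positive = improving". Internally everything is in
scaled fractions; reported gains are ×100.

The binary program (objective = unweighted sum over the chosen objective
traits; constraints `Σ y_ki x_i ≥ R_k·s/100`; excluded clones capped at 0)
is solved by HiGHS branch-and-bound via `scipy.optimize.milp` with zero
optimality gap — instances are a few hundred binaries at most. HiGHS is
deterministic, so reruns reproduce the same optimum; when several optima
exist the reported group is one of them (alternative equally-good groups
are a genuine feature of the problem, and clone exclusion constraints are
the supported way to explore them). The enumeration oracle breaks ties by
lexicographic clone order instead, so tests compare objective values and
feasibility, not the particular subset.

`R_max_p` uses the closed form (mean of the top-s scaled values);
`R_max_a` maximizes one trait subject to non-negative sums for all other
traits of interest (default: all other traits in the matrix) and returns
NaN on infeasibility. The size sweep computes both bounds and the criteria
program for every size in the range; infeasibility is a first-class result
carried in the output, never an exception, so one infeasible size does not
stop the sweep. Feasibility tolerance on scaled sums is 10⁻⁹.

## Synthetic trials

The generator emulates exactly the structure the model assumes: independent
normal row/column/residual effects per trait, clone genotypic effects drawn
multivariate-normal across traits with a user correlation matrix (the only
inter-trait link), random allocation of clones to grid cells within each
replicate. Defaults — 100 clones, 4 replicates, 10×10 grid, two traits with
means 3.5 and 12.0, genetic SDs 0.7 and 0.55, row/column SD 0.2, residual
SD 0.45 — give CV_G near 20%/5% and H² around 0.85–0.9, i.e. a well-run
trial of a variable variety. What the generator does *not* emulate: spatial
trend beyond row/column blocks, genotype-by-year interaction, non-normal
traits, and designed (rather than random) row–column layouts. Passing tests
therefore certify the estimation and optimization machinery under the
model's own assumptions, not robustness to field realities outside them.

`generate_eblup_matrix` is a lighter fixture for the selection layer alone:
multivariate-normal clone×trait values centered so each column sums exactly
to zero, matching the sum-to-zero property of EBLUPs from models with an
intercept.

## Verification scales

The test suite and `scripts/acceptance.py` choose problem sizes so that
each property is measured with real power while the whole run stays
desk-sized: MILP-vs-enumeration on 200 random instances (n ≤ 16, p ≤ 4,
s ≤ 6, mixed and partly infeasible constraints); REML recovery on 200
simulated 100-clone × 4-replicate trials in the tests and 60 in the
acceptance script (mean estimates vs 3 Monte-Carlo SEs); the end-to-end
simulate→fit→select check on 100 replicates in the tests and 30 in the
script. The published reference tables in `polyclonal.datasets` supply the
worked CV_G cells and the 43 correlation coefficients whose strength-class
shares (45% very weak, 16% moderate, 6% strong among significant pairs) the
classifier reproduces.

## Known limitations

* Residual variance is homogeneous within a trait; no spatial correlation,
  no heterogeneous-variance or genotype-by-environment structures.
* The reduced-model refit for the variance test re-estimates row/column
  components; with very few levels the χ²₁ reference is conservative.
* Component SEs are asymptotic and unreliable near boundaries (reported as
  NaN on the boundary).
* The objective sums traits with equal weight by construction; differential
  importance is expressed through the minimum-gain constraints, not through
  weights.
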
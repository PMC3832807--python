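# Methods

## Model and likelihood

The sampling unit is an affected sib pair (ASP).  For relative pairs of
type *r* with prior IBD distribution f_r = (f_{r0}, f_{r1}, f_{r2}) —
(¼, ½, ¼) for full sibs — and marker-conditional distribution f̂_r, the
conditional-logistic model writes the pair likelihood ratio as
(Σᵢ λᵢ f̂_{ri}) / (Σᵢ λᵢ f_{ri}) with λᵢ = e^{βᵢ}, λ₀ ≡ 1.  The sample LOD is
the sum of base-10 logs over independent pairs; the test statistic is
2 ln(10) · LOD.  Only full-sib posteriors are computed here, but the prior
is an explicit field of each pair, so other unilineal pair types can be
carried with a user-supplied prior.

The trait enters only through ascertainment (both sibs affected) and the
marker is unlinked under the null, so the package contains no penetrance
model anywhere — the null simulations need none.

## Analysis models

Six constraint regimes over which the LOD is maximized:

| model | free parameters | feasible set | asymptotic null of 2 ln 10 · LOD |
|---|---|---|---|
| unconstrained 2-par | β₁, β₂ | ℝ² | χ²₂ |
| constrained 2-par | β₁, β₂ | β₁ ≥ 0, β₂ ≥ ln(2e^{β₁}−1) | (½−c)χ²₀ + ½χ²₁ + cχ²₂ |
| unconstrained 1-par | β₁ | minmax tie | χ²₁ |
| constrained 1-par | β₁ | minmax tie, β₁ ≥ 0 | ½χ²₀ + ½χ²₁ |
| unconstrained covariate | β₁, δ₁..δ_K | β₁ ≥ 0, δ free | ½χ²_K + ½χ²_{K+1} |
| constrained covariate | β₁, δ₁..δ_K | additionally β₁ + x·δ ≥ 0 at observed x | data-dependent (see below) |

The minmax tie is λ₂ = (π+1)λ₁ − π with π = 2.634, a one-parameter model
intermediate between recessive and dominant inheritance.  The triangle
constraints are exactly the possible-triangle restrictions in
allele-sharing coordinates: λ₁ ≥ 1 ⟺ z₁ ≥ 2z₀ and λ₂ ≥ 2λ₁ − 1 ⟺ z₁ ≤ ½.

Covariates enter log-linearly.  In the one-parameter covariate models the
default convention applies the minmax tie *after* covariate adjustment,
λ₂ = 3.634·exp(β₁ + Σδⱼxⱼ) − 2.634; the alternative (sharing δ between both
log risks, λ₂ = exp(minmax(β₁) + Σδⱼxⱼ)) is available as
`CovariateConvention.TIED_DELTA`.  The choice is not dictated by the
statistic's definition and materially affects fitted values away from the
null, hence the explicit switch.  The covariate null fixes β₁ = 0 *and*
δ = 0 jointly, consistent with the stated mixture degrees of freedom.

For the constrained covariate model, λ₁ ≥ 1 is imposed at every observed
covariate vector (β₁ + x·δ ≥ 0 for all observed x), which for a
minimum-adjusted covariate with values {0, 1, 2} reduces to δ ≥ −β₁/2 when
β₁ > 0 and δ ≥ 0 at β₁ = 0.  Its true null distribution depends on the
covariate distribution in the data; the packaged ½χ²₀ + ½χ²₁ approximation
is adequate for a single minimum-adjusted binary covariate and is emitted
with a warning — simulation is the recommended route.

## Mixing proportion geometry

The chi-bar-square weight c is the probability that the unconstrained
estimate falls inside the constraint cone.  It is computed geometrically:
let the cone at the null be spanned by rays to an additive vertex A (on the
no-dominance curve) and a dominant vertex D (on the β₂ axis at A's height),
take the spectral decomposition PΛPᵀ of the parameter covariance, map the
vertices by Λ^{±1/2}Pᵀ, rotate rigidly so A's image lies on the positive
horizontal axis with D's image in the upper half-plane, and set
c = θ/2π from θ = atan2(y_D).

Two conventions are exposed and never silently mixed:

* `SCALED` maps the vertices by Λ^{1/2}Pᵀ with Λ the eigenvalues of the covariance
  [[6, 4], [4, 8]].  This is the convention under which the tabulated CL
  values (c₁ ≈ 0.0503, c₂ ≈ 0.0439, c₃ ≈ 0.0543, limit ≈ 0.0701) and the
  critical-LOD table are derived, and the default throughout.
* `WHITEN` is standard sphering, Λ^{−1/2}Pᵀ, which maps the estimate to
  unit covariance.  Applied to the allele-sharing parameterization (cone
  rays (0,1) and (−2,3) at (z₁,z₂) = (½,¼), covariance
  [[¼,−⅛],[−⅛,3/16]]) it reproduces the classical c ≈ 0.098.

The two conventions are genuinely different transforms; the package treats
`SCALED` as the reproduction target and `WHITEN` as the cross-check and
sensitivity tool rather than adjudicating between them.

Because the constraint curve is curved, c grows with the assumed upper
bound on β₁ and converges, like ln(2)/β₁, to the value obtained from the
asymptote direction (1, 1) — c_max ≈ 0.070109, computed analytically by
`mixing_proportion_limit` rather than at a large finite β₁ (at β₁ = 50 the
curve is still ≈ 0.0695).

Numerical conventions fixed for bit-reproducibility: eigenvalues sorted
descending; eigenvector signs chosen so the *second* component is positive
(this orientation reproduces the tabulated intermediate vertices
digit-for-digit; with the opposite sign the second coordinates flip, and θ
and c are unchanged); reflection about the horizontal axis applied after
rotation if D's image lands in the lower half-plane.

## Critical values

`critical_lod` solves mixture_survival(2 ln 10 · LOD) = α by bracketed
Brent root-finding on LOD ∈ [0, 20] (xtol 1e-10).  The df = 0 component is
a point mass at zero contributing nothing for x > 0.  The tabulated
critical-LOD table quotes the four mixing proportions rounded to 4 decimals
(0.0439, 0.0503, 0.0701, 0.0980) and solves from those rounded values —
that is the precision at which the proportions are reported, and the
resulting 24 table cells are stable at 3 decimals; full-precision c is used
everywhere else in the package.

## IBD posteriors

Exact enumeration, no sampling.  With typed parents, the 16 equiprobable
ordered transmission patterns (2 meiosis choices per parent per sib) are
enumerated, patterns inconsistent with the observed sib genotypes dropped,
and IBD counts tallied; zero consistent patterns raises a
Mendelian-inconsistency error.  With untyped parents the same enumeration
is marginalized over ordered parental genotype pairs with Hardy–Weinberg
weights pᵢpⱼ (random mating); the k⁴ × 16 sum is precomputed once per
frequency spec into a joint table over unordered genotype pairs and cached,
making per-family lookup O(1).  One typed parent marginalizes only the
missing parent.  With unique founder alleles the posterior is an indicator
on the true IBD count.

PIC = 1 − Σpᵢ² − ΣΣ_{j>i} 2pᵢ²pⱼ²; the k = 2, 4, 8, 20 equifrequent markers
used by the simulator have PIC 0.38, 0.70, 0.86, 0.95.

## Maximization

The two-parameter objectives use an analytic gradient and L-BFGS-B within
β ∈ [−10, 10]² (LOD contributions saturate far before those bounds).
Multi-start is adaptive: the null point and a moment start (relative risks
implied by the pooled posterior mean) always run; three jittered starts
(fixed internal seed) are added only when those two disagree, which does
not occur for well-behaved likelihoods — in allele-sharing coordinates the
common-prior likelihood is a sum of logs of linear functions, hence concave
with a unique maximum.

The constrained two-parameter fit first tries the unconstrained optimum
(feasible ⇒ done), then searches the interior through the smooth
reparameterization β₁ = u₁², β₂ = boundary(β₁) + u₂² (boundary reachable at
u = 0), and exactly scans the two boundary faces (the constraint curve with
β₁ ∈ [0, 10], and the β₂ axis) with a 65-point grid refined by bounded
Brent — a concave likelihood attains its constrained maximum on a face
whenever the unconstrained optimum is infeasible, so the face scans are an
exactness backstop independent of the reparameterized search.
One-parameter models are maximized the same way on the minmax curve.
Covariate models use SLSQP with bounds and, for the constrained variant,
the linear constraints β₁ + x·δ ≥ 0 per distinct observed covariate vector.

Maximized LODs in (−10⁻⁸, 0) are clipped to 0 (the null is feasible in
every model, so the true maximum is nonnegative).  Non-convergence is
flagged on the result, never raised.  Duplicate (posterior, prior) rows are
collapsed to weights before optimization, which reduces fully informative
samples to their three IBD counts and makes replicate studies cheap; the
simulator additionally caches fits per count triple.

## Gene-dropping simulator

The generator mirrors the null-study design: nuclear families with two
parents and two affected sibs; founders get unique alleles (fully
informative) or Hardy–Weinberg draws from k equifrequent alleles
(k ∈ {2, 4, 8, 20}); each sib independently receives one uniformly chosen
allele from each parent; parents are reported or masked.  Segregation
indicators are drawn *before* founder genotypes so studies with a common
seed share true IBD patterns across marker models (common random numbers
for informativeness comparisons).

Covariates: individual values are N(0, 1) plus a fixed offset (default 0 —
under the null the offset is correlated only with the constant affection
status, so it shifts location only); binary covariates dichotomize at the
population quantile of the generating distribution, prevalence 0.2; the
pair value is the sibs' sum, then mean-centered (continuous) or
minimum-adjusted (binary) *per replicate sample*, as done when covariates
enter a real analysis.

Seeding is counter-based: replicate r uses the substream
`SeedSequence(seed, spawn_key=(r,))`, so results are order-independent,
parallelizable, and a pure function of the master seed.

Empirical p-values follow the rank rule p = (r + 1)/(N + 1) with r = 0 at
the largest LOD and ties broken by input order; the empirical critical LOD
at level α is the LOD whose empirical p is the largest value ≤ α, i.e. the
⌊α(N+1)⌋-th largest.

What the generator does *not* emulate: linkage (no alternative-hypothesis
simulation, hence no power studies), genotyping error, larger sibships or
dependent pairs, missing data patterns beyond whole-parent masking, and
real covariate distributions beyond the two stylized kinds.  Passing tests
therefore establish correctness of the null machinery, not robustness to
those real-data features.

## Small-sample behavior and test scales

The test suite runs scaled-down studies (≤ 10,000 replicates, 100–500
families) chosen to keep the full suite within a few minutes; the empirical
null distributions at these scales are exactly enumerable for fully
informative markers (5,151 count triples at n = 100), which the tests
exploit.  Three findings worth recording:

* At n = 100 ASPs the exact distribution of the unconstrained 2-parameter
  statistic has Kolmogorov distance 0.028 from χ²₂ (0.011 at n = 500), so a
  KS test at 10,000 replicates *correctly* rejects χ²₂ at n = 100 — the
  asymptotic approximation is a statement about larger samples, and tail
  critical values are accurate long before the full CDF is.
* The constrained 2-parameter tail at n = 100 is slightly heavy: the exact
  tail probability at the nominal 0.05 critical LOD is 0.0642, *identically
  so across marker informativeness levels* — the null distribution of the
  statistic does not depend on the magnitude of the marker information,
  which is the invariance the suite checks (a mean-LOD ordering by
  informativeness does not hold and is not asserted).
* The constrained 1-parameter boundary mass is 0.5100 at n = 100 and 0.5033
  at n = 500 (exact), converging to ½.

The unconstrained covariate model needs larger samples: its mean LR at
n = 100 is ≈ 1.8 versus the asymptotic 1.5, matching the asymptotic mixture
well only by n ≈ 200–500.

## Degenerate inputs and edge handling

Frequency specs require ≥ 2 strictly positive frequencies summing to 1
within 1e-12; posteriors must sum to 1 within 1e-10.  The minmax map and
the constraint boundary raise domain errors where the implied λ₂ would be
nonpositive; both are evaluated in a form stable for large β₁
(β₁ + log(2 − e^{−β₁})).  Exponent arguments are clipped at ±700 with a
warning.  Pedigree parsing rejects half-missing genotypes and reports line
numbers; families that are not two-parent nuclear families with ≥ 2 typed
affected sibs are skipped with a warning, and extra affected sibs beyond
the first two are dropped (logged) rather than forming all pairs, keeping
pairs independent.

## Known limitations

Single-marker (two-point) analysis only — no multipoint IBD over marker
maps.  Posterior computation is sib-pair specific.  The constrained
covariate model's null is data-dependent; the packaged approximation is
honest only for the single minimum-adjusted binary covariate case.  The
`SCALED`/`WHITEN` transform discrepancy is documented and surfaced, not
resolved.
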
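# Methods

## Model

Both tests are variable-selection problems in the normal linear model
`Y = α + βX + ε`, `ε ~ N(0, φ⁻¹)`, with predictors centred at their sample
means. For the correlation test the null model M₀ is intercept-only and M₁
adds the single predictor; for the partial-correlation test M₀ already
contains the control variable and M₁ adds the variable under test. A model
with p regression coefficients and coefficient of determination R² has,
under the prior setup below, marginal likelihood proportional to

    J(R², p, n) = ∫₀^∞ (1+g)^((n−1−p)/2) [1+(1−R²)g]^(−(n−1)/2) g^(−3/2) e^(−n/(2g)) dg,

with constants that cancel between nested models. The Bayes factor is

- correlation: BF₁₀ = √(n/2π) · J(r², 1, n), using the analytic
  intercept-only integral J(0, 0, n) = √(2π/n);
- partial correlation: BF₁₀ = J(R₁², p₁, n) / J(R₀², p₀, n), with
  R₀² = r_XZ², R₁² = r_XY|Z²(1 − r_XZ²) + r_XZ².

### Prior

The coefficients carry a Zellner g-prior `β | φ, g ~ N(0, (g/φ)(XᵀX)⁻¹)`
with Jeffreys's prior on the precision and a flat prior on the intercept.
Rather than fixing g, the default (JZS) test mixes over
`g ~ inverse-gamma(1/2, n/2)`, i.e.
`p(g) = (n/2)^(1/2)/Γ(1/2) · g^(−3/2) e^(−n/(2g))`, which is equivalent to a
Cauchy prior on β with unit-information scaling. This mixture is what makes
the test "default": it needs no user-set scale, and it avoids the
Jeffreys–Lindley–Bartlett paradox. The fixed-g Bayes factor
`(1+g)^((n−2)/2)[1+(1−r²)g]^(−(n−1)/2)` (the g-conditional version of the
correlation Bayes factor; no closed form is printed in the source, so this
definition — Eq. 15's integrand ratio at a point mass on g — is adopted as
the uniquely consistent one) is provided purely to exhibit that paradox:
for any fixed data it decays like g^(−1/2) to 0 as g → ∞.

## Numerics

The integrand of J underflows double precision for moderate n, and the
domain is infinite. The implementation therefore:

1. maps (0, ∞) → (0, 1) by u = g/(1+g), then applies u = v(2−v). The second
   substitution removes the (1−u)^(−1/2) endpoint singularity that appears
   for p = 0, leaving a bounded smooth integrand for every admissible
   (R², p);
2. evaluates the log integrand, locates its peak (coarse 65-point grid, then
   bounded scalar minimization), and integrates exp(log f − max log f) with
   `scipy.integrate.quad` at absolute/relative tolerance 1e−12, far below
   the two decimals at which the source reports Bayes factors but useful
   headroom for downstream log-BF differences;
3. reports the achieved relative quadrature error in the result and raises
   if it exceeds 1e−8.

Log-space evaluation keeps log BF₁₀ finite for n ≥ 10⁴; `bf10` itself may
overflow to +inf without being flagged divergent. Genuine divergences
(|r| = 1, or R₁² = 1: the marginal likelihood ratio is unbounded) return
+inf with an explicit `divergent` flag rather than a large number.
Correlation triples whose implied partial correlation falls outside [−1, 1]
(not a positive-semidefinite correlation structure) raise an error rather
than clamp. Evidence-category boundaries (3, 10, 30, 100 and reciprocals)
are assigned to the stronger adjacent category; the published ranges are
open-ended and silent on endpoint ownership, and boundary inputs are
measure-zero. BF₁₀ = 1 maps to "No evidence".

Minimum sample sizes are n = 3 for the pairwise test and n = 4 for the
partial test (at least one degree of freedom); variances use unbiased (n−1)
denominators throughout. Internal computation is at full double precision;
two-decimal rounding exists only in presentation layers (the CLI's
`display` block).

## Sequential monitoring

`sequential_bf` recomputes the correlation Bayes factor on every growing
prefix of a paired stream, starting at `min_n = 5` by default: the integral
is defined from n = 3, but windows that small are noisy and divergence-prone
(a perfectly collinear prefix of 3 points is common), so the default starts
slightly later and is overridable. Prefixes with zero variance in either
variable are skipped with a warning. No stopping rule is imposed — the
package reports trajectories; thresholds are the analyst's decision.

## Synthetic data

The published examples are scatterplot replots whose raw observations are
not tabulated, so the generator produces multivariate normal stand-ins
matching each example's printed n, means/SDs (where printed) and target
correlation matrix. Sampling draws i.i.d. standard normals and recolours
with the symmetric (eigendecomposition) square root of the target
correlation; positive semidefiniteness is verified with eigenvalue
tolerance 1e−10. An exact mode additionally whitens the centred sample
against its own empirical covariance before recolouring, so the *empirical*
means, SDs (ddof = 1) and correlations equal the targets to machine
precision — this is what lets documentation reproduce printed r values from
raw columns deterministically.

Moments not printed in the source were fixed once at field-plausible values
and are not tuned: Facebook friend counts centred on 300 (SD 170) with
standardized grey-matter density; search times centred on 1500 ms (SD 400),
rapid-resumption proportion 0.35 (SD 0.12), age 11.5 years (SD 4.7). The
generator emulates correlation structure only — real data of these kinds
are skewed, bounded (proportions, counts) and contain outliers, so passing
tests demonstrate correctness of the pipeline on normal data, not
robustness of the correlation tests to non-normality.

Simulation problem sizes used by the test suite — 200 streams of n = 100
for the consistency checks, 100 seeds of n = 200 for parameter recovery —
are desk-scale choices that keep the whole suite fast while leaving the
median/proportion criteria far from their thresholds.

## Known discrepancies in the source examples

Two printed Bayes factors are not reproducible from their printed inputs,
under this implementation, an independent 40-digit quadrature oracle, and a
third-party implementation of the same integral (pingouin), all of which
agree to more than 10 digits:

- meditation example: the integral at r = −.36, n = 54 gives 3.72; at the
  unrounded printed ratio −589/1629 it gives 3.85, against a printed 3.86.
- Facebook example: the integral at r = .48, n = 40 gives 16.12, against a
  printed 17.87, which corresponds to r ≈ 0.4844.

The pattern (inverting each printed Bayes factor yields an r that rounds to
the printed two-decimal r) indicates the published values were computed
from the authors' full-precision replotted data, which are unavailable.
This package computes from the printed statistics and reports what the
integral actually gives; the partial-correlation example, whose inputs are
printed to seven decimals, reproduces exactly (0.13). The acceptance tests
for the two correlation examples assert the printed values and accordingly
fail; everything else passes.

## Limitations

- Two-sided tests only; no Spearman/Kendall variants, no confidence or
  credible intervals for ρ, no posterior distribution over ρ.
- Partial correlation with a single control variable (the nested pair
  p₀ = 1, p₁ = 2); the J integral itself accepts general p for the
  summary-statistic API.
- Complete-case deletion is the only missing-data policy.
- The exact-correlation mode requires n > dim and a positive-definite
  target.
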
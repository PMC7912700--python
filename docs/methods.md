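# Methods

## The model

All computations start from a fitted factor-analysis model for p
standardized manifest variables and m common factors,

    X_i = Σ_j λ_ij ξ_j + ε_i,   i = 1..p,

with E(ξ_j) = 0, Var(ξ_j) = 1, Corr(ξ) = Φ, Var(ε_i) = ω_i² > 0 and
mutually uncorrelated unique factors (Ω = diag(ω²) throughout; correlated
unique factors are out of scope). The package never estimates Λ from raw
data — loadings are the output of whatever extraction/rotation procedure
the user ran — and everything downstream is a closed-form function of
(Λ, Φ, ω²) through the implied joint covariance of (X, ξ):

    Σ = ΛΦΛᵀ + Ω,   Cov(X, ξ) = ΛΦ,   Cov(ξ) = Φ.

## Entropy contributions

With Gaussian errors, the symmetrized Kullback–Leibler information between
the conditional law of X given ξ and its marginal reduces to a
signal-to-noise ratio that is additive over variables:

    KL(X, ξ) = Σ_i (ΛΦΛᵀ)_ii / ω_i²  = Σ_i communality_i / uniqueness_i.

Additivity over variables (and hence over any partition of them into
subvectors) is what makes KL usable as a contribution measure; the entropy
coefficient of determination ECD = KL/(KL+1) maps it to [0, 1) like an R².
The moment formulas are distribution-free; the KL interpretation is
validated here in the Gaussian case only (see the Monte-Carlo oracle).

The contribution of a single unit-variance factor η = fᵀξ is defined as
the drop in KL when conditioning on η. Under the Gaussian joint,
conditioning replaces Φ by Φ − Φffᵀ Φ/(fᵀΦf) in the signal term, so the
drop has the closed marginal form

    C(η→X) = Σ_i (ΛΦf)_i² / (ω_i² · fᵀΦf),

which is the implementation; the explicit-conditioning route is kept in
the oracles module (`conditional_kl_given_factor`) and the equivalence is
asserted to 1e-8 in the tests. Relative contributions RC = C/KL may sum
above 1 for correlated factors — no renormalization is applied, because
shared variance is genuinely counted once per factor; RC̃ = C/(KL+1) is
reported alongside.

## Canonical factor analysis

Canonical correlation analysis between a manifest subvector X_a and the
factor vector ξ is computed from the model-implied covariances, never from
data. The contributions ρ_j²/(1−ρ_j²) of the canonical pairs are exactly
the eigenvalues of A_a Φ with A_a = Λ_aᵀΩ_a⁻¹Λ_a, and they sum to
KL(X_a, ξ): the leading canonical factor is the single most important
direction of the factor space for X_a on the entropy scale, and the
importance order of the pairs is the order of their canonical
correlations.

Numerically we solve the symmetric eigenproblem S = TᵀA_aT with the
Cholesky factor Φ = TTᵀ rather than forming Σ_a⁻¹: the route stays stable
when a uniqueness is very small (both worked examples contain a variable
with ω² ≈ 0.04–0.15), and eigenvalues of S are contributions directly, so
ρ_j² = a_j/(1+a_j) can never numerically exceed 1. Factor-side
coefficients f_j = T⁻ᵀu_j have unit variance under Φ by construction;
manifest-side coefficients b_j ∝ Σ_a⁻¹Λ_aΦf_j are rescaled to unit
variance under Σ_a (published tables instead print unit-Euclidean-norm
manifest coefficients; the two differ by a positive scalar per pair and
give identical correlations and contributions).

Deterministic output conventions: pairs are ordered by descending ρ²
(ties broken lexicographically on the coefficient vectors); each f_j is
oriented so its largest-magnitude entry is positive, and b_j so that
corr(V_j, η_j) = +ρ_j. If 1−ρ² falls within 1e-12 of zero the
contribution is reported with a warning (a uniqueness is effectively
zero). A subvector of size q yields min(q, m) pairs.

The whole analysis is invariant under nonsingular linear transforms of
either the manifest variables or the factors, so it does not depend on
the initial rotation of the fitted solution; this is asserted under 50
random factor transforms and random diagonal manifest rescalings.

## Derived (oblique) factor systems

Given m substantive variable groups, the leading canonical factor of each
group defines a row of a coefficient matrix G (each row normalized to
unit variance under Φ). The model is then re-expressed without changing
its implied covariance:

    Λ* = ΛG⁻¹,   Corr(η) = GΦGᵀ.

G must be square and well-conditioned — with fewer than m groups the
loadings Λ* do not exist (contributions still do), and the error message
says so. When more than m groups are of interest (the six-score example
derives three factors in a two-dimensional factor space), systems are
built per m-subset of the groups, as the CLI's `--use` flag exposes; the
derived factors are generally correlated and their full pairwise
correlation matrix fᵀΦf is reported regardless. Group order is preserved
as given; the package does not search over groupings.

## Synthetic models and oracles

`simulate_factor_model` emulates the simple-structure pattern of rotated
solutions on test batteries: each variable gets one dominant loading
drawn from U(0.4, 0.85), cross-loadings from U(0, 0.3) with random sign,
factor correlations bounded by a spread parameter (default 0.3, shrunk
geometrically until Φ is positive definite), and uniquenesses set to
1 − communality with a floor of 0.05 enforced by row rescaling. These
defaults bracket the two embedded examples (whose loadings span 0.25–0.97
and uniquenesses 0.04–0.77). What the generator does not emulate:
sampling error in the loadings, non-Gaussian errors, missing data, or
correlated unique factors — so passing property tests establish the
algebraic identities, not robustness of any estimation step (none is
performed).

Two independent oracles validate the closed forms:

- `mc_kl_estimate` evaluates both directed integrals of the symmetrized
  KL by Monte Carlo with exact Gaussian log-densities (joint draws for
  the forward term, independent draws for the reverse term) and reports a
  standard error; agreement with the closed form is asserted within 3 SE
  at n = 10⁶ on the fixtures and n = 5·10⁴ on random models.
- sample CCA (statsmodels `CanCorr`, test-only dependency) on 10⁶
  simulated joint observations reproduces the model-implied canonical
  correlations within 3 large-sample standard errors (1−ρ²)/√n.

## Numerical choices and conventions

- Positive definiteness: smallest eigenvalue > 1e-10 × largest; transforms
  and derived-system coefficient matrices are rejected above condition
  number 1e12.
- Uniqueness convention: user-supplied ω² are honored verbatim; with
  `recompute_uniqueness` they are set to 1 − communality, which assumes
  standardized manifest variables and is the convention under which the
  embedded examples reproduce published tables (printed uniquenesses are
  rounded to two decimals; chaining them degrades small-uniqueness
  variables badly, e.g. 0.04 vs the exact 0.0447 changes that variable's
  signal-to-noise ratio by 11%).
- All internal arithmetic is double precision; published tables chain
  rounded intermediates, so comparisons against them in the test suite
  use ≤1% relative tolerances (±0.01 on loading tables) while algebraic
  identities are asserted at 1e-8–1e-12.
- Variable/factor names default to X1..Xp / f1..fm.

## Known limitations

- Population quantities only: no standard errors or tests for canonical
  correlations or contributions.
- Conditional contributions given several factors simultaneously are not
  implemented.
- Ω is diagonal by model assumption; the cofactor form of the general
  signal-to-noise ratio reduces to the diagonal-weighted trace used here.
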
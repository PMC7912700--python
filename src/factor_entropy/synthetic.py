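"""Synthetic factor models, Gaussian sampling and brute-force oracles.

The generator emulates the simple-structure pattern typical of rotated
solutions on educational test batteries: each variable loads strongly on
one dominant factor and weakly elsewhere, factors are mildly correlated,
and uniquenesses are 1 - communality (standardized variables). Sampling
and the Monte-Carlo KL estimator provide routes to the same quantities
that do not share code with the closed-form implementation, for use as
independent oracles in tests.

Two published 2-factor solutions ship as named fixtures: ``example1`` —
five school-subject scores (three liberal-arts, two science subjects)
under a varimax solution; ``example2`` — six ability scores (a general
intelligence indicator, three problem-solving and two verbal tests) under
a varimax maximum-likelihood solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .model import FactorModel, FactorModelError, build_model

__all__ = [
    "SyntheticSpec",
    "simulate_factor_model",
    "sample_observations",
    "MCKLEstimate",
    "mc_kl_estimate",
    "conditional_kl_given_factor",
    "builtin_fixture",
    "FIXTURE_NAMES",
]

# 5 subjects x 2 varimax factors (rows: X1..X5; cols: liberal-arts-leaning f1,
# science-leaning f2); uniquenesses recomputed as 1 - communality.
_EXAMPLE1_LOADINGS = [
    [0.60, 0.39],
    [0.75, 0.24],
    [0.65, 0.00],
    [0.32, 0.59],
    [0.00, 0.92],
]

# 6 ability scores x 2 varimax ML factors (rows X1..X6).
_EXAMPLE2_LOADINGS = [
    [0.64, 0.37],
    [0.34, 0.54],
    [0.46, 0.76],
    [0.25, 0.41],
    [0.97, -0.12],
    [0.82, -0.03],
]

FIXTURE_NAMES = ("example1", "example2")


def builtin_fixture(name: str) -> FactorModel:
    """Load a built-in published factor solution by name."""
    table = {"example1": _EXAMPLE1_LOADINGS, "example2": _EXAMPLE2_LOADINGS}
    if name not in table:
        raise FactorModelError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return build_model(np.array(table[name]), recompute_uniqueness=True)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a random factor model with simple structure.

    ``block_structure`` assigns each variable a dominant factor (defaults
    to round-robin); primary loadings are drawn from ``loading_range``,
    off-block loadings from ``cross_loading_range`` with random sign.
    ``factor_corr_spread`` bounds |off-diagonal| factor correlations; rows
    are rescaled whenever a communality would exceed 1 - min_uniqueness.
    """

    p: int
    m: int
    seed: int
    block_structure: tuple[int, ...] | None = None
    loading_range: tuple[float, float] = (0.4, 0.85)
    cross_loading_range: tuple[float, float] = (0.0, 0.3)
    factor_corr_spread: float = 0.3
    min_uniqueness: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.p:
            raise FactorModelError(f"need p >= m >= 1, got p={self.p}, m={self.m}")
        for lo, hi in (self.loading_range, self.cross_loading_range):
            if not (-1 < lo <= hi < 1):
                raise FactorModelError("loading ranges must lie within (-1, 1)")
        if not 0 <= self.factor_corr_spread < 1:
            raise FactorModelError("factor_corr_spread must be in [0, 1)")
        if not 0 < self.min_uniqueness < 1:
            raise FactorModelError("min_uniqueness must be in (0, 1)")
        if self.block_structure is not None:
            if len(self.block_structure) != self.p:
                raise FactorModelError("block_structure must assign all p variables")
            if any(not 0 <= b < self.m for b in self.block_structure):
                raise FactorModelError("block_structure entries must index a factor")


def _random_factor_corr(m: int, spread: float, rng: np.random.Generator) -> np.ndarray:
    phi = np.eye(m)
    if spread == 0 or m == 1:
        return phi
    off = rng.uniform(-spread, spread, size=(m, m))
    off = np.triu(off, 1)
    phi = np.eye(m) + off + off.T
    # shrink off-diagonals until positive definite (always terminates)
    while np.linalg.eigvalsh(phi)[0] < 1e-6:
        off *= 0.8
        phi = np.eye(m) + off + off.T
    return phi


def simulate_factor_model(spec: SyntheticSpec) -> FactorModel:
    """Draw a random valid :class:`FactorModel`; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    blocks = (
        np.asarray(spec.block_structure)
        if spec.block_structure is not None
        else np.arange(spec.p) % spec.m
    )
    lam = np.zeros((spec.p, spec.m))
    lo, hi = spec.cross_loading_range
    for i in range(spec.p):
        cross = rng.uniform(lo, hi, size=spec.m) * rng.choice([-1.0, 1.0], size=spec.m)
        lam[i] = cross
        lam[i, blocks[i]] = rng.uniform(*spec.loading_range)
    phi = _random_factor_corr(spec.m, spec.factor_corr_spread, rng)
    communality = np.einsum("ij,jk,ik->i", lam, phi, lam)
    cap = 1.0 - spec.min_uniqueness
    too_big = communality > cap
    lam[too_big] *= np.sqrt(cap / communality[too_big])[:, None]
    return build_model(lam, factor_corr=phi, recompute_uniqueness=True)


def sample_observations(model: FactorModel, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. rows of the joint Gaussian (X, xi), shape (n, p+m)."""
    if n < 1:
        raise FactorModelError("n must be >= 1")
    cov = model.joint_covariance().full_matrix()
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.p + model.m))
    return z @ chol.T


# ----------------------------------------------------------------------
# oracles


@dataclass(frozen=True)
class MCKLEstimate:
    """Monte-Carlo estimate of the symmetrized KL information with its SE."""

    value: float
    std_error: float
    n: int
    forward: float
    reverse: float


def _log_cond_density(x: np.ndarray, xi: np.ndarray, model: FactorModel) -> np.ndarray:
    """log f(x | xi): independent Gaussians around the predictor Lambda xi."""
    resid = x - xi @ model.loadings.T
    omega = model.unique_vars
    return (
        -0.5 * np.sum(resid**2 / omega, axis=1)
        - 0.5 * np.sum(np.log(2.0 * np.pi * omega))
    )


def mc_kl_estimate(model: FactorModel, n: int, seed: int) -> MCKLEstimate:
    """Monte-Carlo evaluation of the symmetrized KL information KL(X, xi).

    Both directed integrals are estimated separately with exact Gaussian
    log-densities: the forward term averages log f(x|xi) - log f(x) over
    joint draws, the reverse term averages the negative of that difference
    over independent draws of x and xi. Their sum is an unbiased estimate
    of the closed-form signal-to-noise ratio.
    """
    joint = model.joint_covariance()
    marg_x = multivariate_normal(mean=np.zeros(model.p), cov=joint.manifest_block)
    rng = np.random.default_rng(seed)

    draws = sample_observations(model, n, seed=int(rng.integers(2**31)))
    x_joint, xi_joint = draws[:, : model.p], draws[:, model.p :]
    fwd_terms = _log_cond_density(x_joint, xi_joint, model) - marg_x.logpdf(x_joint)

    chol_phi = np.linalg.cholesky(joint.factor_block)
    chol_sigma = np.linalg.cholesky(joint.manifest_block)
    rng_ind = np.random.default_rng(int(rng.integers(2**31)))
    x_ind = rng_ind.standard_normal((n, model.p)) @ chol_sigma.T
    xi_ind = rng_ind.standard_normal((n, model.m)) @ chol_phi.T
    rev_terms = marg_x.logpdf(x_ind) - _log_cond_density(x_ind, xi_ind, model)

    forward, reverse = float(fwd_terms.mean()), float(rev_terms.mean())
    se = float(
        np.sqrt(fwd_terms.var(ddof=1) / n + rev_terms.var(ddof=1) / n)
    )
    return MCKLEstimate(
        value=forward + reverse, std_error=se, n=n, forward=forward, reverse=reverse
    )


def conditional_kl_given_factor(model: FactorModel, factor_coeffs) -> float:
    """KL(X, xi | eta) for eta = f^T xi, by explicit Gaussian conditioning.

    Conditioning the joint Gaussian on eta replaces Phi by
    Phi - Phi f f^T Phi / (f^T Phi f) in the signal term while leaving the
    unique variances untouched. Serves as the independent route to single-
    factor contributions: KL(X, xi) - KL(X, xi | eta) = C(eta -> X).
    """
    f = np.asarray(factor_coeffs, dtype=float).reshape(-1)
    phi = model.factor_corr
    var_eta = float(f @ phi @ f)
    if var_eta <= 0:
        raise FactorModelError("factor_coeffs must have positive variance")
    phi_f = phi @ f
    phi_cond = phi - np.outer(phi_f, phi_f) / var_eta
    signal = np.einsum("ij,jk,ik->i", model.loadings, phi_cond, model.loadings)
    return float(np.sum(signal / model.unique_vars))
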
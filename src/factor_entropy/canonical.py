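"""Canonical factor analysis: CCA between manifest (sub)vectors and factors.

Canonical correlation analysis is run on the model-implied joint covariance
of (X, xi) — no raw data is involved. For a subvector X_a with loadings
Lambda_a and unique variances Omega_a, the canonical contributions
rho_j^2/(1 - rho_j^2) are exactly the eigenvalues of

    S = T^T Lambda_a^T Omega_a^{-1} Lambda_a T,      Phi = T T^T (Cholesky),

a symmetric eigenproblem chosen over inversion of Sigma_a for stability
when uniquenesses are small. Factor-side coefficients are f_j = T^{-T} u_j
(unit variance under Phi); manifest-side coefficients are proportional to
Sigma_a^{-1} Lambda_a Phi f_j, scaled to unit variance. The sum of the
contributions over all pairs equals KL(X_a, xi), which is the decomposition
that makes the leading canonical factor "the most important factor" on the
entropy scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import FactorModel, FactorModelError, GroupSpec
from .contributions import kl_contribution

__all__ = [
    "CanonicalPair",
    "CanonicalDecomposition",
    "canonical_decomposition",
    "subgroup_analysis",
]

#: 1 - rho^2 below this triggers a near-singular warning (uniqueness ~ 0)
RHO_SQ_CAP_EPS = 1e-12


@dataclass(frozen=True)
class CanonicalPair:
    """One canonical pair (V_j, eta_j) with its entropy contribution."""

    rank: int
    rho_sq: float
    factor_coeffs: np.ndarray
    manifest_coeffs: np.ndarray
    contribution: float

    @property
    def rho(self) -> float:
        return float(np.sqrt(self.rho_sq))


@dataclass(frozen=True)
class CanonicalDecomposition:
    """Ordered canonical pairs for one manifest (sub)vector against xi."""

    subset: list[int]
    subset_names: list[str]
    pairs: list[CanonicalPair]
    total_kl: float
    rc: list[float]
    rc_tilde: list[float]

    @property
    def rho_sq(self) -> np.ndarray:
        return np.array([p.rho_sq for p in self.pairs])

    @property
    def contributions(self) -> np.ndarray:
        return np.array([p.contribution for p in self.pairs])

    def factor_coeff_matrix(self) -> np.ndarray:
        """Rows are the factor-side coefficient vectors f_j."""
        return np.vstack([p.factor_coeffs for p in self.pairs])

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset_names),
            "total_kl": self.total_kl,
            "pairs": [
                {
                    "rank": p.rank,
                    "rho_sq": p.rho_sq,
                    "contribution": p.contribution,
                    "rc": self.rc[k],
                    "rc_tilde": self.rc_tilde[k],
                    "factor_coeffs": p.factor_coeffs.tolist(),
                    "manifest_coeffs": p.manifest_coeffs.tolist(),
                }
                for k, p in enumerate(self.pairs)
            ],
        }


def _orient_largest_positive(v: np.ndarray) -> np.ndarray:
    """Flip sign so the largest-magnitude entry is positive (deterministic)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _order_descending(eigvals: np.ndarray, eigvecs: np.ndarray):
    """Descending eigenvalue order; ties broken lexicographically on vectors."""
    order = np.argsort(-eigvals, kind="stable")
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # lexicographic tie-break among numerically equal eigenvalues
    scale = max(eigvals[0], 1.0) if eigvals.size else 1.0
    j = 0
    while j < eigvals.size - 1:
        k = j + 1
        while k < eigvals.size and abs(eigvals[k] - eigvals[j]) <= 1e-12 * scale:
            k += 1
        if k - j > 1:
            block = [_orient_largest_positive(eigvecs[:, c]) for c in range(j, k)]
            for offset, col in enumerate(sorted(range(k - j), key=lambda c: tuple(block[c]))):
                eigvecs[:, j + offset] = block[col]
        j = k
    return eigvals, eigvecs


def canonical_decomposition(
    model: FactorModel, subset=None
) -> CanonicalDecomposition:
    """Canonical pairs between X (or a subvector) and the factor vector xi.

    Returns min(|subset|, m) pairs ordered by descending rho^2; the
    contributions rho_j^2/(1-rho_j^2) sum to KL(X_subset, xi).
    """
    if subset is None:
        idx = list(range(model.p))
    else:
        idx = model.indices_for(subset)
        if not idx:
            raise FactorModelError("subset must be non-empty")
    lam = model.loadings[idx]
    omega = model.unique_vars[idx]
    phi = model.factor_corr

    t = np.linalg.cholesky(phi)
    a_mat = lam.T @ (lam / omega[:, None])  # Lambda_a^T Omega_a^{-1} Lambda_a
    s_mat = t.T @ a_mat @ t
    s_mat = 0.5 * (s_mat + s_mat.T)
    eigvals, eigvecs = np.linalg.eigh(s_mat)
    eigvals = np.clip(eigvals, 0.0, None)
    eigvals, eigvecs = _order_descending(eigvals, eigvecs)

    total = float(kl_contribution(model, idx))
    n_pairs = min(len(idx), model.m)

    sigma_a = lam @ phi @ lam.T + np.diag(omega)
    sigma_cho = scipy.linalg.cho_factor(sigma_a)

    pairs = []
    for j in range(n_pairs):
        contrib = float(eigvals[j])
        rho_sq = contrib / (1.0 + contrib)
        if 1.0 - rho_sq < RHO_SQ_CAP_EPS:
            warnings.warn(
                f"canonical pair {j + 1}: rho^2 within {RHO_SQ_CAP_EPS} of 1 "
                "(a uniqueness is nearly zero); contribution capped",
                RuntimeWarning,
                stacklevel=2,
            )
        f = scipy.linalg.solve_triangular(t, eigvecs[:, j], lower=True, trans="T")
        f = _orient_largest_positive(f)
        cov_x_eta = lam @ (phi @ f)
        b = scipy.linalg.cho_solve(sigma_cho, cov_x_eta)
        var_v = float(b @ sigma_a @ b)
        if var_v <= 0:
            raise FactorModelError(
                f"degenerate subset covariance for canonical pair {j + 1}"
            )
        b = b / np.sqrt(var_v)
        if float(b @ cov_x_eta) < 0:  # corr(V_j, eta_j) = +rho_j
            b = -b
        pairs.append(
            CanonicalPair(
                rank=j + 1,
                rho_sq=float(rho_sq),
                factor_coeffs=f,
                manifest_coeffs=b,
                contribution=contrib,
            )
        )

    rc = [p.contribution / total if total > 0 else 0.0 for p in pairs]
    rc_tilde = [p.contribution / (total + 1.0) for p in pairs]
    return CanonicalDecomposition(
        subset=idx,
        subset_names=[model.variable_names[i] for i in idx],
        pairs=pairs,
        total_kl=total,
        rc=rc,
        rc_tilde=rc_tilde,
    )


def subgroup_analysis(
    model: FactorModel, groups: GroupSpec
) -> dict[str, CanonicalDecomposition]:
    """Per-group canonical decompositions against the full factor vector.

    When the groups partition the manifest variables, the grand sum of all
    contributions equals KL(X, xi); overlapping groups are allowed but the
    additivity identity then no longer applies and a warning is issued.
    """
    groups.validate_against(model.p)
    if not groups.is_partition(model.p):
        warnings.warn(
            "groups do not partition the manifest variables; "
            "per-group contributions will not sum to the total KL",
            UserWarning,
            stacklevel=2,
        )
    return {
        name: canonical_decomposition(model, idx)
        for name, idx in groups.groups.items()
    }
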
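"""Fitted factor-analysis models and their implied covariance structure.

A factor model for p standardized manifest variables X = (X1, ..., Xp) and
m common factors xi = (xi_1, ..., xi_m) is

    X_i = sum_j lambda_ij xi_j + eps_i,

with unit-variance factors, Corr(xi) = Phi, Var(eps_i) = omega_i^2 > 0 and
mutually uncorrelated unique factors. Everything downstream (entropy
contributions, canonical factor analysis, factor derivation) is a function
of (Lambda, Phi, omega^2) only; no raw data is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FactorModel",
    "JointCovariance",
    "GroupSpec",
    "FactorModelError",
    "build_model",
    "implied_joint_covariance",
    "transform_model",
]

#: relative eigenvalue floor for positive-definiteness checks
PD_RTOL = 1e-10
#: condition-number cap for factor transforms
TRANSFORM_COND_MAX = 1e12


class FactorModelError(ValueError):
    """Invalid or degenerate factor-model input."""


def _as_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise FactorModelError(f"{name} must be a 2-d matrix, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise FactorModelError(f"{name} contains non-finite entries")
    return a


def _check_pd(mat: np.ndarray, name: str) -> None:
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals[-1] <= 0 or eigvals[0] <= PD_RTOL * eigvals[-1]:
        raise FactorModelError(
            f"{name} is not positive definite "
            f"(eigenvalue range [{eigvals[0]:.3e}, {eigvals[-1]:.3e}])"
        )


@dataclass(frozen=True)
class FactorModel:
    """A fitted factor model (Lambda, Phi, omega^2) with variable/factor names.

    Parameters
    ----------
    loadings : (p, m) ndarray
        Standardized factor loadings Lambda.
    factor_corr : (m, m) ndarray
        Factor correlation matrix Phi (general positive-definite factor
        covariance on transformed models; see ``standardized_factors``).
    unique_vars : (p,) ndarray
        Unique variances omega_i^2, all strictly positive.
    variable_names, factor_names : list of str
        Labels; auto-generated as X1..Xp / f1..fm when absent.
    standardized_factors : bool
        True when ``factor_corr`` is a correlation matrix (unit diagonal).
        ``transform_model`` clears this flag when the transformed factor
        covariance is no longer unit-diagonal.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    unique_vars: np.ndarray
    variable_names: list[str] = field(default=None)  # type: ignore[assignment]
    factor_names: list[str] = field(default=None)  # type: ignore[assignment]
    standardized_factors: bool = True

    def __post_init__(self) -> None:
        loadings = _as_matrix(self.loadings, "loadings")
        p, m = loadings.shape
        if p < 1 or m < 1:
            raise FactorModelError(f"loadings must be non-empty, got shape {p}x{m}")
        phi = _as_matrix(self.factor_corr, "factor_corr")
        if phi.shape != (m, m):
            raise FactorModelError(
                f"factor_corr shape {phi.shape} does not match m={m} factors"
            )
        if not np.allclose(phi, phi.T, atol=1e-8):
            raise FactorModelError("factor_corr must be symmetric")
        phi = 0.5 * (phi + phi.T)
        if self.standardized_factors and not np.allclose(np.diag(phi), 1.0, atol=1e-8):
            raise FactorModelError("factor_corr must have unit diagonal")
        _check_pd(phi, "factor_corr")
        omega = np.asarray(self.unique_vars, dtype=float).reshape(-1)
        if omega.shape != (p,):
            raise FactorModelError(
                f"unique_vars length {omega.size} does not match p={p} variables"
            )
        if not np.all(omega > 0):
            bad = [i for i, w in enumerate(omega) if w <= 0]
            raise FactorModelError(f"unique variances must be > 0 (rows {bad})")
        vnames = self.variable_names or [f"X{i + 1}" for i in range(p)]
        fnames = self.factor_names or [f"f{j + 1}" for j in range(m)]
        if len(vnames) != p or len(fnames) != m:
            raise FactorModelError("name lists do not match matrix dimensions")
        object.__setattr__(self, "loadings", loadings)
        object.__setattr__(self, "factor_corr", phi)
        object.__setattr__(self, "unique_vars", omega)
        object.__setattr__(self, "variable_names", list(vnames))
        object.__setattr__(self, "factor_names", list(fnames))
        _check_pd(self.implied_covariance(), "implied covariance Sigma")

    # ------------------------------------------------------------------
    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        """diag(Lambda Phi Lambda^T): variance explained by the common factors."""
        return np.einsum(
            "ij,jk,ik->i", self.loadings, self.factor_corr, self.loadings
        )

    def implied_covariance(self) -> np.ndarray:
        """Sigma = Lambda Phi Lambda^T + diag(omega^2)."""
        sigma = self.loadings @ self.factor_corr @ self.loadings.T
        sigma = 0.5 * (sigma + sigma.T)
        sigma[np.diag_indices_from(sigma)] += self.unique_vars
        return sigma

    def joint_covariance(self) -> "JointCovariance":
        return implied_joint_covariance(self)

    def indices_for(self, names) -> list[int]:
        """Resolve variable names (or integer indices) to row indices."""
        lookup = {name: i for i, name in enumerate(self.variable_names)}
        out = []
        for item in names:
            if isinstance(item, (int, np.integer)):
                if not 0 <= item < self.p:
                    raise FactorModelError(f"variable index {item} out of range")
                out.append(int(item))
            else:
                if item not in lookup:
                    raise FactorModelError(f"unknown variable name {item!r}")
                out.append(lookup[item])
        return out


@dataclass(frozen=True)
class JointCovariance:
    """Block covariance of the joint vector (X, xi).

    manifest_block is Sigma = Lambda Phi Lambda^T + diag(omega^2), the
    cross block is Cov(X, xi) = Lambda Phi and the factor block is Phi.
    """

    manifest_block: np.ndarray
    cross_block: np.ndarray
    factor_block: np.ndarray

    def full_matrix(self) -> np.ndarray:
        """Assemble the (p+m) x (p+m) covariance of (X, xi)."""
        return np.block(
            [
                [self.manifest_block, self.cross_block],
                [self.cross_block.T, self.factor_block],
            ]
        )


@dataclass(frozen=True)
class GroupSpec:
    """Named subgroups of manifest variables (index sets over 0..p-1)."""

    groups: dict[str, list[int]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise FactorModelError("GroupSpec requires at least one group")
        clean = {}
        for name, idx in self.groups.items():
            idx = [int(i) for i in idx]
            if not idx:
                raise FactorModelError(f"group {name!r} is empty")
            if len(set(idx)) != len(idx):
                raise FactorModelError(f"group {name!r} repeats an index")
            clean[str(name)] = idx
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_names(cls, model: FactorModel, named: dict) -> "GroupSpec":
        return cls({name: model.indices_for(members) for name, members in named.items()})

    def validate_against(self, p: int) -> None:
        for name, idx in self.groups.items():
            bad = [i for i in idx if not 0 <= i < p]
            if bad:
                raise FactorModelError(f"group {name!r} has out-of-range indices {bad}")

    def is_partition(self, p: int) -> bool:
        """True when the groups are disjoint and cover all p variables."""
        seen: list[int] = []
        for idx in self.groups.values():
            seen.extend(idx)
        return len(seen) == len(set(seen)) == p and set(seen) == set(range(p))


# ----------------------------------------------------------------------
def build_model(
    loadings,
    factor_corr=None,
    unique_vars=None,
    *,
    recompute_uniqueness: bool = False,
    variable_names=None,
    factor_names=None,
) -> FactorModel:
    """Build and validate a :class:`FactorModel`.

    With ``recompute_uniqueness`` the unique variances are set to
    1 - communality, which assumes standardized manifest variables and is
    the convention that reproduces published tables whose printed
    uniquenesses are rounded. Supplied ``unique_vars`` are otherwise
    honored as given.
    """
    loadings = _as_matrix(loadings, "loadings")
    p, m = loadings.shape
    if factor_corr is None:
        factor_corr = np.eye(m)
    if unique_vars is None and not recompute_uniqueness:
        raise FactorModelError(
            "unique_vars absent: pass them or set recompute_uniqueness"
        )
    if recompute_uniqueness:
        phi = _as_matrix(factor_corr, "factor_corr")
        communality = np.einsum("ij,jk,ik->i", loadings, phi, loadings)
        omega = 1.0 - communality
        if np.any(omega <= 0):
            vnames = variable_names or [f"X{i + 1}" for i in range(p)]
            bad = [vnames[i] for i in np.nonzero(omega <= 0)[0]]
            raise FactorModelError(
                f"degenerate model: communality >= 1 for {bad}; "
                "cannot recompute uniqueness for standardized variables"
            )
        unique_vars = omega
    return FactorModel(
        loadings=loadings,
        factor_corr=np.asarray(factor_corr, dtype=float),
        unique_vars=np.asarray(unique_vars, dtype=float),
        variable_names=variable_names,
        factor_names=factor_names,
    )


def implied_joint_covariance(model: FactorModel) -> JointCovariance:
    """Model-implied covariance of the joint vector (X, xi)."""
    cross = model.loadings @ model.factor_corr
    joint = JointCovariance(
        manifest_block=model.implied_covariance(),
        cross_block=cross,
        factor_block=model.factor_corr.copy(),
    )
    _check_pd(joint.full_matrix(), "joint covariance of (X, xi)")
    return joint


def transform_model(model: FactorModel, factor_transform) -> FactorModel:
    """Re-express the model on transformed factors eta = Q xi.

    The loadings become Lambda Q^{-1} and the factor covariance Q Phi Q^T;
    unique variances and the implied covariance of X are unchanged. The
    transformed factor covariance need not be unit-diagonal, so the
    resulting model is flagged as non-standardized unless it happens to be.
    """
    q = _as_matrix(factor_transform, "factor_transform")
    m = model.m
    if q.shape != (m, m):
        raise FactorModelError(f"factor_transform must be {m}x{m}, got {q.shape}")
    cond = np.linalg.cond(q)
    if not np.isfinite(cond) or cond > TRANSFORM_COND_MAX:
        raise FactorModelError(
            f"factor_transform is singular or ill-conditioned (cond={cond:.3e})"
        )
    new_loadings = np.linalg.solve(q.T, model.loadings.T).T
    new_phi = q @ model.factor_corr @ q.T
    new_phi = 0.5 * (new_phi + new_phi.T)
    standardized = bool(np.allclose(np.diag(new_phi), 1.0, atol=1e-8))
    return replace(
        model,
        loadings=new_loadings,
        factor_corr=new_phi,
        standardized_factors=standardized,
        factor_names=[f"t({name})" for name in model.factor_names],
    )
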
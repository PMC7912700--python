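"""Re-expression of a factor model in derived (generally oblique) factors.

Given a nonsingular m x m coefficient matrix G whose rows define derived
factors eta_k = g_k^T xi (each normalized to unit variance under Phi), the
model is reparametrized without changing its implied covariance:

    Lambda* = Lambda G^{-1},    Corr(eta) = G Phi G^T.

The canonical route picks G's rows as the leading canonical factor of each
of m substantive variable groups, which yields interpretable — typically
correlated — factors together with their entropy contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FactorModel, FactorModelError, GroupSpec
from .contributions import factor_contribution, kl_contribution
from .canonical import subgroup_analysis

__all__ = [
    "DerivedFactorSystem",
    "select_leading_factors",
    "derive_factor_system",
]

COND_MAX = 1e12


@dataclass(frozen=True)
class DerivedFactorSystem:
    """A factor model re-expressed in m derived unit-variance factors."""

    coeff_matrix: np.ndarray
    new_loadings: np.ndarray
    factor_corr_new: np.ndarray
    contributions_to_full: np.ndarray
    uniqueness: np.ndarray
    factor_labels: list[str]
    variable_names: list[str]
    contributions_to_groups: dict[str, dict[str, float]] | None = None

    def to_model(self) -> FactorModel:
        """The derived system as a FactorModel on the oblique factors."""
        return FactorModel(
            loadings=self.new_loadings,
            factor_corr=self.factor_corr_new,
            unique_vars=self.uniqueness,
            variable_names=self.variable_names,
            factor_names=self.factor_labels,
        )

    def to_dict(self) -> dict:
        out = {
            "factor_labels": list(self.factor_labels),
            "coeff_matrix": self.coeff_matrix.tolist(),
            "new_loadings": {
                name: row.tolist()
                for name, row in zip(self.variable_names, self.new_loadings)
            },
            "factor_corr_new": self.factor_corr_new.tolist(),
            "contributions_to_full": dict(
                zip(self.factor_labels, self.contributions_to_full.tolist())
            ),
        }
        if self.contributions_to_groups is not None:
            out["contributions_to_groups"] = self.contributions_to_groups
        return out


def select_leading_factors(model: FactorModel, groups: GroupSpec) -> np.ndarray:
    """Coefficient matrix G from the leading canonical factor of each group.

    Requires exactly m groups (G must be square for Lambda* = Lambda G^{-1});
    rows follow the given group order.
    """
    if len(groups.groups) != model.m:
        raise FactorModelError(
            f"need exactly m={model.m} groups to span the factor space, "
            f"got {len(groups.groups)}; loadings on derived factors require "
            "a square, invertible coefficient matrix"
        )
    decomps = subgroup_analysis(model, groups)
    g = np.vstack(
        [decomps[name].pairs[0].factor_coeffs for name in groups.groups]
    )
    if np.linalg.cond(g) > COND_MAX:
        raise FactorModelError(
            "leading canonical factors of the given groups are (nearly) "
            "linearly dependent; choose a different grouping"
        )
    return g


def derive_factor_system(
    model: FactorModel,
    coeff_matrix,
    groups: GroupSpec | None = None,
    factor_labels: list[str] | None = None,
) -> DerivedFactorSystem:
    """Build the derived system for explicit factor coefficients G.

    Rows of G are rescaled to unit variance under Phi before inversion, so
    the derived factors satisfy Var(eta_k) = 1 and ``factor_corr_new`` is a
    correlation matrix. With ``groups`` given, per-group contributions of
    each derived factor are included.
    """
    g = np.asarray(coeff_matrix, dtype=float)
    m = model.m
    if g.shape != (m, m):
        raise FactorModelError(f"coeff_matrix must be {m}x{m}, got {g.shape}")
    row_vars = np.einsum("ij,jk,ik->i", g, model.factor_corr, g)
    if np.any(row_vars <= 0):
        raise FactorModelError("coeff_matrix has a row with non-positive variance")
    g = g / np.sqrt(row_vars)[:, None]
    cond = np.linalg.cond(g)
    if not np.isfinite(cond) or cond > COND_MAX:
        raise FactorModelError(
            f"coeff_matrix is singular or ill-conditioned (cond={cond:.3e})"
        )
    new_loadings = np.linalg.solve(g.T, model.loadings.T).T  # Lambda G^{-1}
    corr_new = g @ model.factor_corr @ g.T
    corr_new = 0.5 * (corr_new + corr_new.T)
    contributions = np.array([factor_contribution(model, row) for row in g])

    labels = factor_labels or [f"eta{k + 1}" for k in range(m)]
    if groups is not None and factor_labels is None:
        labels = list(groups.groups)

    per_group = None
    if groups is not None:
        groups.validate_against(model.p)
        per_group = {}
        for gname, idx in groups.groups.items():
            sub = model.loadings[idx], model.unique_vars[idx]
            per_group[gname] = {}
            for label, row in zip(labels, g):
                cov = sub[0] @ (model.factor_corr @ row)
                per_group[gname][label] = float(np.sum(cov**2 / sub[1]))

    return DerivedFactorSystem(
        coeff_matrix=g,
        new_loadings=new_loadings,
        factor_corr_new=corr_new,
        contributions_to_full=contributions,
        uniqueness=model.unique_vars.copy(),
        factor_labels=labels,
        variable_names=list(model.variable_names),
        contributions_to_groups=per_group,
    )
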
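"""Entropy-based (Kullback-Leibler) factor contribution measures.

Under Gaussian errors the symmetrized KL information between the
conditional distribution of the manifest vector given the factors and its
marginal reduces to an explained-to-unique variance ratio:

    KL(X, xi) = sum_i (Lambda Phi Lambda^T)_ii / omega_i^2,

i.e. a per-variable signal-to-noise ratio communality/uniqueness. It is
additive over manifest variables and over any partition of them into
subvectors, which is what makes it usable as a contribution measure. The
entropy coefficient of determination ECD = KL/(KL+1) plays the role of an
R^2 on the entropy scale.

The contribution of a single (unit-variance) factor eta = f^T xi to X is
the drop in KL caused by conditioning on eta; under the Gaussian joint
this equals the marginal form

    C(eta -> X) = sum_i Cov(X_i, eta)^2 / (omega_i^2 Var(eta)),

with Cov(X, eta) = Lambda Phi f and Var(eta) = f^T Phi f. The equivalence
with the conditional definition is exercised by the test-suite oracle that
performs the Gaussian conditioning explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FactorModel, FactorModelError, GroupSpec

__all__ = [
    "ContributionReport",
    "kl_contribution",
    "per_variable_contributions",
    "factor_contribution",
    "contribution_report",
]


def per_variable_contributions(model: FactorModel) -> np.ndarray:
    """KL(X_i, xi) for each manifest variable: communality_i / omega_i^2."""
    return model.communalities() / model.unique_vars


def kl_contribution(model: FactorModel, subset=None) -> float:
    """KL(X, xi), or KL(X_subset, xi) for a subvector of manifest variables.

    Additivity over variables makes the subset value a plain partial sum
    of the per-variable signal-to-noise ratios.
    """
    per_var = per_variable_contributions(model)
    if subset is None:
        return float(per_var.sum())
    idx = model.indices_for(subset)
    if not idx:
        raise FactorModelError("subset must be non-empty")
    return float(per_var[idx].sum())


def factor_contribution(model: FactorModel, factor_coeffs) -> float:
    """Contribution C(eta -> X) of the single factor eta = f^T xi.

    Invariant to (nonzero) rescaling of ``factor_coeffs``; the factor is
    normalized to unit variance internally.
    """
    f = np.asarray(factor_coeffs, dtype=float).reshape(-1)
    if f.shape != (model.m,):
        raise FactorModelError(
            f"factor_coeffs must have length m={model.m}, got {f.size}"
        )
    var_eta = float(f @ model.factor_corr @ f)
    if var_eta <= 0 or not np.any(f):
        raise FactorModelError("factor_coeffs must be a nonzero vector")
    cov = model.loadings @ (model.factor_corr @ f)
    return float(np.sum(cov**2 / model.unique_vars) / var_eta)


def ecd(total_kl: float) -> float:
    """Entropy coefficient of determination KL/(KL+1)."""
    return total_kl / (total_kl + 1.0)


@dataclass(frozen=True)
class ContributionReport:
    """Assembled KL contribution summary for one factor model.

    ``rc`` is each factor's share of the total KL (may sum above 1 for
    correlated factors); ``rc_tilde`` divides by KL+1 instead, so the
    whole factor vector gets RC~ = ECD.
    """

    total_kl: float
    per_variable: dict[str, float]
    per_group: dict[str, float]
    per_factor: dict[str, float]
    ecd: float
    rc: dict[str, float]
    rc_tilde: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "total_kl": self.total_kl,
            "ecd": self.ecd,
            "per_variable": dict(self.per_variable),
            "per_group": dict(self.per_group),
            "per_factor": dict(self.per_factor),
            "rc": dict(self.rc),
            "rc_tilde": dict(self.rc_tilde),
        }


def contribution_report(
    model: FactorModel,
    groups: GroupSpec | None = None,
    factor_set: dict | list | None = None,
) -> ContributionReport:
    """Full contribution report: totals, per-variable/group/factor, ECD, RC, RC~.

    ``factor_set`` maps labels to coefficient vectors (or is a plain list,
    labeled eta1, eta2, ...); by default the m coordinate factors are used,
    so ``per_factor`` reports C(xi_j -> X).
    """
    per_var = per_variable_contributions(model)
    total = float(per_var.sum())
    per_variable = dict(zip(model.variable_names, per_var.tolist()))

    per_group: dict[str, float] = {}
    if groups is not None:
        groups.validate_against(model.p)
        for name, idx in groups.groups.items():
            per_group[name] = float(per_var[idx].sum())

    if factor_set is None:
        factor_set = {
            name: np.eye(model.m)[j] for j, name in enumerate(model.factor_names)
        }
    elif not isinstance(factor_set, dict):
        factor_set = {f"eta{k + 1}": np.asarray(v) for k, v in enumerate(factor_set)}

    per_factor = {
        label: factor_contribution(model, f) for label, f in factor_set.items()
    }
    rc = {label: (c / total if total > 0 else 0.0) for label, c in per_factor.items()}
    rc_tilde = {label: c / (total + 1.0) for label, c in per_factor.items()}
    return ContributionReport(
        total_kl=total,
        per_variable=per_variable,
        per_group=per_group,
        per_factor=per_factor,
        ecd=ecd(total),
        rc=rc,
        rc_tilde=rc_tilde,
    )
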
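"""Analysis configuration and the end-to-end report workflow.

Chains the library into the two standard workflows: full-vector canonical
factor analysis, and subgroup-derived interpretable factors with their
re-expressed loadings. Produces a single JSON-serializable document.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import FactorModel, FactorModelError, GroupSpec
from .contributions import contribution_report
from .canonical import canonical_decomposition, subgroup_analysis
from .derivation import derive_factor_system, select_leading_factors
from . import io as fio
from .synthetic import builtin_fixture

__all__ = ["AnalysisConfig", "load_model", "run_analysis", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"
VALID_OUTPUTS = ("contributions", "cca", "subgroups", "derive")

log = logging.getLogger("factor_entropy")


@dataclass
class AnalysisConfig:
    """One analysis request: model source, groups, requested outputs."""

    fixture: str | None = None
    loadings_path: str | None = None
    factor_corr_path: str | None = None
    uniqueness_path: str | None = None
    recompute_uniqueness: bool = False
    groups_path: str | None = None
    derive_groups: tuple[str, ...] | None = None
    outputs: tuple[str, ...] = field(default_factory=tuple)
    out_path: str | None = None

    def validate(self) -> None:
        sources = [self.fixture is not None, self.loadings_path is not None]
        if sum(sources) != 1:
            raise FactorModelError(
                "exactly one model source required: --fixture or --loadings"
            )
        if not self.outputs:
            raise FactorModelError("requested outputs must be non-empty")
        unknown = [o for o in self.outputs if o not in VALID_OUTPUTS]
        if unknown:
            raise FactorModelError(
                f"unknown outputs {unknown}; valid: {', '.join(VALID_OUTPUTS)}"
            )


def load_model(config: AnalysisConfig) -> FactorModel:
    """Load and validate the model a config points at."""
    if config.fixture is not None:
        model = builtin_fixture(config.fixture)
        log.info("loaded fixture %s: p=%d, m=%d", config.fixture, model.p, model.m)
        return model
    loadings, vnames, fnames, uniq = fio.read_loadings_csv(config.loadings_path)
    phi = (
        fio.read_factor_corr_csv(config.factor_corr_path, fnames)
        if config.factor_corr_path
        else None
    )
    if config.uniqueness_path:
        uniq = fio.read_uniqueness_csv(config.uniqueness_path)
    recompute = config.recompute_uniqueness
    if uniq is not None and recompute:
        log.warning(
            "uniqueness supplied AND recompute flag set: recomputing as "
            "1 - communality (flag wins)"
        )
    model = fio.build_model(
        loadings,
        factor_corr=phi,
        unique_vars=None if recompute else uniq,
        recompute_uniqueness=recompute,
        variable_names=vnames,
        factor_names=fnames,
    )
    log.info(
        "loaded model: p=%d, m=%d, uniqueness %s",
        model.p,
        model.m,
        "recomputed as 1 - communality" if recompute else "as supplied",
    )
    return model


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the requested analyses and assemble the report document."""
    config.validate()
    model = load_model(config)
    groups: GroupSpec | None = None
    if config.groups_path:
        groups = fio.read_groups_json(config.groups_path, model)

    document: dict = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "p": model.p,
            "m": model.m,
            "variable_names": model.variable_names,
            "factor_names": model.factor_names,
            "loadings": model.loadings.tolist(),
            "factor_corr": model.factor_corr.tolist(),
            "unique_vars": model.unique_vars.tolist(),
        },
    }

    if "contributions" in config.outputs:
        document["contributions"] = contribution_report(model, groups=groups).to_dict()
    if "cca" in config.outputs:
        document["cca"] = canonical_decomposition(model).to_dict()
    if "subgroups" in config.outputs:
        if groups is None:
            raise FactorModelError("subgroups output requires a groups file")
        document["subgroups"] = {
            name: dec.to_dict() for name, dec in subgroup_analysis(model, groups).items()
        }
    if "derive" in config.outputs:
        if groups is None:
            raise FactorModelError("derive output requires a groups file")
        derive_spec = groups
        if config.derive_groups:
            missing = [n for n in config.derive_groups if n not in groups.groups]
            if missing:
                raise FactorModelError(f"unknown derive groups {missing}")
            derive_spec = GroupSpec(
                {n: groups.groups[n] for n in config.derive_groups}
            )
        g = select_leading_factors(model, derive_spec)
        system = derive_factor_system(
            model, g, groups=groups, factor_labels=list(derive_spec.groups)
        )
        document["derived_system"] = system.to_dict()
    return document
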
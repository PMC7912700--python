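"""Reading and writing loading matrices, group specs and reports.

Loadings CSV dialect: first column holds variable names, the header row
holds factor names, cells hold loadings; an optional trailing
``uniqueness`` column carries the unique variances. Factor correlations
are a square CSV with matching factor-name header. Groups are JSON:
``{"groups": {"name": ["X1", "X2", ...], ...}}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FactorModel, FactorModelError, GroupSpec, build_model

__all__ = [
    "read_loadings_csv",
    "read_factor_corr_csv",
    "read_uniqueness_csv",
    "read_groups_json",
    "write_model_csv",
    "write_json_report",
]

UNIQUENESS_COLUMN = "uniqueness"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise FactorModelError(f"cannot parse {path}: {err}") from err
    return frame


def _numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().any().any():
        row, col = next(
            (r, c) for r in coerced.index for c in coerced.columns
            if pd.isna(coerced.at[r, c])
        )
        raise FactorModelError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return coerced


def read_loadings_csv(path) -> tuple[np.ndarray, list[str], list[str], np.ndarray | None]:
    """Read a loadings table; returns (loadings, variable_names, factor_names, uniqueness_or_None)."""
    frame = _numeric(_read_table(path), path)
    uniqueness = None
    if UNIQUENESS_COLUMN in frame.columns:
        uniqueness = frame[UNIQUENESS_COLUMN].to_numpy(dtype=float)
        frame = frame.drop(columns=[UNIQUENESS_COLUMN])
    if frame.empty:
        raise FactorModelError(f"{path}: no factor columns found")
    return (
        frame.to_numpy(dtype=float),
        [str(v) for v in frame.index],
        [str(c) for c in frame.columns],
        uniqueness,
    )


def read_factor_corr_csv(path, factor_names: list[str] | None = None) -> np.ndarray:
    frame = _numeric(_read_table(path), path)
    mat = frame.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FactorModelError(f"{path}: factor correlation matrix must be square")
    if factor_names is not None and list(frame.columns) != list(factor_names):
        raise FactorModelError(
            f"{path}: factor names {list(frame.columns)} do not match loadings "
            f"header {list(factor_names)}"
        )
    return mat


def read_uniqueness_csv(path) -> np.ndarray:
    frame = _numeric(_read_table(path), path)
    return frame.iloc[:, 0].to_numpy(dtype=float)


def read_groups_json(path, model: FactorModel) -> GroupSpec:
    with open(path) as handle:
        try:
            payload = json.load(handle)
        except json.JSONDecodeError as err:
            raise FactorModelError(f"cannot parse {path}: {err}") from err
    if not isinstance(payload, dict) or "groups" not in payload:
        raise FactorModelError(f'{path}: expected an object with a "groups" key')
    return GroupSpec.from_names(model, payload["groups"])


def write_model_csv(model: FactorModel, path) -> None:
    """Export a model in the loadings-CSV dialect (uniqueness column included)."""
    frame = pd.DataFrame(
        model.loadings, index=model.variable_names, columns=model.factor_names
    )
    frame[UNIQUENESS_COLUMN] = model.unique_vars
    frame.to_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(document: dict, path=None) -> str:
    """Serialize a report document to JSON (optionally writing it to path)."""
    text = json.dumps(_jsonable(document), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
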
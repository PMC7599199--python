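"""File formats: structures, response tables, parameter and fit files.

Structures and response data travel as plain CSV (one state/respondent per
row, one column per item, integer level codes; responses may carry a
trailing ``frequency`` column).  Structures also round-trip through a JSON
form; parameters and fit results are JSON with full float precision and a
schema version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .em import FitResult
from .model import PolimParameters
from .monotonicity import RateParameters
from .structures import (
    Domain,
    LevelSet,
    PolytomousStructure,
    ResponseData,
    state_from_string,
    state_to_string,
)

__all__ = [
    "read_structure_csv", "write_structure_csv",
    "read_structure_json", "write_structure_json",
    "read_response_csv", "write_response_csv",
    "read_params_json", "write_params_json",
    "read_fit_json", "write_fit_json",
]

FIT_SCHEMA_VERSION = 1
FREQ_COLUMN = "frequency"


def _level_set_for(values: np.ndarray, n_levels: int | None) -> LevelSet:
    n = int(values.max()) + 1 if n_levels is None else int(n_levels)
    return LevelSet.from_count(max(n, 2))


def _validate_levels(df: pd.DataFrame, n_levels: int | None, path) -> np.ndarray:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        try:
            arr = arr.astype(np.int64)
            if not np.all(arr == df.to_numpy(dtype=float)):
                raise ValueError
        except (ValueError, TypeError):
            raise ValueError(f"{path}: all level entries must be integers")
    bad = np.argwhere(arr < 0)
    if n_levels is not None:
        bad = np.vstack([bad, np.argwhere(arr >= n_levels)])
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: level {arr[r, c]} out of range at row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return arr


def read_structure_csv(path, n_levels: int | None = None) -> PolytomousStructure:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty structure file")
    arr = _validate_levels(df, n_levels, path)
    domain = Domain(tuple(str(c) for c in df.columns))
    return PolytomousStructure(domain, _level_set_for(arr, n_levels), arr)


def write_structure_csv(structure: PolytomousStructure, path) -> None:
    pd.DataFrame(structure.states,
                 columns=[str(i) for i in structure.domain.items]
                 ).to_csv(path, index=False)


def read_structure_json(path) -> PolytomousStructure:
    with open(path) as fh:
        obj = json.load(fh)
    domain = Domain(tuple(obj["items"]))
    levels = LevelSet(tuple(obj["levels"]))
    return PolytomousStructure(domain, levels, np.asarray(obj["states"]))


def write_structure_json(structure: PolytomousStructure, path) -> None:
    obj = {
        "items": list(structure.domain.items),
        "levels": list(structure.levels.labels),
        "states": structure.states.tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def read_response_csv(path, n_levels: int | None = None) -> ResponseData:
    """Respondent-by-item CSV; a trailing ``frequency`` column is honored."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty response file")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing entries (ragged rows?)")
    freqs = None
    if df.columns[-1].lower() == FREQ_COLUMN:
        freqs = df.iloc[:, -1].to_numpy(dtype=np.int64)
        df = df.iloc[:, :-1]
    arr = _validate_levels(df, n_levels, path)
    domain = Domain(tuple(str(c) for c in df.columns))
    levels = _level_set_for(arr, n_levels)
    if freqs is None:
        return ResponseData.from_responses(arr, domain=domain, levels=levels)
    pats, inv = np.unique(arr, axis=0, return_inverse=True)
    agg = np.zeros(len(pats), dtype=np.int64)
    np.add.at(agg, inv, freqs)
    return ResponseData(pats, agg, domain=domain, levels=levels)


def write_response_csv(data: ResponseData, path, aggregated: bool = True) -> None:
    cols = [str(i) for i in data.domain.items]
    if aggregated:
        df = pd.DataFrame(data.patterns, columns=cols)
        df[FREQ_COLUMN] = data.frequencies
    else:
        df = pd.DataFrame(data.expand(), columns=cols)
    df.to_csv(path, index=False)


def _params_to_obj(params: PolimParameters) -> dict:
    struct = params.structure
    return {
        "items": list(struct.domain.items),
        "levels": list(struct.levels.labels),
        "epsilon": {str(item): params.epsilon[q].tolist()
                    for q, item in enumerate(struct.domain.items)},
        "pi": {s: float(p) for s, p in zip(struct.state_strings(), params.pi)},
    }


def _params_from_obj(obj: dict) -> PolimParameters:
    domain = Domain(tuple(obj["items"]))
    levels = LevelSet(tuple(obj["levels"]))
    n_items, n_levels = len(domain), len(levels)
    states = [state_from_string(s, n_items, n_levels) for s in obj["pi"]]
    structure = PolytomousStructure(domain, levels, states)
    eps = np.stack([np.asarray(obj["epsilon"][str(item)], dtype=float)
                    for item in domain.items])
    pi = np.array([obj["pi"][s] for s in structure.state_strings()])
    return PolimParameters(structure, eps, pi)


def write_params_json(params: PolimParameters, path) -> None:
    Path(path).write_text(json.dumps(_params_to_obj(params)))


def read_params_json(path) -> PolimParameters:
    with open(path) as fh:
        return _params_from_obj(json.load(fh))


def write_fit_json(result: FitResult, path) -> None:
    obj = {
        "schema_version": FIT_SCHEMA_VERSION,
        "params": _params_to_obj(result.params),
        "loglik_trace": [float(x) for x in result.loglik_trace],
        "iterations": result.iterations,
        "converged": result.converged,
        "seed": result.seed,
        "settings": result.settings,
    }
    if result.rates is not None:
        obj["rates"] = [
            {"item": str(r.item), "omega": r.omega.tolist(),
             "upsilon": r.upsilon.tolist()} for r in result.rates
        ]
    Path(path).write_text(json.dumps(obj))


def read_fit_json(path) -> FitResult:
    with open(path) as fh:
        obj = json.load(fh)
    version = obj.get("schema_version")
    if version != FIT_SCHEMA_VERSION:
        raise ValueError(
            f"fit file schema version {version!r} unsupported "
            f"(expected {FIT_SCHEMA_VERSION})"
        )
    rates = None
    if "rates" in obj:
        rates = [
            RateParameters(r["item"], np.asarray(r["omega"], dtype=float),
                           np.asarray(r["upsilon"], dtype=float))
            for r in obj["rates"]
        ]
    return FitResult(
        params=_params_from_obj(obj["params"]),
        loglik_trace=obj["loglik_trace"],
        iterations=obj["iterations"],
        converged=obj["converged"],
        seed=obj.get("seed"),
        rates=rates,
        settings=obj.get("settings", {}),
    )
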
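"""CSV/JSON/YAML readers and writers shared by the CLI and examples.

Conventions: comma-separated, "." decimal, mandatory header row, UTF-8.
Missing values are an error — these are small numeric design matrices,
not general tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DlassoConfig, FittedModel
from .simulate import SimulatedDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_coefficients",
    "write_json",
    "write_simulated",
    "resolve_config",
]


def read_dataset(path: str | Path, target: str):
    """Read a CSV with header into (X, y, feature_names).

    The ``target`` column becomes y; the remaining columns, in file
    order, become the feature matrix.  All columns must be numeric and
    complete.
    """
    path = Path(path)
    # correctly-rounded parsing so writes round-trip bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    if target not in df.columns:
        raise ValueError(
            f"target column {target!r} not found in {path.name}; "
            f"available columns: {list(df.columns)}"
        )
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.flatnonzero(bad.isna())[0])
            raise ValueError(
                f"non-numeric or missing value at row {row}, column {col!r}"
            )
    y = df[target].to_numpy(dtype=float)
    features = [c for c in df.columns if c != target]
    X = df[features].to_numpy(dtype=float)
    return X, y, features


def write_dataset(path: str | Path, X, y, feature_names=None, target: str = "y"):
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    df[target] = np.asarray(y)
    # %.17g guarantees bit-exact float round-trips through text
    df.to_csv(path, index=False, float_format="%.17g")


def write_coefficients(path: str | Path, model: FittedModel, feature_names=None):
    """Fitted coefficients as CSV: feature, beta_hat, selected."""
    p = model.beta_hat.shape[0]
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    pd.DataFrame({
        "feature": feature_names,
        "beta_hat": model.beta_hat,
        "selected": model.beta_hat != 0,
    }).to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def write_json(path: str | Path, payload: dict):
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def write_simulated(prefix: str | Path, ds: SimulatedDataset):
    """Write a simulated dataset as train/test CSVs plus a JSON sidecar
    carrying the true coefficients and generation metadata."""
    prefix = Path(prefix)
    write_dataset(prefix.with_suffix(".train.csv"), ds.X_train, ds.y_train)
    write_dataset(prefix.with_suffix(".test.csv"), ds.X_test, ds.y_test)
    write_json(prefix.with_suffix(".meta.json"),
               {"beta_true": ds.beta_true, "meta": ds.meta})


def resolve_config(
    config_file: str | Path | None = None, **cli_overrides
) -> DlassoConfig:
    """Merge built-in defaults, a YAML config file and CLI flags.

    Precedence: CLI flag > config file > built-in default.  CLI
    overrides with value None are treated as "not given".
    """
    merged: dict = {}
    if config_file is not None:
        loaded = yaml.safe_load(Path(config_file).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {config_file} must contain a mapping")
        unknown = set(loaded) - set(DlassoConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged.update(loaded)
    merged.update({k: v for k, v in cli_overrides.items() if v is not None})
    return DlassoConfig(**merged)
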
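"""Reading and writing GBD-dialect burden CSVs and standard-population weights."""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    COLUMNS,
    SchemaError,
    normalize_age,
    normalize_measure,
    normalize_metric,
    normalize_sex,
    validate_burden,
)

_FLOAT_FMT = "%.6g"


def read_burden_csv(path: str | Path, check_identities: bool = True) -> pd.DataFrame:
    """Read a burden table in the GBD results-tool CSV dialect.

    The header is matched case-insensitively and order-free; labels are
    normalized to the canonical vocabulary. Raises :class:`SchemaError` for
    unknown columns or labels and :class:`ValidationError` (with row indices)
    for rows breaking ``lower <= val <= upper`` or the additive identities.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[list(COLUMNS)]

    df["measure"] = df["measure"].map(normalize_measure)
    df["sex"] = df["sex"].map(normalize_sex)
    df["age"] = df["age"].map(normalize_age)
    df["metric"] = df["metric"].map(normalize_metric)
    df["year"] = df["year"].astype(int)
    for col in ("val", "upper", "lower"):
        df[col] = df[col].astype(float)

    # identities are checked to the precision the 6-significant-digit CSV
    # format can carry, not the generator's in-memory 1e-9
    return validate_burden(df, check_identities=check_identities, identity_rtol=1e-4)


def write_burden_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a burden table with bit-stable column order and float formatting.

    Floats are rendered with 6 significant digits so that diffs between runs
    are meaningful.
    """
    path = Path(path)
    out = table[list(COLUMNS)]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_standard_population(path: str | Path | None = None) -> pd.Series:
    """Read age-bin standardization weights from a 2-column (age, weight) CSV.

    With no path, loads the packaged WHO World Standard Population (2000-2025)
    5-year weights. Weights are normalized to sum to exactly 1. Note that GBD
    uses its own internal standard population; replicating GBD-published ASRs
    exactly requires supplying those weights.
    """
    if path is None:
        ref = importlib.resources.files("burdenqci").joinpath("data/who_world_standard.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"age", "weight"} <= set(df.columns):
        raise SchemaError("standard population CSV needs columns: age, weight")
    ages = df["age"].map(normalize_age)
    weights = df["weight"].astype(float)
    if (weights < 0).any():
        raise SchemaError("standard-population weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise SchemaError("standard-population weights sum to zero")
    series = pd.Series(np.asarray(weights) / total, index=list(ages), name="weight")
    series.index.name = "age"
    return series


def write_standard_population(std: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"age": std.index, "weight": std.values})
    df.to_csv(path, index=False, float_format="%.10g")
    return path
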
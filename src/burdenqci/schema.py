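"""Canonical vocabulary and validation for GBD-dialect burden tables.

The long format used by the GBD results tool has nine columns
(measure, location, sex, age, year, metric, val, upper, lower). This module
is the single point of truth for the label vocabulary: labels are normalized
to short canonical strings on read ("15-19", "all-ages", "dalys", ...) so
that the rest of the package never has to match the results-tool spelling
("15-19 years", "All ages", "DALYs (Disability-Adjusted Life Years)").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MEASURES = ("incidence", "prevalence", "deaths", "ylls", "ylds", "dalys")
METRICS = ("number", "rate")
SEXES = ("female", "male", "both")

#: 5-year age bins spanning 0 to 95+, in ascending order.
AGE_BINS = (
    "<5",
    "5-9",
    "10-14",
    "15-19",
    "20-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90-94",
    "95+",
)

AGE_ALL = "all-ages"
AGE_STD = "age-standardized"
AGE_LABELS = AGE_BINS + (AGE_ALL, AGE_STD)

COLUMNS = ("measure", "location", "sex", "age", "year", "metric", "val", "upper", "lower")

# Results-tool spellings accepted on read (lower-cased before lookup).
_MEASURE_ALIASES = {
    "incidence": "incidence",
    "prevalence": "prevalence",
    "deaths": "deaths",
    "death": "deaths",
    "ylls": "ylls",
    "ylls (years of life lost)": "ylls",
    "ylds": "ylds",
    "ylds (years lived with disability)": "ylds",
    "dalys": "dalys",
    "dalys (disability-adjusted life years)": "dalys",
}

_SEX_ALIASES = {"female": "female", "male": "male", "both": "both", "both sexes": "both"}

_AGE_ALIASES = {label.lower(): label for label in AGE_LABELS}
_AGE_ALIASES.update({f"{label} years".lower(): label for label in AGE_BINS})
_AGE_ALIASES.update(
    {
        "all ages": AGE_ALL,
        "age-standardized": AGE_STD,
        "age standardized": AGE_STD,
        "<5 years": "<5",
        "under 5": "<5",
        "95 plus": "95+",
    }
)


class SchemaError(ValueError):
    """A column or label does not belong to the GBD-dialect vocabulary."""


class ValidationError(ValueError):
    """Rows violate a table invariant (e.g. lower > val); carries row indices."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


def normalize_measure(value: str) -> str:
    try:
        return _MEASURE_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise SchemaError(f"unknown measure label: {value!r}") from None


def normalize_sex(value: str) -> str:
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise SchemaError(f"unknown sex label: {value!r}") from None


def normalize_age(value: str) -> str:
    try:
        return _AGE_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise SchemaError(f"unknown age label: {value!r}") from None


def normalize_metric(value: str) -> str:
    metric = str(value).strip().lower()
    if metric not in METRICS:
        raise SchemaError(f"unknown metric label: {value!r}")
    return metric


def age_midpoint(age_bin: str) -> float:
    """Midpoint in years of a 5-year age bin; the open 95+ bin uses 97.5."""
    if age_bin == "<5":
        return 2.5
    if age_bin == "95+":
        return 97.5
    if age_bin in (AGE_ALL, AGE_STD):
        raise ValueError(f"aggregate label {age_bin!r} has no midpoint")
    lo, hi = age_bin.split("-")
    return (int(lo) + int(hi) + 1) / 2.0


def validate_burden(
    df: pd.DataFrame, check_identities: bool = True, identity_rtol: float = 1e-9
) -> pd.DataFrame:
    """Validate a burden table against the schema invariants.

    Checks per-row bounds (lower <= val <= upper, non-negative values) and,
    when ``check_identities`` and the relevant strata are present, the
    additive identities both = female + male (numbers) and
    dalys = ylls + ylds. Returns the (unchanged) frame; raises
    :class:`ValidationError` listing offending row indices otherwise.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    bad = df.index[(df["lower"] > df["val"]) | (df["val"] > df["upper"])].tolist()
    if bad:
        raise ValidationError(
            f"{len(bad)} rows violate lower <= val <= upper (rows {bad[:10]}...)"
            if len(bad) > 10
            else f"rows violate lower <= val <= upper: {bad}",
            rows=bad,
        )
    neg = df.index[(df[["val", "upper", "lower"]] < 0).any(axis=1)].tolist()
    if neg:
        raise ValidationError(f"rows with negative values: {neg}", rows=neg)

    for col, normalizer in [
        ("measure", normalize_measure),
        ("sex", normalize_sex),
        ("age", normalize_age),
        ("metric", normalize_metric),
    ]:
        for value in df[col].unique():
            normalizer(value)

    if check_identities:
        _check_additive_identities(df, rtol=identity_rtol)
    return df


def _check_additive_identities(df: pd.DataFrame, rtol: float = 1e-9) -> None:
    num = df[df["metric"] == "number"]
    if num.empty:
        return
    key = ["measure", "location", "age", "year"]

    by_sex = num.pivot_table(index=key, columns="sex", values="val", aggfunc="first")
    if {"female", "male", "both"} <= set(by_sex.columns):
        complete = by_sex.dropna(subset=["female", "male", "both"])
        total = complete["female"] + complete["male"]
        off = ~np.isclose(complete["both"], total, rtol=rtol, atol=1e-12)
        if off.any():
            raise ValidationError(
                f"both-sex numbers differ from female+male on {int(off.sum())} strata"
            )

    key2 = ["location", "sex", "age", "year"]
    by_measure = num.pivot_table(index=key2, columns="measure", values="val", aggfunc="first")
    if {"ylls", "ylds", "dalys"} <= set(by_measure.columns):
        complete = by_measure.dropna(subset=["ylls", "ylds", "dalys"])
        total = complete["ylls"] + complete["ylds"]
        off = ~np.isclose(complete["dalys"], total, rtol=rtol, atol=1e-12)
        if off.any():
            raise ValidationError(
                f"dalys differ from ylls+ylds on {int(off.sum())} strata"
            )
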
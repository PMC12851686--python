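"""Direct age-standardization, endpoint percent change, and EAPC.

The estimated annual percentage change (EAPC) summarizes the log-linear
trend of an age-standardized rate (ASR) series: ordinary least squares of
ln(ASR) on calendar year gives slope b1, and EAPC = (exp(b1) - 1) x 100 with
a 95% CI from b1 +/- 1.96 se. The normal multiplier (rather than a
t-quantile) is used: with three decades of yearly points the difference is
negligible, and ``z`` can be overridden for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import AGE_STD


@dataclass(frozen=True)
class EAPCResult:
    """Log-linear trend fit of an ASR series.

    beta0/beta1 are the intercept and per-year slope of ln(ASR);
    eapc and the CI bounds are percents.
    """

    beta0: float
    beta1: float
    se_beta1: float
    eapc: float
    ci_low: float
    ci_high: float
    n_years: int


def age_standardize(counts: pd.Series, pop: pd.Series, std: pd.Series) -> float:
    """Directly age-standardized rate per 100,000.

    ASR = sum_a w_a * (count_a / pop_a) * 1e5 with standard weights w_a
    (renormalized over the bins present). A bin with zero population and
    zero count contributes 0; zero population with a positive count is an
    undefined rate and raises.
    """
    counts, pop = counts.align(pop, join="inner")
    if counts.empty:
        raise ValueError("counts and population share no age bins")
    w = std.reindex(counts.index)
    if w.isna().any():
        missing = list(w.index[w.isna()])
        raise ValueError(f"standard population misses bins {missing}")
    w = w / w.sum()

    c, p = counts.to_numpy(float), pop.to_numpy(float)
    undefined = (p == 0) & (c > 0)
    if undefined.any():
        raise ZeroDivisionError(
            f"zero population with positive counts in bins {list(counts.index[undefined])}"
        )
    rate = np.divide(c, p, out=np.zeros_like(c), where=p > 0)
    return float((w.to_numpy() * rate).sum() * 1e5)


def percent_change(v_start: float, v_end: float) -> float:
    """Endpoint percent change (v_end - v_start) / v_start * 100."""
    if v_start <= 0:
        raise ValueError("percent change needs a positive starting value")
    if v_end < 0:
        raise ValueError("end value must be non-negative")
    return (v_end - v_start) / v_start * 100.0


def share(part: float, whole: float) -> float:
    """Percentage share part / whole * 100."""
    if whole <= 0:
        raise ValueError("share needs a positive denominator")
    if part < 0:
        raise ValueError("part must be non-negative")
    return part / whole * 100.0


def eapc(years, asr, z: float = 1.96) -> EAPCResult:
    """Estimated annual percentage change of an ASR series.

    Fits ln(ASR) = b0 + b1*year by OLS and returns
    EAPC = (exp(b1) - 1) x 100 with CI (exp(b1 -/+ z*se) - 1) x 100.
    Requires >= 3 points and strictly positive rates.
    """
    years = np.asarray(years, float)
    asr = np.asarray(asr, float)
    if years.shape != asr.shape or years.ndim != 1:
        raise ValueError("years and asr must be equal-length 1-D sequences")
    if len(years) < 3:
        raise ValueError("EAPC needs at least 3 time points")
    if (asr <= 0).any():
        raise ValueError("EAPC is undefined for non-positive rates (log-linear model)")

    fit = stats.linregress(years, np.log(asr))
    se = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    value = (np.exp(fit.slope) - 1.0) * 100.0
    lo = (np.exp(fit.slope - z * se) - 1.0) * 100.0
    hi = (np.exp(fit.slope + z * se) - 1.0) * 100.0
    return EAPCResult(
        beta0=float(fit.intercept),
        beta1=float(fit.slope),
        se_beta1=se,
        eapc=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        n_years=len(years),
    )


def asr_series(
    burden: pd.DataFrame,
    pop: pd.DataFrame,
    std: pd.Series,
    measure: str,
    location: str,
    sex: str,
) -> pd.Series:
    """Per-year ASR computed from age-specific counts and population.

    Recomputes the standardization from the number rows rather than trusting
    stored age-standardized rows, so a custom standard population can be
    applied to any table.
    """
    sub = burden[
        (burden["measure"] == measure)
        & (burden["location"] == location)
        & (burden["sex"] == sex)
        & (burden["metric"] == "number")
        & burden["age"].isin(std.index)
    ]
    if sub.empty:
        raise ValueError(f"no age-specific number rows for {measure}/{location}/{sex}")
    psub = pop[pop["location"] == location]
    if sex == "both" and "both" not in set(psub["sex"]):
        psub = psub.groupby(["location", "age", "year"], as_index=False)["persons"].sum()
    else:
        psub = psub[psub["sex"] == sex]
    out = {}
    for year, grp in sub.groupby("year"):
        counts = grp.set_index("age")["val"]
        p = psub[psub["year"] == year].set_index("age")["persons"]
        out[year] = age_standardize(counts, p, std)
    return pd.Series(out, name="asr").sort_index()


def eapc_table(
    burden: pd.DataFrame, measures=None, locations=None, sexes=("both",), z: float = 1.96
) -> pd.DataFrame:
    """EAPC per (measure, location, sex) from stored age-standardized rate rows."""
    std_rows = burden[(burden["age"] == AGE_STD) & (burden["metric"] == "rate")]
    rows = []
    for (m, loc, sex), grp in std_rows.groupby(["measure", "location", "sex"]):
        if measures is not None and m not in measures:
            continue
        if locations is not None and loc not in locations:
            continue
        if sexes is not None and sex not in sexes:
            continue
        grp = grp.sort_values("year")
        res = eapc(grp["year"].to_numpy(), grp["val"].to_numpy(), z=z)
        rows.append(
            {
                "measure": m,
                "location": loc,
                "sex": sex,
                "eapc": res.eapc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "beta1": res.beta1,
                "se_beta1": res.se_beta1,
                "n_years": res.n_years,
            }
        )
    return pd.DataFrame(rows)
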
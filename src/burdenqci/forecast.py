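"""Box-Jenkins ARIMA(p,d,q) projection of burden-rate series.

Order selection replaces visual ACF/PACF identification with a reproducible
procedure: the differencing order d is the smallest order (capped at 2) at
which the augmented Dickey-Fuller test rejects non-stationarity at 0.05;
candidate (p, q) orders up to configurable maxima are fitted by maximum
likelihood and ranked by AIC or BIC; residual whiteness of the winner is
summarized by the Ljung-Box p-value at lag min(10, n/5). ACF/PACF values are
attached for inspection. Forecasts carry model-based Gaussian 95% intervals.

Three decades of annual observations is short for ARIMA; fits on fewer than
30 points trigger a warning and projections should be read as extrapolative
baselines, not scenario forecasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf, adfuller, pacf


@dataclass
class ArimaFit:
    """Selected ARIMA model with diagnostics and projections."""

    order: tuple[int, int, int]
    params: pd.Series
    bse: pd.Series
    aic: float
    bic: float
    ljung_box_p: float
    adf_p_by_d: list[float]
    forecasts: pd.DataFrame  # columns: year, point, lo95, hi95
    acf: np.ndarray = field(repr=False, default=None)
    pacf: np.ndarray = field(repr=False, default=None)
    candidates: pd.DataFrame = field(repr=False, default=None)
    degenerate: bool = False


def _choose_d(values: np.ndarray, alpha: float = 0.05, d_max: int = 2) -> tuple[int, list[float]]:
    pvals = []
    x = values.astype(float)
    for d in range(d_max + 1):
        series = np.diff(x, n=d) if d else x
        if np.allclose(series, series[0]):
            # constant after differencing: trivially stationary
            pvals.append(0.0)
            return d, pvals
        try:
            p = float(adfuller(series, autolag="AIC")[1])
        except Exception:
            p = 1.0
        pvals.append(p)
        if p < alpha:
            return d, pvals
    return d_max, pvals


def fit_arima(
    years,
    values,
    horizon: int,
    p_max: int = 3,
    q_max: int = 3,
    criterion: str = "aic",
    d: int | None = None,
    seed: int | None = None,
) -> ArimaFit:
    """Select, fit and project an ARIMA model for an annual series.

    Parameters
    ----------
    years, values
        Annual observations (>= 15 points; consecutive years).
    horizon
        Last calendar year to project (beyond the observed range).
    criterion
        "aic" or "bic" ranking of the (p, q) grid.
    d
        Force the differencing order instead of choosing it by sequential
        ADF testing.
    seed
        Accepted for interface uniformity; the ML fit itself is
        deterministic.
    """
    years = np.asarray(years, int)
    x = np.asarray(values, float)
    if years.ndim != 1 or years.shape != x.shape:
        raise ValueError("years and values must be equal-length 1-D sequences")
    if not np.all(np.diff(years) == 1):
        raise ValueError("series must be annual and gap-free")
    n = len(x)
    if n < 15:
        raise ValueError(f"need >= 15 observations, got {n}")
    if n < 30:
        warnings.warn(
            f"{n} observations is short for ARIMA; treat projections as a baseline",
            stacklevel=2,
        )
    if horizon <= years[-1]:
        raise ValueError("horizon must lie beyond the last observed year")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    steps = int(horizon - years[-1])
    future_years = np.arange(years[-1] + 1, horizon + 1)

    if np.allclose(x, x[0]):
        fc = pd.DataFrame(
            {"year": future_years, "point": x[0], "lo95": x[0], "hi95": x[0]}
        )
        return ArimaFit(
            order=(0, 0, 0),
            params=pd.Series({"const": x[0]}),
            bse=pd.Series({"const": 0.0}),
            aic=float("nan"),
            bic=float("nan"),
            ljung_box_p=float("nan"),
            adf_p_by_d=[0.0],
            forecasts=fc,
            degenerate=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_auto, adf_ps = _choose_d(x)
    if d is None:
        d = d_auto
    elif not 0 <= d <= 2:
        raise ValueError("d must be 0, 1 or 2")
    lb_lag = max(1, min(10, n // 5))

    rows, fits = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(p_max + 1):
            for q in range(q_max + 1):
                trend = "c" if d == 0 else ("t" if d == 1 else None)
                try:
                    res = ARIMA(x, order=(p, d, q), trend=trend).fit()
                except Exception:
                    continue
                if not np.isfinite(res.aic):
                    continue
                rows.append({"p": p, "d": d, "q": q, "aic": res.aic, "bic": res.bic})
                fits[(p, q)] = res
    if not fits:
        attempted = [(p, d, q) for p in range(p_max + 1) for q in range(q_max + 1)]
        raise RuntimeError(f"no ARIMA candidate converged; attempted {attempted}")

    cand = pd.DataFrame(rows).sort_values(criterion, kind="stable").reset_index(drop=True)
    p_sel, q_sel = int(cand.loc[0, "p"]), int(cand.loc[0, "q"])
    best = fits[(p_sel, q_sel)]

    resid = best.resid[d:]  # drop differencing burn-in
    try:
        lb = acorr_ljungbox(resid, lags=[lb_lag], model_df=0)
        lb_p = float(lb["lb_pvalue"].iloc[0])
    except Exception:
        lb_p = float("nan")

    pred = best.get_forecast(steps=steps)
    ci = pred.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    fc = pd.DataFrame(
        {
            "year": future_years,
            "point": np.asarray(pred.predicted_mean),
            "lo95": ci[:, 0],
            "hi95": ci[:, 1],
        }
    )

    nlags = min(10, n // 2 - 1)
    return ArimaFit(
        order=(p_sel, d, q_sel),
        params=pd.Series(best.params, index=best.param_names),
        bse=pd.Series(best.bse, index=best.param_names),
        aic=float(best.aic),
        bic=float(best.bic),
        ljung_box_p=lb_p,
        adf_p_by_d=adf_ps,
        forecasts=fc,
        acf=acf(x, nlags=nlags, fft=True),
        pacf=pacf(x, nlags=nlags),
        candidates=cand,
    )
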
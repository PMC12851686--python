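"""Quality of Care Index (QCI): ratio indices -> PCA -> 0-100 composite.

Four secondary indices are derived from age-standardized primary measures of
a stratum x (a region-year-sex or region-year-sex-age cell):

* prevalence/incidence   -- disease control and survival (higher = better)
* deaths/incidence (MIR) -- fatal outcome per new case (higher = worse)
* DALY/prevalence        -- burden per prevalent case (higher = worse)
* YLL/YLD                -- fatal vs non-fatal burden mix (higher = worse)

The composite is built by principal component analysis of the z-standardized
indices (eigendecomposition of their correlation matrix): the first two
components are combined with weights proportional to their explained
variance, each component's sign oriented so that it correlates non-positively
with MIR (higher score = better care), and the weighted score is min-max
scaled to 0-100 over a scaling pool.

The DALY-based index divides by prevalence by default ("burden per prevalent
case"); ``daly_denominator="incidence"`` switches to dividing by incidence
for sensitivity analysis, since both conventions appear in the applied
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import AGE_STD

RATIO_COLUMNS = ("prev_inc", "mir", "daly_prev", "yll_yld")

#: Orientation metadata: +1 means higher raw ratio = better care.
ORIENTATION = {"prev_inc": +1, "mir": -1, "daly_prev": -1, "yll_yld": -1}


class DegeneratePoolError(ValueError):
    """The observation pool cannot support a PCA (too small or rank-deficient)."""


@dataclass
class RatioIndices:
    """Per-stratum secondary ratio indices with exclusion bookkeeping."""

    values: pd.DataFrame  # indexed by stratum, columns RATIO_COLUMNS
    excluded: pd.DataFrame  # strata dropped for zero denominators, with reason
    orientation: dict = field(default_factory=lambda: dict(ORIENTATION))


@dataclass
class QCIResult:
    """PCA loadings, variance weights, scores and the scaled 0-100 index."""

    loadings: pd.DataFrame  # index: ratio columns used; columns: PC1, PC2
    var_pc1: float
    var_pc2: float
    weight1: float
    weight2: float
    pca_score: pd.Series
    qci: pd.Series
    orientation_flipped: tuple[bool, bool]
    dropped_constant: tuple[str, ...] = ()


def compute_ratios(
    burden: pd.DataFrame,
    stratify: tuple[str, ...] = ("location", "year", "sex"),
    age: str | None = AGE_STD,
    metric: str = "rate",
    daly_denominator: str = "prevalence",
) -> RatioIndices:
    """Derive the four ratio indices per stratum from a burden table.

    With ``age=AGE_STD`` (default) the age-standardized rate rows feed a
    region-year-sex QCI; passing ``age=None`` with ``"age" in stratify``
    builds age-specific indices instead. Strata with a zero denominator
    (incidence, prevalence or YLD) are excluded and reported in
    ``result.excluded`` rather than silently dropped.
    """
    if daly_denominator not in ("prevalence", "incidence"):
        raise ValueError("daly_denominator must be 'prevalence' or 'incidence'")
    sub = burden[burden["metric"] == metric]
    if age is not None:
        sub = sub[sub["age"] == age]
    else:
        sub = sub[~sub["age"].isin(["all-ages", AGE_STD])]
    if (sub["val"] < 0).any():
        raise ValueError("negative values in burden table")

    wide = sub.pivot_table(index=list(stratify), columns="measure", values="val", aggfunc="first")
    needed = ["incidence", "prevalence", "deaths", "dalys", "ylls", "ylds"]
    missing = [m for m in needed if m not in wide.columns]
    if missing:
        raise ValueError(f"measures missing from table: {missing}")
    wide = wide.dropna(subset=needed)

    bad_inc = wide["incidence"] == 0
    bad_prev = wide["prevalence"] == 0
    bad_yld = wide["ylds"] == 0
    reasons = pd.Series("", index=wide.index, dtype=object)
    reasons[bad_inc] += "incidence=0;"
    reasons[bad_prev] += "prevalence=0;"
    reasons[bad_yld] += "yld=0;"
    excluded = pd.DataFrame({"reason": reasons[reasons != ""]})
    keep = wide[reasons == ""]

    daly_den = keep[daly_denominator]
    values = pd.DataFrame(
        {
            "prev_inc": keep["prevalence"] / keep["incidence"],
            "mir": keep["deaths"] / keep["incidence"],
            "daly_prev": keep["dalys"] / daly_den,
            "yll_yld": keep["ylls"] / keep["ylds"],
        }
    )
    return RatioIndices(values=values, excluded=excluded)


def compute_qci(
    ratios: RatioIndices | pd.DataFrame,
    scaling_pool: pd.Index | None = None,
    log_transform: bool = False,
) -> QCIResult:
    """Build the QCI from ratio indices over a pool of observations.

    z-standardizes each index over the pool, eigendecomposes the 4x4
    correlation matrix, combines the top two components with
    variance-proportional weights, and min-max scales to [0, 100] over
    ``scaling_pool`` (default: all observations). Constant columns are
    dropped (they carry no comparative information); a pool with fewer than
    3 observations or fewer than 2 varying indices raises
    :class:`DegeneratePoolError`. A pool in which the weighted score is
    constant maps every observation to 100.
    """
    X = ratios.values if isinstance(ratios, RatioIndices) else ratios
    X = X.astype(float)
    if X.shape[0] < 3:
        raise DegeneratePoolError(f"need >= 3 observations, got {X.shape[0]}")
    if log_transform:
        if (X <= 0).any().any():
            raise ValueError("log transform requires strictly positive ratios")
        X = np.log(X)

    # a column is constant when its spread is zero relative to its magnitude;
    # exact-zero detection misses ratios that are constant by construction but
    # carry ~1e-16 float noise, whose z-scores would be amplified garbage
    sd = X.std(ddof=1)
    scale = X.abs().mean().replace(0.0, 1.0)
    constant = sd[(sd / scale) <= 1e-12].index.tolist()
    kept = [c for c in X.columns if c not in constant]
    if not kept:
        # all observations identical: min-max scaling is degenerate and every
        # stratum is defined to attain the top of the scale
        const_score = pd.Series(0.0, index=X.index, name="pca_score")
        return QCIResult(
            loadings=pd.DataFrame(columns=["PC1", "PC2"]),
            var_pc1=0.0,
            var_pc2=0.0,
            weight1=0.5,
            weight2=0.5,
            pca_score=const_score,
            qci=pd.Series(100.0, index=X.index, name="qci"),
            orientation_flipped=(False, False),
            dropped_constant=tuple(constant),
        )
    if len(kept) < 2:
        raise DegeneratePoolError(
            f"fewer than 2 varying indices (constant columns: {constant})"
        )
    Z = (X[kept] - X[kept].mean()) / X[kept].std(ddof=1)

    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise DegeneratePoolError("correlation matrix is not finite")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam1, lam2 = float(max(eigval[0], 0.0)), float(max(eigval[1], 0.0))
    if lam1 + lam2 <= 0:
        raise DegeneratePoolError("top two eigenvalues are zero")

    v1, v2 = eigvec[:, 0].copy(), eigvec[:, 1].copy()
    scores = [Z.to_numpy() @ v1, Z.to_numpy() @ v2]
    flipped = []
    badness = _badness_reference(Z)
    for i, v in enumerate((v1, v2)):
        c = _corr_or_zero(scores[i], badness)
        if c > 0:
            v *= -1.0
            scores[i] = -scores[i]
            flipped.append(True)
        else:
            flipped.append(False)

    w1 = lam1 / (lam1 + lam2)
    w2 = 1.0 - w1
    pca_score = pd.Series(w1 * scores[0] + w2 * scores[1], index=Z.index, name="pca_score")

    pool = pca_score if scaling_pool is None else pca_score.loc[scaling_pool]
    lo, hi = float(pool.min()), float(pool.max())
    if hi > lo:
        qci = (pca_score - lo) / (hi - lo) * 100.0
    else:
        qci = pd.Series(100.0, index=pca_score.index)
    qci = qci.clip(0.0, 100.0).rename("qci")

    loadings = pd.DataFrame({"PC1": v1, "PC2": v2}, index=kept)
    return QCIResult(
        loadings=loadings,
        var_pc1=lam1,
        var_pc2=lam2,
        weight1=w1,
        weight2=w2,
        pca_score=pca_score,
        qci=qci,
        orientation_flipped=tuple(flipped),
        dropped_constant=tuple(constant),
    )


def _badness_reference(Z: pd.DataFrame) -> np.ndarray:
    """Reference 'worse care' direction used to orient component signs.

    MIR when it varies in the pool, otherwise the mean of the z-scored
    indices flagged higher-is-worse (sign-flipping the better-is-higher ones).
    """
    if "mir" in Z.columns:
        return Z["mir"].to_numpy()
    signed = [-ORIENTATION[c] * Z[c].to_numpy() for c in Z.columns]
    return np.mean(signed, axis=0)


def _corr_or_zero(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def qci_by_age_sex(
    burden: pd.DataFrame,
    pool_policy: str = "global",
    daly_denominator: str = "prevalence",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Age- and sex-stratified QCI table from age-specific rates.

    ``pool_policy`` controls the PCA/min-max pool: "global" pools every
    (location, year, sex, age) observation in one run, keeping scores
    comparable across years and regions; "per-year" repeats the construction
    within each calendar year. Returns a tidy frame with the four ratios,
    the weighted PCA score and the 0-100 QCI per stratum.
    """
    if pool_policy not in ("global", "per-year"):
        raise ValueError("pool_policy must be 'global' or 'per-year'")
    ratios = compute_ratios(
        burden,
        stratify=("location", "year", "sex", "age"),
        age=None,
        daly_denominator=daly_denominator,
    )

    frames = []
    if pool_policy == "global":
        res = compute_qci(ratios, log_transform=log_transform)
        frames.append(_tidy(ratios, res))
    else:
        years = ratios.values.index.get_level_values("year")
        for year in sorted(set(years)):
            sub = RatioIndices(
                values=ratios.values[years == year],
                excluded=ratios.excluded,
                orientation=ratios.orientation,
            )
            res = compute_qci(sub, log_transform=log_transform)
            frames.append(_tidy(sub, res))
    return pd.concat(frames).reset_index()


def _tidy(ratios: RatioIndices, res: QCIResult) -> pd.DataFrame:
    out = ratios.values.copy()
    out["pca_score"] = res.pca_score
    out["qci"] = res.qci
    return out
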
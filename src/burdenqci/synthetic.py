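"""Synthetic GBD-shaped burden and population tables with known ground truth.

Every downstream stage (age-standardization, EAPC, joinpoint, decomposition,
QCI, forecasting) is tested by parameter recovery on data from this
generator, which emulates the stratification of a GBD extract: 5-year age
bins, both sexes, multi-decade annual series with log-linear trends of
configurable annual percent change, a Gaussian age pattern with configurable
peak, a female:male rate ratio, the DALY = YLL + YLD identity, and a
population whose age structure drifts (aging) while its size grows.

The generator is intentionally simpler than real GBD estimates: no
covariates, no draw-level uncertainty (upper/lower are normal-approximation
bands), no cohort effects, and noise that is independent across strata.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .io import read_standard_population
from .schema import AGE_ALL, AGE_BINS, AGE_STD, MEASURES, age_midpoint

#: Measures the generator draws directly; ylls/ylds are split off dalys.
_BASE_MEASURES = ("incidence", "prevalence", "deaths", "dalys")


class ScenarioConfig(BaseModel):
    """Ground-truth parameters of a synthetic burden scenario.

    Rates are per 100,000 person-years at the age-pattern mode for males in
    the first year; the age pattern is Gaussian over bin midpoints; rates for
    females are multiplied by ``sex_ratio``; each measure's rate grows by
    ``trend_apc`` percent per year. Bimodal age patterns can be produced by
    summing the burden tables of two configs sharing a population.
    """

    years: tuple[int, int] = (1990, 2021)
    age_bins: tuple[str, ...] = AGE_BINS
    sexes: tuple[str, ...] = ("female", "male")
    locations: tuple[str, ...] = ("Simland",)
    base_pop: float = Field(2e7, gt=0, description="persons per location in the first year")
    pop_growth: float = Field(0.008, ge=-0.5, description="annual proportional growth")
    aging_shift: float = Field(0.15, description="annual shift of the population age mode, years")
    pop_age_mode: float = Field(30.0, ge=0, description="population age-mode in the first year")
    pop_age_sd: float = Field(20.0, gt=0, description="spread of the population age pattern")
    base_rate: dict[str, float] = Field(
        default_factory=lambda: {
            "incidence": 1.5,
            "prevalence": 30.0,
            "deaths": 0.25,
            "dalys": 14.0,
        }
    )
    trend_apc: dict[str, float] = Field(
        default_factory=lambda: {
            "incidence": 0.3,
            "prevalence": 0.9,
            "deaths": -0.5,
            "dalys": -0.4,
        }
    )
    age_mode: float = Field(42.0, ge=0, description="age (years) of peak burden rate")
    age_sd: float = Field(15.0, gt=0, description="width of the Gaussian age pattern, years")
    sex_ratio: float = Field(2.0, gt=0, description="female:male rate ratio")
    yll_share: float = Field(0.3, ge=0, le=1, description="fraction of DALYs that are YLLs")
    noise_cv: float = Field(0.05, ge=0, description="lognormal coefficient of variation")
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("years")
    @classmethod
    def _years_span(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[1] - v[0] < 2:
            raise ValueError("need at least 3 calendar years (a trend regression)")
        return v

    @field_validator("age_bins")
    @classmethod
    def _bins_exhaustive(cls, v: Sequence[str]) -> tuple[str, ...]:
        if tuple(v) != AGE_BINS:
            raise ValueError("age_bins must be the full 5-year ladder <5 ... 95+ in order")
        return tuple(v)

    @field_validator("base_rate", "trend_apc")
    @classmethod
    def _measures_known(cls, v: dict[str, float], info) -> dict[str, float]:
        unknown = set(v) - set(_BASE_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}; use {_BASE_MEASURES}")
        if info.field_name == "base_rate" and any(r < 0 for r in v.values()):
            raise ValueError("base rates must be non-negative")
        return v

    @model_validator(mode="after")
    def _mode_stays_in_range(self) -> "ScenarioConfig":
        mids = [age_midpoint(b) for b in self.age_bins]
        final_mode = self.pop_age_mode + self.aging_shift * (self.years[1] - self.years[0])
        if not (min(mids) <= final_mode <= max(mids)) or not (
            min(mids) <= self.pop_age_mode <= max(mids)
        ):
            raise ValueError(
                "aging_shift pushes the population age mode outside the age-bin range"
            )
        return self

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic population panel (location, sex, age, year, persons).

    Per location the total grows by ``pop_growth`` per year; the age
    distribution is a discretized Gaussian over bin midpoints whose mode
    advances by ``aging_shift`` years per calendar year; sexes split equally.
    """
    mids = np.array([age_midpoint(b) for b in config.age_bins])
    rows = []
    for location in config.locations:
        for year in config.year_list:
            t = year - config.years[0]
            total = config.base_pop * (1.0 + config.pop_growth) ** t
            mode = config.pop_age_mode + config.aging_shift * t
            shape = np.exp(-((mids - mode) ** 2) / (2.0 * config.pop_age_sd**2))
            shares = shape / shape.sum()
            for sex in config.sexes:
                persons = total / len(config.sexes) * shares
                for age, p in zip(config.age_bins, persons):
                    rows.append((location, sex, age, year, p))
    return pd.DataFrame(rows, columns=["location", "sex", "age", "year", "persons"])


def true_rate(config: ScenarioConfig, measure: str, sex: str, age: str, year: int) -> float:
    """Noise-free ground-truth rate per 100,000 for one stratum."""
    mid = age_midpoint(age)
    t = year - config.years[0]
    rate = (
        config.base_rate[measure]
        * np.exp(-((mid - config.age_mode) ** 2) / (2.0 * config.age_sd**2))
        * (1.0 + config.trend_apc[measure] / 100.0) ** t
    )
    if sex == "female":
        rate *= config.sex_ratio
    return float(rate)


def generate_burden(
    config: ScenarioConfig,
    pop: pd.DataFrame | None = None,
    std: pd.Series | None = None,
) -> pd.DataFrame:
    """Generate a burden table matching the GBD long format.

    Emits number and rate metrics for every (measure, location, sex, age bin,
    year) stratum, plus sex=both and all-ages aggregates and age-standardized
    rate rows (direct standardization with ``std``, defaulting to the packaged
    WHO world-standard weights). YLLs and YLDs are carved out of DALYs so that
    dalys = ylls + ylds holds exactly on every stratum; with ``noise_cv=0``
    the output is a bit-identical deterministic function of the config.
    """
    if pop is None:
        pop = generate_population(config)
    if std is None:
        std = read_standard_population()
    std = std.reindex(list(config.age_bins))
    if std.isna().any():
        raise ValueError("standard population does not cover the scenario age bins")
    std = std / std.sum()

    rng = np.random.default_rng(config.seed)
    # mean-1 lognormal noise: sigma^2 = ln(1 + cv^2)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    pop_panel = pop.set_index(["location", "sex", "age", "year"])["persons"]
    years = config.year_list
    mids = np.array([age_midpoint(b) for b in config.age_bins])
    n_age, n_year = len(config.age_bins), len(years)

    records: list[tuple] = []
    for location in config.locations:
        # counts[measure][sex] -> (n_age, n_year) arrays of observed numbers
        counts: dict[str, dict[str, np.ndarray]] = {m: {} for m in MEASURES}
        pops: dict[str, np.ndarray] = {}
        for sex in config.sexes:
            try:
                persons = np.array(
                    [[pop_panel[(location, sex, a, y)] for y in years] for a in config.age_bins]
                )
            except KeyError as exc:
                raise ValueError(f"population table misses stratum {exc.args[0]}") from None
            pops[sex] = persons
            t = np.arange(n_year)
            age_shape = np.exp(-((mids - config.age_mode) ** 2) / (2.0 * config.age_sd**2))
            sex_mult = config.sex_ratio if sex == "female" else 1.0
            for m in _BASE_MEASURES:
                rate = (
                    config.base_rate[m]
                    * sex_mult
                    * age_shape[:, None]
                    * (1.0 + config.trend_apc[m] / 100.0) ** t[None, :]
                )
                if config.noise_cv > 0:
                    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=rate.shape)
                else:
                    noise = 1.0
                counts[m][sex] = persons * rate / 1e5 * noise
            counts["ylls"][sex] = config.yll_share * counts["dalys"][sex]
            counts["ylds"][sex] = (1.0 - config.yll_share) * counts["dalys"][sex]

        pops["both"] = sum(pops[s] for s in config.sexes)
        for m in MEASURES:
            counts[m]["both"] = sum(counts[m][s] for s in config.sexes)

        sexes_out = list(config.sexes) + ["both"]
        for m in MEASURES:
            for sex in sexes_out:
                c, p = counts[m][sex], pops[sex]
                for i, age in enumerate(config.age_bins):
                    for j, year in enumerate(years):
                        records.append((m, location, sex, age, year, "number", c[i, j]))
                        records.append((m, location, sex, age, year, "rate", c[i, j] / p[i, j] * 1e5))
                # all-ages aggregates
                c_all, p_all = c.sum(axis=0), p.sum(axis=0)
                for j, year in enumerate(years):
                    records.append((m, location, sex, AGE_ALL, year, "number", c_all[j]))
                    records.append((m, location, sex, AGE_ALL, year, "rate", c_all[j] / p_all[j] * 1e5))
                # age-standardized rate (direct method)
                asr = (std.values[:, None] * c / p * 1e5).sum(axis=0)
                for j, year in enumerate(years):
                    records.append((m, location, sex, AGE_STD, year, "rate", asr[j]))

    df = pd.DataFrame(
        records, columns=["measure", "location", "sex", "age", "year", "metric", "val"]
    )
    band = 1.96 * config.noise_cv
    df["upper"] = df["val"] * (1.0 + band)
    df["lower"] = np.maximum(df["val"] * (1.0 - band), 0.0)
    return df[["measure", "location", "sex", "age", "year", "metric", "val", "upper", "lower"]]
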
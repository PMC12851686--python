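"""Three-factor decomposition of the change in an all-ages burden count.

A count at time t factorizes as C(t) = N(t) * sum_a s_a(t) * c_a(t) where
N is total population, s_a the age-structure shares and c_a the age-specific
rates. The change C(t1) - C(t0) is attributed to epidemiological change
(rates), population aging (shares) and population growth (size) by the
symmetric averaged-substitution method of Das Gupta: each factor's effect is
the average of its sequential-substitution contribution over all orderings
of the three factors, which for a per-bin three-way product has the closed
form

    effect(alpha) = (a2 - a1) * [ (b1 c1 + b2 c2)/3 + (b1 c2 + b2 c1)/6 ]

(and symmetrically for the other two factors). The three effects sum to the
total change exactly, bin by bin, which gives the additivity identity
delta_total = delta_epi + delta_age + delta_pop with no residual term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DecompositionResult:
    """Additive split of a count change into epidemiology / aging / growth."""

    delta_total: float
    delta_epi: float
    delta_age: float
    delta_pop: float

    @property
    def contributions_pct(self) -> dict[str, float]:
        """Each component as a percent of the total change (total != 0)."""
        if self.delta_total == 0:
            raise ZeroDivisionError("percent contributions undefined when total change is 0")
        return {
            "epi": self.delta_epi / self.delta_total * 100.0,
            "age": self.delta_age / self.delta_total * 100.0,
            "pop": self.delta_pop / self.delta_total * 100.0,
        }

    def scaled(self, factor: float) -> "DecompositionResult":
        """Rescaled copy, e.g. per 100,000 of baseline population."""
        return DecompositionResult(
            self.delta_total * factor,
            self.delta_epi * factor,
            self.delta_age * factor,
            self.delta_pop * factor,
        )


def _dasgupta_effect(a1, a2, b1, b2, c1, c2):
    """Averaged-substitution effect of factor a in the product a*b*c (vectorized)."""
    return (a2 - a1) * ((b1 * c1 + b2 * c2) / 3.0 + (b1 * c2 + b2 * c1) / 6.0)


def decompose(
    rates_t0,
    rates_t1,
    shares_t0,
    shares_t1,
    n_t0: float,
    n_t1: float,
    share_tol: float = 1e-8,
) -> DecompositionResult:
    """Decompose the change in a count into rate, age-structure and size effects.

    Parameters
    ----------
    rates_t0, rates_t1
        Age-specific rates (per person; any consistent scale) at both times.
    shares_t0, shares_t1
        Age-structure proportions at both times, each summing to 1.
    n_t0, n_t1
        Total population at both times (> 0).
    """
    c1 = np.asarray(rates_t0, float)
    c2 = np.asarray(rates_t1, float)
    s1 = np.asarray(shares_t0, float)
    s2 = np.asarray(shares_t1, float)
    if not (c1.shape == c2.shape == s1.shape == s2.shape):
        raise ValueError("age-bin vectors must share one length at both times")
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("rates must be non-negative")
    for name, s in (("shares_t0", s1), ("shares_t1", s2)):
        if abs(s.sum() - 1.0) > share_tol:
            raise ValueError(f"{name} sum to {s.sum():.12g}, expected 1")
    if n_t0 <= 0 or n_t1 <= 0:
        raise ValueError("total population must be positive")

    delta_pop = float(_dasgupta_effect(n_t0, n_t1, s1, s2, c1, c2).sum())
    delta_age = float(_dasgupta_effect(s1, s2, n_t0, n_t1, c1, c2).sum())
    delta_epi = float(_dasgupta_effect(c1, c2, n_t0, n_t1, s1, s2).sum())
    delta_total = float(n_t1 * (s2 * c2).sum() - n_t0 * (s1 * c1).sum())
    return DecompositionResult(delta_total, delta_epi, delta_age, delta_pop)


def decompose_table(
    burden: pd.DataFrame,
    pop: pd.DataFrame,
    measure: str,
    location: str,
    sex: str,
    year0: int,
    year1: int,
) -> DecompositionResult:
    """Decomposition driver working directly on burden/population tables.

    Extracts age-specific counts (metric=number) and population for the two
    years, derives rates and shares, and calls :func:`decompose`. The result
    is in counts; use ``result.scaled(1e5 / n_t0)`` for a per-100,000-of-
    baseline-population scaling. Both-sex decompositions should be run on
    sex="both" inputs rather than by summing sex-specific components (the
    method is not linear in the factors).
    """
    sub = burden[
        (burden["measure"] == measure)
        & (burden["location"] == location)
        & (burden["sex"] == sex)
        & (burden["metric"] == "number")
        & burden["year"].isin([year0, year1])
        & ~burden["age"].isin(["all-ages", "age-standardized"])
    ]
    ploc = pop[(pop["location"] == location) & pop["year"].isin([year0, year1])]
    if sex == "both" and "both" not in set(ploc["sex"]):
        # population tables usually carry only the sexes; aggregate on the fly
        psub = (
            ploc.groupby(["location", "age", "year"], as_index=False)["persons"].sum()
        )
    else:
        psub = ploc[ploc["sex"] == sex]

    counts = sub.pivot_table(index="age", columns="year", values="val", aggfunc="first")
    persons = psub.pivot_table(index="age", columns="year", values="persons", aggfunc="first")
    missing = []
    for year in (year0, year1):
        if year not in counts.columns:
            missing.append(f"burden counts for {year}")
        if year not in persons.columns:
            missing.append(f"population for {year}")
    if missing:
        raise ValueError(f"{measure}/{location}/{sex}: missing {missing}")
    counts, persons = counts.align(persons, join="inner", axis=0)
    incomplete = counts.index[counts.isna().any(axis=1) | persons.isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(f"incomplete age bins: {list(incomplete)}")

    n0, n1 = float(persons[year0].sum()), float(persons[year1].sum())
    shares0 = (persons[year0] / n0).to_numpy()
    shares1 = (persons[year1] / n1).to_numpy()
    rates0 = (counts[year0] / persons[year0]).to_numpy()
    rates1 = (counts[year1] / persons[year1]).to_numpy()
    return decompose(rates0, rates1, shares0, shares1, n0, n1)


def sequential_substitution_components(
    rates_t0, rates_t1, shares_t0, shares_t1, n_t0, n_t1
) -> DecompositionResult:
    """Brute-force reference: average of all 6 factor-substitution orderings.

    Enumerates every ordering in which the three factors are switched from
    t0 to t1, credits each factor with the count change occurring on its
    switch, and averages over orderings. Algebraically identical to
    :func:`decompose`; kept as an independent implementation for testing and
    didactic use.
    """
    import itertools

    c = {0: np.asarray(rates_t0, float), 1: np.asarray(rates_t1, float)}
    s = {0: np.asarray(shares_t0, float), 1: np.asarray(shares_t1, float)}
    n = {0: float(n_t0), 1: float(n_t1)}

    def count(state):
        return n[state["pop"]] * (s[state["age"]] * c[state["epi"]]).sum()

    effects = {"epi": 0.0, "age": 0.0, "pop": 0.0}
    orderings = list(itertools.permutations(["epi", "age", "pop"]))
    for order in orderings:
        state = {"epi": 0, "age": 0, "pop": 0}
        prev = count(state)
        for factor in order:
            state[factor] = 1
            cur = count(state)
            effects[factor] += cur - prev
            prev = cur
    k = len(orderings)
    return DecompositionResult(
        delta_total=count({"epi": 1, "age": 1, "pop": 1}) - count({"epi": 0, "age": 0, "pop": 0}),
        delta_epi=effects["epi"] / k,
        delta_age=effects["age"] / k,
        delta_pop=effects["pop"] / k,
    )
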
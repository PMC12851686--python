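"""Das Gupta three-factor decomposition: exactness and driver isolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenqci import ScenarioConfig, decompose, decompose_table, generate_burden, generate_population
from burdenqci.decompose import sequential_substitution_components

from conftest import flat_apc


def random_instance(rng, nbins=5):
    r0, r1 = rng.random(nbins) * 1e-3, rng.random(nbins) * 1e-3
    s0, s1 = rng.random(nbins) + 0.05, rng.random(nbins) + 0.05
    return r0, r1, s0 / s0.sum(), s1 / s1.sum(), rng.uniform(1e5, 1e7), rng.uniform(1e5, 1e7)


class TestDecompose:
    def test_identical_inputs_give_zero_components(self):
        r = np.array([1e-4, 2e-4, 3e-4])
        s = np.array([0.2, 0.3, 0.5])
        res = decompose(r, r, s, s, 1e6, 1e6)
        assert res.delta_total == res.delta_epi == res.delta_age == res.delta_pop == 0.0

    def test_pure_growth_is_all_population(self):
        r = np.array([1e-4, 2e-4])
        s = np.array([0.4, 0.6])
        res = decompose(r, r, s, s, 1e6, 2e6)
        assert res.delta_pop == pytest.approx(res.delta_total, rel=1e-12)
        assert res.delta_epi == 0.0 and res.delta_age == 0.0

    def test_each_factor_zero_when_unchanged(self, rng):
        r0, r1, s0, s1, n0, n1 = random_instance(rng)
        assert decompose(r0, r1, s0, s0, n0, n0).delta_age == 0.0
        assert decompose(r0, r0, s0, s1, n0, n1).delta_epi == 0.0
        assert decompose(r0, r1, s0, s1, n0, n0).delta_pop == 0.0

    def test_swap_symmetry_negates_components(self, rng):
        r0, r1, s0, s1, n0, n1 = random_instance(rng)
        fwd = decompose(r0, r1, s0, s1, n0, n1)
        rev = decompose(r1, r0, s1, s0, n1, n0)
        assert rev.delta_total == pytest.approx(-fwd.delta_total, rel=1e-12)
        assert rev.delta_epi == pytest.approx(-fwd.delta_epi, rel=1e-12)
        assert rev.delta_age == pytest.approx(-fwd.delta_age, rel=1e-12)
        assert rev.delta_pop == pytest.approx(-fwd.delta_pop, rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_additivity_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        r0, r1, s0, s1, n0, n1 = random_instance(rng)
        res = decompose(r0, r1, s0, s1, n0, n1)
        total = n1 * (s1 * r1).sum() - n0 * (s0 * r0).sum()
        scale = max(abs(total), 1e-12)
        assert abs(res.delta_epi + res.delta_age + res.delta_pop - total) <= 1e-9 * scale

        oracle = sequential_substitution_components(r0, r1, s0, s1, n0, n1)
        assert res.delta_epi == pytest.approx(oracle.delta_epi, rel=1e-9, abs=1e-9)
        assert res.delta_age == pytest.approx(oracle.delta_age, rel=1e-9, abs=1e-9)
        assert res.delta_pop == pytest.approx(oracle.delta_pop, rel=1e-9, abs=1e-9)

    def test_contributions_sum_to_100(self, rng):
        r0, r1, s0, s1, n0, n1 = random_instance(rng)
        pct = decompose(r0, r1, s0, s1, n0, n1).contributions_pct
        assert pct["epi"] + pct["age"] + pct["pop"] == pytest.approx(100.0)

    def test_unnormalized_shares_rejected(self):
        r = np.array([1e-4, 2e-4])
        with pytest.raises(ValueError, match="sum"):
            decompose(r, r, np.array([0.5, 0.6]), np.array([0.4, 0.6]), 1e6, 1e6)


class TestDecomposeTable:
    def test_aging_only_scenario_isolates_age_component(self):
        cfg = ScenarioConfig(
            years=(2000, 2015), noise_cv=0.0, trend_apc=flat_apc(0.0),
            pop_growth=0.0, aging_shift=0.5,
        )
        pop = generate_population(cfg)
        burden = generate_burden(cfg, pop)
        res = decompose_table(burden, pop, "prevalence", "Simland", "both", 2000, 2015)
        assert res.delta_pop == pytest.approx(0.0, abs=1e-9 * abs(res.delta_total))
        assert res.delta_epi == pytest.approx(0.0, abs=1e-9 * abs(res.delta_total))
        assert res.delta_age == pytest.approx(res.delta_total, rel=1e-9)

    def test_trend_only_scenario_isolates_epi_component(self):
        cfg = ScenarioConfig(
            years=(2000, 2015), noise_cv=0.0, trend_apc=flat_apc(1.5),
            pop_growth=0.0, aging_shift=0.0,
        )
        pop = generate_population(cfg)
        burden = generate_burden(cfg, pop)
        res = decompose_table(burden, pop, "dalys", "Simland", "both", 2000, 2015)
        assert res.delta_age == pytest.approx(0.0, abs=1e-9 * abs(res.delta_total))
        assert res.delta_pop == pytest.approx(0.0, abs=1e-9 * abs(res.delta_total))
        assert res.delta_epi == pytest.approx(res.delta_total, rel=1e-9)

    def test_sex_ratio_scales_female_change(self, small_tables):
        pop, burden = small_tables  # sex_ratio = 2 in the default config
        f = decompose_table(burden, pop, "incidence", "Simland", "female", 2000, 2015)
        m = decompose_table(burden, pop, "incidence", "Simland", "male", 2000, 2015)
        assert f.delta_total == pytest.approx(2.0 * m.delta_total, rel=1e-9)

    def test_missing_year_reported(self, small_tables):
        pop, burden = small_tables
        with pytest.raises(ValueError, match="2050"):
            decompose_table(burden, pop, "incidence", "Simland", "both", 2000, 2050)

    def test_scaled_result(self, small_tables):
        pop, burden = small_tables
        res = decompose_table(burden, pop, "deaths", "Simland", "both", 2000, 2015)
        n0 = pop[(pop["sex"].isin(["female", "male"])) & (pop["year"] == 2000)]["persons"].sum()
        per1e5 = res.scaled(1e5 / n0)
        assert per1e5.delta_total == pytest.approx(res.delta_total / n0 * 1e5)
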
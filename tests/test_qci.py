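"""QCI construction: ratio indices, PCA composite, orientation, scaling."""

import numpy as np
import pandas as pd
import pytest

from burdenqci import ScenarioConfig, compute_qci, compute_ratios, generate_burden, qci_by_age_sex
from burdenqci.qci import DegeneratePoolError, RatioIndices


def burden_row(measure, location, year, val, sex="both", age="age-standardized"):
    return dict(
        measure=measure, location=location, sex=sex, age=age, year=year,
        metric="rate", val=val, upper=val, lower=val,
    )


def toy_burden(strata):
    """strata: dict (location, year) -> dict measure -> ASR value."""
    rows = []
    for (loc, year), measures in strata.items():
        for m, v in measures.items():
            rows.append(burden_row(m, loc, year, v))
    return pd.DataFrame(rows)


BASE = dict(incidence=1.0, prevalence=25.0, deaths=0.2, dalys=12.0, ylls=4.0, ylds=8.0)


def vary(incidence=1.0, deaths=0.2, **kw):
    d = dict(BASE)
    d.update(incidence=incidence, deaths=deaths, **kw)
    return d


class TestRatios:
    def test_printed_style_arithmetic(self):
        # G20-2021-like cell: prevalence 24.7 with incidence 0.9 -> 27.4
        b = toy_burden({("G20", 2021): dict(BASE, prevalence=24.7, incidence=0.9)})
        r = compute_ratios(b).values
        assert round(float(r["prev_inc"].iloc[0]), 1) == 27.4

    def test_zero_deaths_and_zero_yll_give_best_ratios(self):
        b = toy_burden({("X", 2000): dict(BASE, deaths=0.0, ylls=0.0)})
        r = compute_ratios(b).values
        assert float(r["mir"].iloc[0]) == 0.0
        assert float(r["yll_yld"].iloc[0]) == 0.0

    def test_zero_denominators_excluded_and_reported(self):
        b = toy_burden(
            {("A", 2000): BASE, ("B", 2000): dict(BASE, incidence=0.0)}
        )
        r = compute_ratios(b)
        assert len(r.values) == 1
        assert len(r.excluded) == 1
        assert "incidence=0" in r.excluded["reason"].iloc[0]

    def test_daly_denominator_flag(self):
        b = toy_burden({("A", 2000): BASE})
        prev = compute_ratios(b, daly_denominator="prevalence").values
        inc = compute_ratios(b, daly_denominator="incidence").values
        assert float(prev["daly_prev"].iloc[0]) == pytest.approx(12.0 / 25.0)
        assert float(inc["daly_prev"].iloc[0]) == pytest.approx(12.0 / 1.0)


def two_index_pool(n=12, seed=0):
    """Pool where only prev_inc and mir vary; daly_prev and yll_yld constant."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        {
            "prev_inc": rng.uniform(10, 40, n),
            "mir": rng.uniform(0.05, 0.4, n),
            "daly_prev": 0.5,
            "yll_yld": 0.5,
        }
    )
    return RatioIndices(values=values, excluded=pd.DataFrame())


class TestQCI:
    def test_minmax_endpoints(self):
        res = compute_qci(two_index_pool())
        assert res.qci.min() == pytest.approx(0.0, abs=1e-12)
        assert res.qci.max() == pytest.approx(100.0, abs=1e-12)
        assert res.qci.idxmin() == res.pca_score.idxmin()
        assert res.qci.idxmax() == res.pca_score.idxmax()

    def test_two_index_pool_matches_hand_eigendecomposition(self):
        """With 2 varying indices the correlation matrix is [[1, r], [r, 1]]
        whose eigenvectors are (1, 1)/sqrt(2) and (1, -1)/sqrt(2) with
        eigenvalues 1 +/- r; the weighted score follows in closed form."""
        ratios = two_index_pool()
        res = compute_qci(ratios)
        assert res.dropped_constant == ("daly_prev", "yll_yld")

        X = ratios.values[["prev_inc", "mir"]].to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        r = float(np.corrcoef(Z, rowvar=False)[0, 1])
        s = np.sign(r) if r != 0 else 1.0
        lam1, lam2 = 1 + abs(r), 1 - abs(r)
        v1 = np.array([1.0, s]) / np.sqrt(2)  # top eigenvector
        v2 = np.array([1.0, -s]) / np.sqrt(2)
        # orient each component against MIR (higher score = better care)
        if np.corrcoef(Z @ v1, Z[:, 1])[0, 1] > 0:
            v1 = -v1
        if np.corrcoef(Z @ v2, Z[:, 1])[0, 1] > 0:
            v2 = -v2
        w1 = lam1 / (lam1 + lam2)
        expected = w1 * (Z @ v1) + (1 - w1) * (Z @ v2)
        assert np.allclose(res.pca_score.to_numpy(), expected, atol=1e-9)
        assert res.var_pc1 == pytest.approx(lam1, abs=1e-12)
        assert res.weight1 + res.weight2 == pytest.approx(1.0)

    def test_dominant_observation_attains_100(self):
        rng = np.random.default_rng(1)
        n = 10
        values = pd.DataFrame(
            {
                "prev_inc": rng.uniform(10, 20, n),
                "mir": rng.uniform(0.2, 0.4, n),
                "daly_prev": rng.uniform(0.4, 0.6, n),
                "yll_yld": rng.uniform(0.4, 0.6, n),
            }
        )
        # one observation strictly better on every index
        values.loc[n - 1] = [50.0, 0.01, 0.1, 0.1]
        res = compute_qci(RatioIndices(values=values, excluded=pd.DataFrame()))
        assert res.qci.idxmax() == n - 1
        assert res.qci.loc[n - 1] == pytest.approx(100.0)

    def test_orientation_anticorrelated_with_mir(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.uniform(0.1, 5.0, size=(15, 4)), columns=list(two_index_pool().values.columns))
            res = compute_qci(RatioIndices(values=values, excluded=pd.DataFrame()))
            for i in (0, 1):
                comp = res.loadings.iloc[:, i].to_numpy()
                Z = (values - values.mean()) / values.std(ddof=1)
                score = Z[res.loadings.index].to_numpy() @ comp
                assert np.corrcoef(score, values["mir"])[0, 1] <= 1e-12

    def test_affine_invariance_of_one_column(self):
        ratios = two_index_pool()
        res1 = compute_qci(ratios)
        shifted = ratios.values.copy()
        shifted["mir"] = 3.0 * shifted["mir"] + 7.0
        res2 = compute_qci(RatioIndices(values=shifted, excluded=pd.DataFrame()))
        assert np.allclose(res1.qci.to_numpy(), res2.qci.to_numpy(), atol=1e-9)

    def test_row_permutation_equivariance(self):
        ratios = two_index_pool()
        res = compute_qci(ratios)
        perm = ratios.values.iloc[::-1]
        res_p = compute_qci(RatioIndices(values=perm, excluded=pd.DataFrame()))
        assert np.allclose(res_p.qci.sort_index().to_numpy(), res.qci.sort_index().to_numpy(), atol=1e-12)

    def test_reconstruction_from_loadings(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.uniform(0.5, 3.0, (20, 4)), columns=list(two_index_pool().values.columns))
        res = compute_qci(RatioIndices(values=values, excluded=pd.DataFrame()))
        Z = (values - values.mean()) / values.std(ddof=1)
        proj = Z.to_numpy() @ (res.weight1 * res.loadings["PC1"].to_numpy() + res.weight2 * res.loadings["PC2"].to_numpy())
        assert np.allclose(proj, res.pca_score.to_numpy(), atol=1e-12)

    def test_sklearn_cross_check(self):
        """Eigenstructure agrees with an independent PCA implementation."""
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.uniform(0.5, 3.0, (30, 4)), columns=list(two_index_pool().values.columns))
        res = compute_qci(RatioIndices(values=values, excluded=pd.DataFrame()))
        Z = ((values - values.mean()) / values.std(ddof=1)).to_numpy()
        pca = sklearn_pca.PCA(n_components=2).fit(Z)
        for i in (0, 1):
            ours = res.loadings.iloc[:, i].to_numpy()
            theirs = pca.components_[i]
            assert np.allclose(np.abs(ours @ theirs), 1.0, atol=1e-9)

    def test_degenerate_pools(self):
        values = two_index_pool().values.iloc[:2]
        with pytest.raises(DegeneratePoolError, match="observations"):
            compute_qci(RatioIndices(values=values, excluded=pd.DataFrame()))
        # one varying column only
        one = two_index_pool().values.copy()
        one["mir"] = 0.3
        with pytest.raises(DegeneratePoolError, match="varying"):
            compute_qci(RatioIndices(values=one, excluded=pd.DataFrame()))

    def test_identical_strata_all_score_100(self):
        const = two_index_pool().values.copy()
        const[:] = [20.0, 0.2, 0.5, 0.5]
        res = compute_qci(RatioIndices(values=const, excluded=pd.DataFrame()))
        assert (res.qci == 100.0).all()


@pytest.fixture(scope="module")
def burden():
    cfg = ScenarioConfig(years=(2000, 2005), seed=21, noise_cv=0.05)
    return generate_burden(cfg)


class TestAgeSexQCI:

    def test_tidy_output_shape(self, burden):
        table = qci_by_age_sex(burden)
        assert {"location", "year", "sex", "age", "qci", "pca_score"} <= set(table.columns)
        assert table["qci"].between(0, 100).all()

    def test_sex_swap_symmetry(self, burden):
        swapped = burden.copy()
        swapped["sex"] = swapped["sex"].map({"female": "male", "male": "female", "both": "both"})
        a = qci_by_age_sex(burden).set_index(["location", "year", "sex", "age"])["qci"]
        b = qci_by_age_sex(swapped).set_index(["location", "year", "sex", "age"])["qci"]
        relabeled = {
            (loc, yr, {"female": "male", "male": "female", "both": "both"}[sx], ag): v
            for (loc, yr, sx, ag), v in a.items()
        }
        for key, v in relabeled.items():
            assert b.loc[key] == pytest.approx(v, abs=1e-9)

    def test_elderly_mortality_depresses_elderly_qci(self):
        """Mortality concentrated in old bins pushes elderly QCI below
        mid-age QCI (the 'both-ends-low' direction)."""
        cfg = ScenarioConfig(years=(2000, 2003), seed=5, noise_cv=0.0)
        burden = generate_burden(cfg)
        # move deaths mass into the oldest bins
        old = burden["age"].isin(["80-84", "85-89", "90-94", "95+"])
        is_deaths = burden["measure"] == "deaths"
        burden.loc[is_deaths & old, ["val", "upper", "lower"]] *= 40.0
        table = qci_by_age_sex(burden)
        both = table[table["sex"] == "both"]
        elderly = both[both["age"].isin(["85-89", "90-94", "95+"])]["qci"].mean()
        midage = both[both["age"].isin(["35-39", "40-44", "45-49"])]["qci"].mean()
        assert elderly < midage

    def test_per_year_pool_policy(self, burden):
        table = qci_by_age_sex(burden, pool_policy="per-year")
        for _, grp in table.groupby("year"):
            assert grp["qci"].min() == pytest.approx(0.0, abs=1e-9)
            assert grp["qci"].max() == pytest.approx(100.0, abs=1e-9)
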
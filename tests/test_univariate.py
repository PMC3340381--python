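import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from audiotwin import simulate_cohort
from audiotwin.univariate import (
    FitError,
    UnivariateFit,
    VarianceComponents,
    ZygosityCorrelations,
    age_adjust,
    compare_models,
    falconer_estimates,
    fit_univariate,
    zygosity_correlations,
)
from tests.conftest import clean_config


def table_from_pairs(mz: np.ndarray, dz: np.ndarray) -> pd.DataFrame:
    rows = []
    for zyg, pairs in (("MZ", mz), ("DZ", dz)):
        for i, (y1, y2) in enumerate(pairs):
            pid = f"{zyg}{i:04d}"
            rows.append({"subject_id": f"{pid}a", "pair_id": pid, "zygosity": zyg,
                         "age": 60.0, "y": y1})
            rows.append({"subject_id": f"{pid}b", "pair_id": pid, "zygosity": zyg,
                         "age": 60.0, "y": y2})
    return pd.DataFrame(rows)


class TestZygosityCorrelations:
    def test_identical_pairs_r_one(self):
        mz = np.column_stack([np.arange(10.0), np.arange(10.0)])
        dz = np.column_stack([np.arange(10.0), np.arange(10.0)[::-1]])
        corr = zygosity_correlations(table_from_pairs(mz, dz), "y")
        assert corr.r_mz == pytest.approx(1.0)

    def test_double_entry_antisymmetric(self):
        # pairs (1,2) and (2,1) double-entered -> 4 points with r = -1
        mz = np.array([[1.0, 2.0], [2.0, 1.0]])
        corr = zygosity_correlations(table_from_pairs(mz, mz), "y")
        assert corr.r_mz == pytest.approx(-1.0)

    def test_independent_cotwins_r_zero(self):
        rng = np.random.default_rng(0)
        mz = rng.standard_normal((10_000, 2))
        dz = rng.standard_normal((10_000, 2))
        corr = zygosity_correlations(table_from_pairs(mz, dz), "y")
        assert corr.r_mz == pytest.approx(0.0, abs=0.03)
        assert corr.r_dz == pytest.approx(0.0, abs=0.03)

    def test_constant_phenotype_rejected(self):
        mz = np.ones((5, 2))
        with pytest.raises(FitError):
            zygosity_correlations(table_from_pairs(mz, mz), "y")


class TestFalconer:
    def test_direct_substitution(self):
        vc = falconer_estimates(ZygosityCorrelations(0.70, 0.35, 100, 100))
        assert (vc.a2, vc.c2, vc.e2) == pytest.approx((0.70, 0.0, 0.30))

    def test_pure_common_environment(self):
        vc = falconer_estimates(ZygosityCorrelations(0.5, 0.5, 100, 100))
        assert (vc.a2, vc.c2, vc.e2) == pytest.approx((0.0, 0.5, 0.5))

    def test_negative_c_clipped(self):
        corr = ZygosityCorrelations(0.6, 0.2, 100, 100)
        raw = falconer_estimates(corr)
        assert (raw.a2, raw.c2, raw.e2) == pytest.approx((0.8, -0.2, 0.4))
        assert not raw.clipped
        clipped = falconer_estimates(corr, clip=True)
        assert clipped.clipped
        assert clipped.c2 == 0.0
        assert clipped.a2 + clipped.c2 + clipped.e2 == pytest.approx(1.0)

    @given(st.floats(-0.9, 0.9), st.floats(-0.9, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_components_always_sum_to_one(self, r_mz, r_dz):
        vc = falconer_estimates(ZygosityCorrelations(r_mz, r_dz, 10, 10))
        assert vc.a2 + vc.c2 + vc.e2 == pytest.approx(1.0, abs=1e-9)


def _clean_table(seed, n=250):
    from audiotwin import audiogram_matrix, build_phenotypes, fit_pca

    cohort = simulate_cohort(clean_config(n_mz_pairs=n, n_dz_pairs=n, seed=seed))
    table = build_phenotypes(cohort, fit_pca(audiogram_matrix(cohort), n_components=2))
    table["pta_adj"] = age_adjust(table, "pta")
    return table


class TestFitUnivariate:
    def test_components_sum_to_one(self, clean_table):
        for model in ("ACE", "AE", "CE", "E"):
            fit = fit_univariate(clean_table, "pta_adj", model=model, compute_ci=False)
            c = fit.components
            assert c.a2 + c.c2 + c.e2 == pytest.approx(1.0, abs=1e-9)
            assert min(c.a2, c.c2, c.e2) >= 0

    def test_matches_falconer_oracle(self, clean_table):
        fit = fit_univariate(clean_table, "pta_adj", model="ACE", compute_ci=False)
        fal = falconer_estimates(zygosity_correlations(clean_table, "pta_adj"), clip=True)
        assert fit.components.a2 == pytest.approx(fal.a2, abs=0.05)

    def test_nested_models_never_fit_better(self, clean_table):
        full = fit_univariate(clean_table, "pta_adj", model="ACE", compute_ci=False)
        for model in ("AE", "CE", "E"):
            nested = fit_univariate(clean_table, model=model, column="pta_adj",
                                    compute_ci=False)
            assert nested.minus2logl - full.minus2logl >= -1e-6

    def test_saturated_implies_sample_correlations(self):
        # ML implied MZ/DZ correlations match double-entry sample values when
        # the solution is interior (c2 truth > 0 keeps it off the boundary)
        from audiotwin import audiogram_matrix, build_phenotypes, fit_pca
        from audiotwin import simulate_cohort

        cfg = clean_config(n_mz_pairs=800, n_dz_pairs=800, seed=99)
        cfg.var_components["level"] = (0.4, 0.3, 0.3)
        cohort = simulate_cohort(cfg)
        table = build_phenotypes(cohort, fit_pca(audiogram_matrix(cohort), n_components=2))
        table["pta_adj"] = age_adjust(table, "pta")
        fit = fit_univariate(table, "pta_adj", model="ACE", compute_ci=False)
        corr = zygosity_correlations(table, "pta_adj")
        c = fit.components
        assert not fit.boundary
        # common-mean/common-variance ML vs per-zygosity double-entry stats
        # agree to O(1/n) on balanced data
        assert c.a2 + c.c2 == pytest.approx(corr.r_mz, abs=0.02)
        assert 0.5 * c.a2 + c.c2 == pytest.approx(corr.r_dz, abs=0.02)

    def test_null_structure_gives_zero_a2(self):
        rng = np.random.default_rng(3)
        mz = rng.standard_normal((300, 2))
        dz = rng.standard_normal((300, 2))
        table = table_from_pairs(mz, dz)
        ace = fit_univariate(table, "y", model="ACE", compute_ci=False)
        e = fit_univariate(table, "y", model="E", compute_ci=False)
        assert ace.components.a2 == pytest.approx(0.0, abs=0.08)
        assert e.minus2logl - ace.minus2logl < 3.84

    def test_monotone_in_generating_a2(self):
        means = []
        for a2 in (0.2, 0.4, 0.6, 0.8):
            ests = []
            for rep in range(20):
                cfg = clean_config(n_mz_pairs=150, n_dz_pairs=150,
                                   seed=10_000 + int(a2 * 10) * 100 + rep)
                cfg.var_components["level"] = (a2, 0.0, 1.0 - a2)
                cohort = simulate_cohort(cfg)
                rows = [
                    {"subject_id": r.subject_id, "pair_id": r.pair_id,
                     "zygosity": r.zygosity, "age": r.age, "y": r.thresholds_left.mean()}
                    for r in cohort.records
                ]
                fit = fit_univariate(pd.DataFrame(rows), "y", model="AE",
                                     compute_ci=False)
                ests.append(fit.components.a2)
            means.append(np.mean(ests))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_few_pairs_rejected(self):
        mz = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(FitError):
            fit_univariate(table_from_pairs(mz, mz), "y", compute_ci=False)


class TestCompareModels:
    @pytest.mark.parametrize(
        "delta, p_expected, aic_expected",
        [
            (0.069, 0.792, -1.931),
            (1.709, 0.191, -0.291),
            (0.000, 1.000, -2.000),
        ],
    )
    def test_published_arithmetic(self, delta, p_expected, aic_expected):
        full = UnivariateFit(model="ACE", minus2logl=1000.0, df=1025)
        nested = UnivariateFit(model="AE", minus2logl=1000.0 + delta, df=1026)
        cmp_ = compare_models(full, nested)
        assert cmp_.delta_df == 1
        assert cmp_.p_value == pytest.approx(p_expected, abs=1e-3)
        assert cmp_.aic == pytest.approx(aic_expected, abs=1e-9)

    def test_non_nested_rejected(self):
        ae = UnivariateFit(model="AE", minus2logl=10.0, df=100)
        ce = UnivariateFit(model="CE", minus2logl=11.0, df=100)
        with pytest.raises(ValueError):
            compare_models(ae, ce)

    def test_negative_delta_raises(self):
        full = UnivariateFit(model="ACE", minus2logl=10.0, df=100)
        nested = UnivariateFit(model="AE", minus2logl=9.0, df=101)
        with pytest.raises(FitError):
            compare_models(full, nested)


class TestAgeAdjust:
    def test_linear_phenotype_residuals_zero(self):
        table = pd.DataFrame({"age": np.arange(50.0), "y": 2 * np.arange(50.0) + 3})
        resid = age_adjust(table, "y")
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_orthogonal_to_age(self, phenotype_table):
        resid = age_adjust(phenotype_table, "pta")
        r = np.corrcoef(resid, phenotype_table["age"])[0, 1]
        assert abs(r) < 1e-10

    def test_residual_variance(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(40, 90, 100_000)
        table = pd.DataFrame({"age": age, "y": age + rng.standard_normal(100_000)})
        resid = age_adjust(table, "y")
        assert np.var(resid) == pytest.approx(1.0, abs=0.02)

    def test_constant_age_rejected(self):
        table = pd.DataFrame({"age": np.full(10, 60.0), "y": np.arange(10.0)})
        with pytest.raises(FitError):
            age_adjust(table, "y")
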
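import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from audiotwin import (
    audiogram_matrix,
    better_ear,
    build_phenotypes,
    fit_pca,
    kruskal_wallis,
    log_transform,
    scalar_averages,
    simulate_cohort,
)
from audiotwin.phenotypes import (
    AudiogramMatrix,
    PhenotypeError,
    compute_ranking_criteria,
    rank_criteria,
    rank_phenotypes,
)
from tests.conftest import clean_config

FREQS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


class TestBetterEar:
    def test_lower_mean_ear_wins(self):
        left = np.full(7, 10.0)
        right = np.full(7, 30.0)
        assert np.array_equal(better_ear(left, right), left)

    def test_tie_goes_left(self):
        left = np.arange(7.0)
        right = np.arange(7.0)[::-1]  # same mean
        assert np.array_equal(better_ear(left, right), left)

    def test_whole_ear_rule(self):
        # right mean 19.9 < left mean 20 -> whole right ear returned, even
        # at frequencies where the left ear is individually better
        left = np.full(7, 20.0)
        right = np.array([40.0, 10.0, 10.0, 10.0, 10.0, 34.3, 25.0])
        assert right.mean() == pytest.approx(19.9)
        assert np.array_equal(better_ear(left, right), right)

    def test_missing_both_ears_raises(self):
        left = np.array([10.0, np.nan, 10.0])
        right = np.array([10.0, np.nan, 10.0])
        with pytest.raises(PhenotypeError):
            better_ear(left, right)


class TestLogTransform:
    def test_boundary(self):
        out = log_transform(np.array([-25.0 + 1e-9]), offset=25.0)
        assert out[0] < -8
        with pytest.raises(PhenotypeError):
            log_transform(np.array([-25.0]), offset=25.0)

    def test_direct_values(self):
        out = log_transform(np.array([0.0, 75.0]), offset=25.0, base=10.0)
        assert out == pytest.approx([np.log10(25.0), 2.0])

    def test_zero_offset_plain_log(self):
        out = log_transform(np.array([10.0, 100.0]), offset=0.0, base=10.0)
        assert out == pytest.approx([1.0, 2.0])


class TestScalarAverages:
    def test_flat_audiogram(self):
        pta, behl = scalar_averages(np.full(7, 40.0), FREQS)
        assert pta == behl == 40.0

    def test_worked_example(self):
        thr = np.array([10, 10, 10, 20, 30, 40, 50], dtype=float)
        pta, behl = scalar_averages(thr, FREQS)
        assert pta == pytest.approx(170 / 7)
        assert behl == pytest.approx(25.0)

    def test_empty_freqs_error(self):
        with pytest.raises(PhenotypeError):
            scalar_averages(np.array([]), ())


class TestFitPCA:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(0)
        factor = rng.standard_normal((500, 1))
        data = factor @ np.ones((1, 7)) + 1e-3 * rng.standard_normal((500, 7))
        m = AudiogramMatrix(subjects=[str(i) for i in range(500)], freqs=FREQS,
                            values=data, transform_params=(0, 10))
        pca = fit_pca(m)
        assert pca.var_explained[0] > 0.99
        assert np.all(pca.loadings[:, 0] > 0)

    def test_independent_columns_identity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20_000, 7))
        m = AudiogramMatrix(subjects=[str(i) for i in range(20_000)], freqs=FREQS,
                            values=data, transform_params=(0, 10))
        pca = fit_pca(m, n_components=7)
        assert np.allclose(pca.eigenvalues, 1.0, atol=0.1)

    def test_two_factor_structure(self, default_cohort):
        # generator has a level factor and a sign-flipping slope factor
        pca = fit_pca(audiogram_matrix(default_cohort))
        assert int(np.sum(pca.eigenvalues > 1.0)) == 2
        assert np.all(pca.loadings[:, 0] > 0)
        i05 = FREQS.index(0.5)
        i4 = FREQS.index(4.0)
        assert np.sign(pca.loadings[i05, 1]) != np.sign(pca.loadings[i4, 1])
        assert pca.loadings[0, 1] > 0  # low-frequency loading positive

    def test_matches_eigendecomposition_oracle(self, default_cohort):
        matrix = audiogram_matrix(default_cohort)
        pca = fit_pca(matrix, n_components=2)
        corr = np.corrcoef(matrix.values.T)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert pca.eigenvalues == pytest.approx(evals, rel=1e-8)

    def test_scores_uncorrelated(self, default_cohort):
        pca = fit_pca(audiogram_matrix(default_cohort), n_components=2)
        r = np.corrcoef(pca.scores[:, 0], pca.scores[:, 1])[0, 1]
        assert abs(r) < 1e-10

    def test_constant_column_rejected(self):
        data = np.ones((50, 7))
        m = AudiogramMatrix(subjects=[str(i) for i in range(50)], freqs=FREQS,
                            values=data, transform_params=(0, 10))
        with pytest.raises(PhenotypeError):
            fit_pca(m)

    def test_variance_captured_band_with_tuned_noise(self):
        # generator-calibration check: ~22% noise -> 2 PCs capture ~78%
        cfg = clean_config(n_mz_pairs=1500, n_dz_pairs=1500,
                           slope_loadings=(-5.0, -4.0, -2.5, 0.0, 2.5, 4.0, 6.0),
                           ear_noise_sd=4.5, seed=12)
        pca = fit_pca(audiogram_matrix(simulate_cohort(cfg)), n_components=2)
        assert 0.70 <= pca.var_explained.sum() <= 0.86


class TestBuildPhenotypes:
    def test_pc_difference_exact(self, phenotype_table):
        assert np.allclose(
            phenotype_table["pc1_minus_pc2"],
            phenotype_table["pc1"] - phenotype_table["pc2"],
        )

    def test_mean_audiogram_projects_to_zero(self, default_cohort):
        pca = fit_pca(audiogram_matrix(default_cohort), n_components=2)
        scores = pca.project(pca.center)
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_flat_elevated_vs_flat_normal(self, default_cohort):
        pca = fit_pca(audiogram_matrix(default_cohort), n_components=2)
        elevated = pca.project(log_transform(np.full(7, 60.0)))
        normal = pca.project(log_transform(np.full(7, 5.0)))
        assert elevated[0] > normal[0]
        assert abs(elevated[1] - normal[1]) < abs(elevated[0] - normal[0])

    def test_freq_mismatch_rejected(self, default_cohort):
        pca = fit_pca(audiogram_matrix(default_cohort), n_components=2)
        object.__setattr__(pca, "freqs", (0.5, 1.0))
        with pytest.raises(PhenotypeError):
            build_phenotypes(default_cohort, pca)


class TestRanking:
    def test_paper_style_criteria_rank_composite_first(self):
        # criterion values as inputs: the PC1-PC2 composite must rank first
        criteria = pd.DataFrame(
            {
                "phenotype": ["pc1_minus_pc2", "pta", "pc1", "behl", "pc2"],
                "r_age": [0.61, 0.55, 0.53, 0.49, -0.29],
                "r2_pc2": [0.26, 0.08, 0.12, 0.08, 1.00],
            }
        )
        ranked = rank_criteria(criteria)
        assert ranked.iloc[0]["phenotype"] == "pc1_minus_pc2"
        assert ranked.iloc[0]["overall_rank"] == 1
        row = ranked.set_index("phenotype")
        assert row.loc["pta", "rank_pc2"] == row.loc["behl", "rank_pc2"]  # tie shares min rank
        assert np.isnan(row.loc["pc2", "rank_pc2"])

    def test_identical_phenotypes_all_tied(self):
        criteria = pd.DataFrame(
            {
                "phenotype": ["a", "b", "c"],
                "r_age": [0.5, 0.5, 0.5],
                "r2_pc2": [0.2, 0.2, 0.2],
            }
        )
        ranked = rank_criteria(criteria)
        assert (ranked["overall_rank"] == 1).all()

    def test_noise_ranks_last(self, phenotype_table):
        rng = np.random.default_rng(0)
        table = phenotype_table.copy()
        table["noise"] = rng.standard_normal(len(table))
        ranked = rank_phenotypes(table, phenotypes=("pta", "noise"), seed=0)
        row = ranked.set_index("phenotype")
        assert row.loc["noise", "rank_age"] == 2
        assert row.loc["noise", "rank_pc2"] == 2

    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, phenotype_table, scale, shift):
        base = compute_ranking_criteria(phenotype_table, seed=0)
        table = phenotype_table.copy()
        table["pta"] = scale * table["pta"] + shift
        scaled = compute_ranking_criteria(table, seed=0)
        merged = base.merge(scaled, on="phenotype", suffixes=("_a", "_b"))
        assert np.allclose(np.abs(merged["r_age_a"]), np.abs(merged["r_age_b"]), atol=1e-9)
        assert np.allclose(merged["r2_pc2_a"], merged["r2_pc2_b"], atol=1e-9)

    def test_zero_variance_excluded(self, phenotype_table, caplog):
        table = phenotype_table.copy()
        table["flat"] = 1.0
        crit = compute_ranking_criteria(table, phenotypes=("pta", "pc1", "flat"), seed=0)
        assert "flat" not in set(crit["phenotype"])


class TestKruskalWallis:
    def test_worked_value(self):
        h, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(float(stats.chi2.sf(2.4, 1)))

    def test_degenerate_identical(self):
        h, p = kruskal_wallis([5.0, 5.0], ["a", "b"])
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(PhenotypeError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_empty_group_rejected(self):
        with pytest.raises(PhenotypeError):
            kruskal_wallis([], [])
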
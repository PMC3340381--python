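import numpy as np
import pytest

from audiotwin import SimConfig, simulate_cohort


def clean_config(**kwargs) -> SimConfig:
    """Noise-free generator: observed PTA is an affine image of the latent
    level trait, so variance-component recovery is exact in expectation."""
    defaults = dict(
        n_mz_pairs=250,
        n_dz_pairs=250,
        n_singletons=0,
        slope_loadings=(0.0,) * 7,
        ear_noise_sd=0.0,
        round_to_5db=False,
        seed=0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig(n_mz_pairs=200, n_dz_pairs=200, n_singletons=15, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    return simulate_cohort(clean_config(seed=21))


@pytest.fixture(scope="session")
def phenotype_table(default_cohort):
    from audiotwin import audiogram_matrix, build_phenotypes, fit_pca

    matrix = audiogram_matrix(default_cohort)
    pca = fit_pca(matrix, n_components=2)
    return build_phenotypes(default_cohort, pca)


@pytest.fixture(scope="session")
def clean_table(clean_cohort):
    from audiotwin import audiogram_matrix, build_phenotypes, fit_pca
    from audiotwin.univariate import age_adjust

    matrix = audiogram_matrix(clean_cohort)
    pca = fit_pca(matrix, n_components=2)
    table = build_phenotypes(clean_cohort, pca)
    table["pta_adj"] = age_adjust(table, "pta")
    table["snr_adj"] = age_adjust(table, "snr")
    return table
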
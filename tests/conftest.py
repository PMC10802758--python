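import warnings

import numpy as np
import pandas as pd
import pytest

import vasculonet as v


@pytest.fixture(scope="session")
def default_cohort():
    """The desk-scale study cohort used across the suite."""
    return v.generate_cohort(v.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def corrected_cohort(default_cohort):
    """TAMPOR-corrected vascular matrix restricted to biological samples,
    plus traits carrying the batch column."""
    c = default_cohort
    mat = v.filter_missingness(c.vascular)
    res = v.tampor_correct(mat, c.design)
    bio = [s for s in res.corrected.columns if not c.design.loc[s, "is_gis"]]
    traits = c.traits.copy()
    traits["batch"] = c.design.loc[traits.index, "batch"]
    return c, res.corrected[bio], traits


@pytest.fixture(scope="session")
def small_cohort():
    cfg = v.GeneratorConfig(
        n_proteins=300, module_sizes=(60, 50, 40),
        marker_assignment={"endothelial": 0, "neuron": 1, "SMC": 2},
        disease_effects={0: {"AD": 0.5}}, gwas_enriched_modules=(0,),
        n_unique_vascular=10, n_unique_bulk=5, seed=7)
    return v.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_block_matrix(rng, n_blocks=3, block_size=50, within=0.1, between=0.9):
    """Block-structured dissimilarity for tree-cut tests."""
    n = n_blocks * block_size
    D = np.full((n, n), between)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        D[sl, sl] = within
    np.fill_diagonal(D, 0.0)
    return D
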
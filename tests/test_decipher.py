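"""NMF factorization, bootstrap-stability rank selection and refitting.

The factorization is cross-checked against scikit-learn's NMF as an
independent oracle, and the exposure refit against an exhaustive simplex
grid search.
"""

import numpy as np
import pytest

from cancersig.decipher import (
    DecipherConfig,
    decipher,
    match_signatures,
    nmf_factorize,
    refit_exposures,
    select_k,
)
from cancersig.fixtures import make_planted_cohort
from cancersig.matrix import FeatureMatrix
from cancersig.catalogs import build_full_catalog
from _oracles import grid_search_refit, random_signatures


# ----------------------------------------------------------------- NMF core

def test_rank_one_input_recovers_the_common_column():
    rng = np.random.default_rng(0)
    v = rng.dirichlet(np.ones(40))
    V = np.tile(v[:, None], (1, 12))
    P, E, errs = nmf_factorize(V, k=1, seed=1)
    np.testing.assert_allclose(P[:, 0], v, atol=1e-6)
    assert errs[-1] < 1e-8
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)


def test_same_seed_gives_bitwise_identical_factors():
    rng = np.random.default_rng(1)
    V = rng.random((30, 10))
    P1, E1, _ = nmf_factorize(V, 3, seed=42)
    P2, E2, _ = nmf_factorize(V, 3, seed=42)
    assert np.array_equal(P1, P2)
    assert np.array_equal(E1, E2)


def test_objective_is_monotone_non_increasing():
    rng = np.random.default_rng(2)
    V = rng.random((50, 20))
    for seed in (0, 1, 2):
        _, _, errs = nmf_factorize(V, 4, seed=seed, max_iter=200, tolerance=0.0)
        diffs = np.diff(errs)
        assert np.all(diffs <= 1e-10)


def test_factor_constraints_and_errors():
    rng = np.random.default_rng(3)
    V = rng.random((20, 8))
    P, E, _ = nmf_factorize(V, 2, seed=0)
    assert np.all(P >= 0) and np.all(E >= 0)
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="out of range"):
        nmf_factorize(V, 0, seed=0)
    with pytest.raises(ValueError, match="out of range"):
        nmf_factorize(V, 9, seed=0)
    bad = V.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-negative and finite"):
        nmf_factorize(bad, 2, seed=0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_planted_factors_recovered_across_seeds(seed):
    """Well-separated planted signatures are recovered at cosine >= 0.95."""
    cohort = make_planted_cohort(3, 40, events_per_sample=5000, seed=100 + seed)
    P, E, _ = nmf_factorize(cohort.matrix.values, 3, seed=seed)
    _, cosines = match_signatures(cohort.P0, P)
    assert np.all(cosines >= 0.95)


def test_agrees_with_sklearn_nmf_oracle():
    """scikit-learn's NMF on the same planted matrix finds the same
    signatures (cosine >= 0.95 after matching) with comparable error."""
    from sklearn.decomposition import NMF

    cohort = make_planted_cohort(3, 40, events_per_sample=5000, seed=55)
    V = cohort.matrix.values
    P_own, _, errs = nmf_factorize(V, 3, seed=0)
    sk = NMF(n_components=3, init="random", random_state=0, max_iter=2000, tol=1e-8)
    W = sk.fit_transform(V)
    _, cosines = match_signatures(W, P_own)
    assert np.all(cosines >= 0.95)
    sk_err = np.linalg.norm(V - W @ sk.components_)
    assert errs[-1] <= 1.1 * sk_err + 1e-12


# ------------------------------------------------------------ rank selection

def small_config(**kw):
    defaults = dict(k_min=2, k_max=4, bootstrap_iterations=15, seed=5)
    defaults.update(kw)
    return DecipherConfig(**defaults)


def test_planted_three_signature_cohort_selects_k3():
    cohort = make_planted_cohort(3, 40, events_per_sample=5000, seed=5)
    diags, suggested = select_k(cohort.matrix, small_config())
    assert suggested == 3
    by_k = {d.k: d for d in diags}
    assert by_k[3].stability >= 0.9
    assert by_k[4].stability < by_k[3].stability


def test_single_signature_cohort_is_stable_only_at_k1():
    cohort = make_planted_cohort(1, 12, events_per_sample=5000, seed=6)
    diags, suggested = select_k(
        cohort.matrix, small_config(k_min=1, k_max=2, seed=6)
    )
    by_k = {d.k: d.stability for d in diags}
    assert by_k[1] > 0.95
    assert by_k[2] < by_k[1]
    assert suggested == 1


def test_identical_columns_support_no_multi_signature_solution():
    rng = np.random.default_rng(7)
    catalog = build_full_catalog()
    v = rng.dirichlet(np.ones(len(catalog)))
    V = np.tile(v[:, None], (1, 10))
    matrix = FeatureMatrix(catalog, [f"S{j}" for j in range(10)], V)
    diags, suggested = select_k(matrix, small_config(k_min=2, k_max=3, seed=7))
    assert suggested is None
    assert all(d.stability < 0.8 for d in diags)


def test_decipher_end_to_end_recovers_planted_signatures():
    cohort = make_planted_cohort(3, 40, events_per_sample=5000, seed=8)
    result = decipher(cohort.matrix, small_config(seed=8))
    assert result.k_selected == 3
    assert result.P.k == 3
    result.P.validate_stochastic()
    assert np.all(result.E.values >= 0)
    _, cosines = match_signatures(cohort.P0, result.P.values)
    assert np.all(cosines >= 0.95)
    # exposures reproduce the matrix closely
    recon = result.P.values @ result.E.values
    assert np.linalg.norm(recon - cohort.matrix.values) / np.linalg.norm(
        cohort.matrix.values
    ) < 0.2


# -------------------------------------------------------------- refitting

def test_refit_trivial_cases():
    P = random_signatures(3, seed=9)
    r = refit_exposures(P, P[:, 1].copy())
    np.testing.assert_allclose(r.fractions, [0, 1, 0], atol=1e-9)
    assert r.error < 1e-12

    m = 0.5 * P[:, 0] + 0.5 * P[:, 1]
    r = refit_exposures(P, m)
    np.testing.assert_allclose(r.fractions, [0.5, 0.5, 0.0], atol=1e-9)

    # disjoint support: nothing to fit, residual is the whole profile
    m_orth = np.zeros(P.shape[0])
    dead = np.all(P == 0, axis=1)
    assert dead.sum() == 0
    P2 = P.copy()
    P2[:10, :] = 0.0
    m_orth[:10] = 0.3
    r = refit_exposures(P2, m_orth)
    np.testing.assert_allclose(r.exposures, 0.0, atol=1e-12)
    assert r.error == pytest.approx(np.linalg.norm(m_orth))

    z = refit_exposures(P, np.zeros(P.shape[0]))
    assert z.all_zero and z.error == 0.0


def test_refit_conservation_identity():
    P = random_signatures(3, seed=10)
    rng = np.random.default_rng(10)
    m = rng.random(P.shape[0])
    r = refit_exposures(P, m)
    np.testing.assert_array_equal(r.residual, m - r.reconstruction)


@pytest.mark.parametrize("k, seed", [(2, 11), (2, 12), (3, 13), (3, 14)])
def test_refit_matches_simplex_grid_oracle(k, seed):
    P = random_signatures(k, seed=seed)
    rng = np.random.default_rng(seed)
    true_f = rng.dirichlet(np.ones(k))
    m = P @ true_f + rng.normal(0, 0.001, P.shape[0]).clip(min=0)
    r = refit_exposures(P, m)
    grid_f, grid_err = grid_search_refit(P, m)
    np.testing.assert_allclose(r.fractions, grid_f, atol=1.5e-3)
    assert r.error <= grid_err + 1e-9
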
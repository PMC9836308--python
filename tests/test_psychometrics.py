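"""Reliability and EFA tests, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

import haisac
from haisac.psychometrics import (
    bartlett_sphericity,
    cronbach_alpha,
    efa,
    factor_scores,
    kmo,
    principal_axis_factoring,
    promax_rotation,
)

from conftest import make_data_with_exact_corr


# ---------------------------------------------------------------------------
# Cronbach's alpha

def test_alpha_identical_items_is_one():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100)
    assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)


def test_alpha_uncorrelated_items_near_zero():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20_000, 5))
    assert cronbach_alpha(X) == pytest.approx(0.0, abs=0.05)


def test_alpha_matches_pingouin_oracle():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    X = rng.standard_normal((200, 6)) + rng.standard_normal((200, 1))
    ours = cronbach_alpha(X)
    theirs = pg.cronbach_alpha(pd.DataFrame(X))[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_alpha_shift_invariance_and_errors():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((50, 4))
    shifted = X + np.array([10.0, -3.0, 0.5, 100.0])
    assert cronbach_alpha(X) == pytest.approx(cronbach_alpha(shifted))
    with pytest.raises(ValueError):
        cronbach_alpha(np.ones((10, 3)))  # zero total variance
    with pytest.raises(ValueError):
        cronbach_alpha(np.random.default_rng(0).standard_normal((1, 3)))


# ---------------------------------------------------------------------------
# KMO

def _kmo_bruteforce(R):
    """Independent KMO oracle: partial correlations by explicit regression."""
    p = R.shape[0]
    partial = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            if not others:
                partial[i, j] = R[i, j]
                continue
            Roo = R[np.ix_(others, others)]
            ri = R[np.ix_([i], others)].ravel()
            rj = R[np.ix_([j], others)].ravel()
            bi = np.linalg.solve(Roo, ri)
            bj = np.linalg.solve(Roo, rj)
            num = R[i, j] - ri @ bj
            den = np.sqrt((1 - ri @ bi) * (1 - rj @ bj))
            partial[i, j] = num / den
    r2 = R**2
    np.fill_diagonal(r2, 0)
    q2 = partial**2
    return r2.sum() / (r2.sum() + q2.sum())


@pytest.mark.parametrize(
    "R",
    [
        np.array(  # two blocks of two, r=0.8 within, 0 between
            [[1, 0.8, 0, 0], [0.8, 1, 0, 0], [0, 0, 1, 0.8], [0, 0, 0.8, 1]]
        ),
        np.full((4, 4), 0.01) + np.eye(4) * 0.99,  # near-identity → KMO ≈ 0.5
        np.array([[1, 0.5, 0.3], [0.5, 1, 0.4], [0.3, 0.4, 1]]),
    ],
)
def test_kmo_matches_bruteforce_oracle(R):
    rng = np.random.default_rng(4)
    X = make_data_with_exact_corr(R, 500, rng)
    overall, per_item = kmo(X)
    assert overall == pytest.approx(_kmo_bruteforce(R), abs=1e-8)
    assert np.all((per_item >= 0) & (per_item <= 1))


def test_kmo_near_identity_is_half():
    R = np.full((4, 4), 0.01) + np.eye(4) * 0.99
    X = make_data_with_exact_corr(R, 500, np.random.default_rng(5))
    overall, _ = kmo(X)
    assert overall == pytest.approx(0.5, abs=0.01)


def test_kmo_duplicated_item_errors():
    rng = np.random.default_rng(6)
    x = rng.standard_normal((100, 3))
    X = np.column_stack([x, x[:, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kmo(X)


def test_kmo_rescaling_invariance():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((300, 5)) + 0.6 * rng.standard_normal((300, 1))
    a, _ = kmo(X)
    b, _ = kmo(X * np.array([2.0, 0.1, 5.0, 1.0, 30.0]))
    assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# Bartlett

def test_bartlett_identity_correlation():
    X = make_data_with_exact_corr(np.eye(4), 200, np.random.default_rng(8))
    chi2, df, p = bartlett_sphericity(X)
    assert chi2 == pytest.approx(0.0, abs=1e-8)
    assert df == 6
    assert p == pytest.approx(1.0)


def test_bartlett_equicorrelation_closed_form():
    r, p_items, n = 0.5, 3, 100
    R = np.full((3, 3), r) + np.eye(3) * (1 - r)
    X = make_data_with_exact_corr(R, n, np.random.default_rng(9))
    chi2, df, _ = bartlett_sphericity(X)
    det = (1 - r) ** 2 * (1 + 2 * r)  # closed form for p=3 equicorrelation
    expected = -(n - 1 - (2 * p_items + 5) / 6) * np.log(det)
    assert chi2 == pytest.approx(expected, abs=1e-8)
    assert df == 3


def test_bartlett_battery_df(scored_battery):
    chi2, df, p = bartlett_sphericity(scored_battery)
    assert df == 10  # 5-item battery
    assert chi2 > 0 and p < 0.001


# ---------------------------------------------------------------------------
# Principal-axis factoring

def test_paf_recovers_exact_rank_one_model():
    lam = np.array([0.9, 0.8, 0.7])
    R = np.outer(lam, lam) + np.diag(1 - lam**2)
    L, comm = principal_axis_factoring(R, 1, tol=1e-10)
    assert np.allclose(L.ravel(), lam, atol=1e-6)
    assert np.allclose(comm, lam**2, atol=1e-6)


def test_paf_identity_gives_zero_loadings():
    L, comm = principal_axis_factoring(np.eye(4), 1, tol=1e-10)
    assert np.allclose(L, 0.0, atol=1e-8)


def test_paf_recovers_two_factor_construction():
    lam = np.array(
        [[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 0.75], [0.0, 0.65], [0.2, 0.6]]
    )
    R = lam @ lam.T + np.diag(1 - (lam**2).sum(axis=1))
    L, comm = principal_axis_factoring(R, 2, tol=1e-10)
    # orthogonal fit is identified only up to rotation: compare communalities
    # and the reproduced off-diagonal correlations
    assert np.allclose(comm, (lam**2).sum(axis=1), atol=1e-6)
    fitted = L @ L.T
    off = ~np.eye(6, dtype=bool)
    assert np.allclose(fitted[off], R[off], atol=1e-6)


def test_paf_agrees_with_statsmodels_oracle(scored_battery):
    smf = pytest.importorskip("statsmodels.multivariate.factor")
    R = np.corrcoef(scored_battery.to_numpy(dtype=float), rowvar=False)
    L, comm = principal_axis_factoring(R, 2)
    res = smf.Factor(corr=R, n_factor=2, method="pa", smc=True).fit()
    theirs = (np.asarray(res.loadings) ** 2).sum(axis=1)
    # both iterate the same update but stop by different criteria on a
    # slowly drifting communality ridge, hence the loose tolerance
    assert np.allclose(comm, theirs, atol=0.02)


def test_paf_rejects_bad_inputs():
    with pytest.raises(ValueError):
        principal_axis_factoring(np.eye(3), 3)
    with pytest.raises(ValueError):
        principal_axis_factoring(np.eye(3)[:2], 1)


def test_paf_improves_offdiagonal_fit_over_smc_start():
    """Converged solution reproduces off-diagonal correlations at least as
    well as the first (SMC-start) iterate."""
    lam = np.array([[0.8, 0.1], [0.7, -0.1], [0.5, 0.5], [0.1, 0.7], [0.0, 0.6]])
    R0 = lam @ lam.T + np.diag(1 - (lam**2).sum(axis=1))
    X = make_data_with_exact_corr(R0, 400, np.random.default_rng(10))
    R = np.corrcoef(X, rowvar=False)
    off = ~np.eye(5, dtype=bool)

    Rinv = np.linalg.inv(R)
    h0 = 1 - 1 / np.diag(Rinv)
    R_red = R.copy()
    np.fill_diagonal(R_red, h0)
    w, V = np.linalg.eigh(R_red)
    order = np.argsort(w)[::-1][:2]
    L_start = V[:, order] * np.sqrt(np.clip(w[order], 0, None))
    start_resid = np.abs((L_start @ L_start.T)[off] - R[off]).sum()

    L, _ = principal_axis_factoring(R, 2)
    final_resid = np.abs((L @ L.T)[off] - R[off]).sum()
    assert final_resid <= start_resid + 1e-12


# ---------------------------------------------------------------------------
# Promax rotation

def test_promax_fixed_point_on_simple_structure():
    lam = np.array([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.75]])
    pattern, phi = promax_rotation(lam)
    # align columns/signs to the input before comparing
    order = np.argsort(-np.abs(pattern[0]))
    pattern = pattern[:, order] * np.sign(pattern[0, order[0]])
    assert np.allclose(np.abs(pattern), lam, atol=1e-6)
    assert np.allclose(np.abs(phi - np.eye(2))[~np.eye(2, dtype=bool)], 0.0, atol=1e-6)


def test_promax_single_factor_errors():
    with pytest.raises(ValueError):
        promax_rotation(np.array([[0.9], [0.8]]))


def test_promax_matches_r_oracle():
    """Frozen oracle: R stats::promax(lam, m=4) pattern and factor correlation."""
    lam = np.array(
        [[0.75, 0.15], [0.7, 0.05], [0.62, -0.05], [0.1, 0.7], [0.0, 0.66], [0.25, 0.55]]
    )
    pattern, phi = promax_rotation(lam, power=4)
    r_pattern = np.array(
        [
            [0.743117423, 0.07797359],
            [0.705971687, -0.01926819],
            [0.638274892, -0.11349269],
            [0.005427996, 0.70583662],
            [-0.090899788, 0.67498602],
            [0.178842332, 0.53734424],
        ]
    )
    assert np.abs(pattern - r_pattern).max() < 1e-3
    assert phi[0, 1] == pytest.approx(0.2303675, abs=1e-3)


def test_promax_preserves_model_fit():
    """Pattern·Φ·Patternᵀ reproduces the common part: rotation does not change fit."""
    lam = np.array(
        [[0.8, 0.0], [0.7, 0.1], [0.6, 0.0], [0.05, 0.75], [0.0, 0.65], [0.3, 0.5]]
    )
    R = lam @ lam.T + np.diag(1 - (lam**2).sum(axis=1))
    L, _ = principal_axis_factoring(R, 2, tol=1e-10)
    pattern, phi = promax_rotation(L)
    assert np.allclose(pattern @ phi @ pattern.T, L @ L.T, atol=1e-8)


# ---------------------------------------------------------------------------
# Full EFA pipeline and factor scores

def test_efa_two_block_orthogonal_battery_has_uncorrelated_factors():
    lam = np.array(
        [[0.8, 0.0], [0.75, 0.0], [0.7, 0.0], [0.0, 0.8], [0.0, 0.75], [0.0, 0.7]]
    )
    R = lam @ lam.T + np.diag(1 - (lam**2).sum(axis=1))
    X = make_data_with_exact_corr(R, 2000, np.random.default_rng(11))
    res = efa(pd.DataFrame(X), n_factors=2)
    assert abs(res.factor_correlation[0, 1]) < 0.1
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # sorted descending


def test_efa_auto_selects_two_factors_on_continuous_default_battery(factor_spec):
    rng = np.random.default_rng(5)
    X = rng.multivariate_normal(
        np.zeros(5), factor_spec.implied_correlation(), size=5000
    )
    res = efa(pd.DataFrame(X, columns=factor_spec.items))
    assert res.n_factors == 2


def test_efa_variance_explained_orders_factors(scored_battery):
    res = efa(scored_battery, n_factors=2)
    assert res.variance_explained[0] >= res.variance_explained[1] > 0
    assert res.pattern_loadings.shape == (5, 2)
    # strongest item of each factor loads positively (sign convention)
    for j in range(2):
        col = res.pattern_loadings[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_factor_scores_examples_and_errors():
    X = np.array([[10.0, 6.0], [2.0, 4.0]])
    assert np.allclose(factor_scores(X, np.eye(2)), X)
    assert np.allclose(factor_scores(X, np.zeros((2, 2))), 0.0)
    assert factor_scores(X, np.array([[0.5], [0.5]]))[0, 0] == pytest.approx(8.0)
    with pytest.raises(ValueError):
        factor_scores(X, np.ones((3, 2)))


def test_reliability_bundle_on_default_battery(scored_battery):
    rel = haisac.reliability(scored_battery)
    # band implied by the generating model (measured across seeds), and the
    # published adequacy conclusions: KMO comfortably above 0.6, Bartlett rejects
    assert 0.75 <= rel.alpha <= 0.85
    assert 0.6 <= rel.kmo_overall <= 0.9
    assert rel.bartlett_df == 10 and rel.bartlett_p < 1e-10
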
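"""PCA and OPLS-DA against independent oracles and algebraic invariants."""

import numpy as np
import pytest

from thyromet.chemometrics import (OPLSDAModel, ScalingParams, fit_oplsda,
                                   fit_pca, predict, predict_class)
from thyromet.errors import RankError, SchemaError, ValidationError


def nipals_pls1(X, y):
    """Independent single-component NIPALS PLS1 on pre-scaled data.

    Closed form for one response: w = X'y/||X'y||, t = Xw.
    """
    w = X.T @ y
    w = w / np.linalg.norm(w)
    t = X @ w
    return w, t


def _scale(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


# --- scaling ---------------------------------------------------------------

def test_scaling_round_trip(rng):
    X = rng.normal(3.0, 2.0, (12, 7))
    for mode in ("mean_center", "unit_variance"):
        sc = ScalingParams.fit(X, mode)
        np.testing.assert_allclose(sc.invert(sc.apply(X)), X, atol=1e-10)


def test_unit_variance_scaling_rejects_constant_column(rng):
    X = rng.normal(size=(10, 3))
    X[:, 1] = 5.0
    with pytest.raises(ValidationError):
        ScalingParams.fit(X, "unit_variance")


# --- PCA -------------------------------------------------------------------

def test_pca_identical_rows_zero_scores():
    X = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (6, 1))
    X[0, 0] += 1e-9  # avoid the all-constant degenerate case
    model = fit_pca(X, 1)
    assert np.abs(model.scores).max() < 1e-6


def test_pca_matches_svd_oracle(rng):
    X = rng.normal(size=(20, 50))
    model = fit_pca(X, 5)
    Xc = X - X.mean(0)
    s = np.linalg.svd(Xc, compute_uv=False)
    np.testing.assert_allclose(model.explained_variance_fraction,
                               s[:5] ** 2 / (s**2).sum(), atol=1e-8)
    # rank-k reconstruction equals the truncated SVD reconstruction
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    np.testing.assert_allclose(model.scores @ model.loadings.T,
                               U[:, :5] @ np.diag(sv[:5]) @ Vt[:5], atol=1e-8)


def test_pca_scores_centered_and_loadings_orthonormal(rng):
    model = fit_pca(rng.normal(size=(15, 30)), 4)
    np.testing.assert_allclose(model.scores.sum(0), 0.0, atol=1e-9)
    np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4),
                               atol=1e-8)
    ev = model.explained_variance_fraction
    assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-12


def test_pca_validation_errors(rng):
    with pytest.raises(ValidationError):
        fit_pca(rng.normal(size=(5, 3)), 10)
    with pytest.raises(ValidationError):
        fit_pca(np.ones((6, 4)), 1)


# --- OPLS-DA ---------------------------------------------------------------

def test_perfect_single_column_gives_r2y_one(rng):
    y = np.array([0, 0, 0, 1, 1, 1])
    X = rng.normal(size=(6, 4))
    X[:, 2] = y * 2.0 - 1.0
    model = fit_oplsda(X, y, n_ortho=0, scaling="mean_center")
    # noiseless informative column: the fit cannot be perfect unless that
    # column dominates; build X purely from y to pin R2Y = 1
    X2 = np.outer(y * 2.0 - 1.0, np.array([0.5, -1.0, 2.0]))
    X2 += rng.normal(scale=1e-12, size=X2.shape)
    m2 = fit_oplsda(X2, y, n_ortho=0, scaling="mean_center")
    assert abs(m2.R2Y - 1.0) < 1e-8
    assert model.R2Y <= 1.0


def test_oplsda_zero_ortho_equals_nipals_pls1(rng):
    y = np.array([0] * 8 + [1] * 7)
    X = rng.normal(size=(15, 40)) + np.outer(y, rng.normal(size=40))
    model = fit_oplsda(X, y, n_ortho=0)
    Xs = _scale(X)
    _, t_oracle = nipals_pls1(Xs, y - y.mean())
    np.testing.assert_allclose(model.t, t_oracle, atol=1e-8)


def test_orthogonal_filtering_improves_score_correlation(rng):
    """Removing structured y-orthogonal variation never hurts corr(t, y):
    X = y a' + z c' + noise with z orthogonal to y."""
    wins = 0
    for rep in range(50):
        r = np.random.default_rng(rep)
        y = np.array([0] * 10 + [1] * 10, dtype=float)
        yc = y - y.mean()
        z = r.normal(size=20)
        z -= z @ yc / (yc @ yc) * yc  # orthogonalize
        X = (np.outer(yc, r.normal(size=30))
             + 3.0 * np.outer(z, r.normal(size=30))
             + 0.5 * r.normal(size=(20, 30)))
        t1 = fit_oplsda(X, y, n_ortho=1).t
        t0 = fit_oplsda(X, y, n_ortho=0).t
        c1 = np.corrcoef(t1, y)[0, 1]
        c0 = np.corrcoef(t0, y)[0, 1]
        wins += c1 >= c0 - 1e-12
    assert wins >= 45


def test_score_orthogonality_and_r2x_partition(rng):
    y = np.array([0] * 9 + [1] * 9)
    X = rng.normal(size=(18, 25)) + np.outer(y, rng.normal(size=25))
    model = fit_oplsda(X, y, n_ortho=2)
    for i in range(2):
        t_o = model.T_o[:, i]
        cos = model.t @ t_o / (np.linalg.norm(model.t) * np.linalg.norm(t_o))
        assert abs(cos) < 1e-8
        assert abs(model.w @ model.W_o[:, i]) < 1e-8
    # predictive + orthogonal + residual variance fractions sum to 1
    Xs = _scale(X)
    resid = Xs.copy()
    for i in range(2):
        resid -= np.outer(model.T_o[:, i], model.P_o[:, i])
    resid -= np.outer(model.t, model.p_load)
    frac_resid = (resid**2).sum() / (Xs**2).sum()
    assert abs(model.R2X_pred + model.R2X_ortho + frac_resid - 1.0) < 1e-8
    assert 0 <= model.R2X <= 1 and 0 <= model.R2Y <= 1
    assert abs(model.w @ model.w - 1) < 1e-10


def test_sample_permutation_equivariance(rng):
    y = np.array([0] * 7 + [1] * 7)
    X = rng.normal(size=(14, 20)) + np.outer(y, rng.normal(size=20))
    perm = rng.permutation(14)
    m1 = fit_oplsda(X, y, n_ortho=1)
    m2 = fit_oplsda(X[perm], y[perm], n_ortho=1)
    np.testing.assert_allclose(m1.t[perm], m2.t, atol=1e-8)
    np.testing.assert_allclose(m1.w, m2.w, atol=1e-8)


def test_predict_consistency_and_duplicates(rng):
    y = np.array([0] * 8 + [1] * 8)
    X = rng.normal(size=(16, 12)) + np.outer(y, rng.normal(size=12))
    model = fit_oplsda(X, y, n_ortho=1)
    np.testing.assert_allclose(predict(model, X), model.y_fitted, atol=1e-10)
    two = predict(model, np.vstack([X[3], X[3]]))
    assert two[0] == two[1]


def test_predict_variable_mismatch_raises(rng):
    y = np.array([0] * 5 + [1] * 5)
    X = rng.normal(size=(10, 8))
    model = fit_oplsda(X, y, n_ortho=0)
    with pytest.raises(SchemaError):
        predict(model, rng.normal(size=(3, 5)))


def test_worked_four_sample_example():
    """Hand-computed oracle on a tiny 4x2 problem, mean-center scaling,
    no orthogonal component: w ~ Xc'yc, t = Xc w, b = t'yc/t't.

    Column means (2.5, 2); Xc'yc = (2, 1) so w = (2, 1)/sqrt(5),
    t = (-3, -2, 2, 3)/sqrt(5), b = sqrt(5)/5.2,
    yhat = (-0.0769, 0.1154, 0.8846, 1.0769) to 4 dp.
    """
    X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0], [4.0, 2.0]])
    y = np.array([0, 0, 1, 1])
    model = fit_oplsda(X, y, n_ortho=0, scaling="mean_center")
    s5 = np.sqrt(5.0)
    np.testing.assert_allclose(model.w, np.array([2.0, 1.0]) / s5, atol=1e-12)
    np.testing.assert_allclose(model.t, np.array([-3.0, -2.0, 2.0, 3.0]) / s5,
                               atol=1e-12)
    np.testing.assert_allclose(model.b, s5 / 5.2, atol=1e-12)
    yhat_oracle = (s5 / 5.2) * (np.array([-3.0, -2.0, 2.0, 3.0]) / s5) + 0.5
    np.testing.assert_allclose(predict(model, X), yhat_oracle, atol=1e-12)
    assert list(predict_class(model, X)) == [0, 0, 1, 1]


def test_zero_variance_columns_dropped(rng):
    y = np.array([0] * 6 + [1] * 6)
    X = rng.normal(size=(12, 5)) + np.outer(y, rng.normal(size=5))
    X[:, 3] = 7.0
    model = fit_oplsda(X, y, n_ortho=0)
    assert model.kept.sum() == 4 and not model.kept[3]
    assert predict(model, X).shape == (12,)


def test_oplsda_error_cases(rng):
    X = rng.normal(size=(8, 6))
    with pytest.raises(ValidationError):
        fit_oplsda(X, np.zeros(8), n_ortho=0)  # single class
    with pytest.raises(RankError):
        fit_oplsda(X, np.array([0] * 4 + [1] * 4), n_ortho=7)


def test_model_json_round_trip(tmp_path, rng):
    y = np.array([0] * 6 + [1] * 6)
    X = rng.normal(size=(12, 9)) + np.outer(y, rng.normal(size=9))
    model = fit_oplsda(X, y, n_ortho=1)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = OPLSDAModel.from_json(path)
    np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)
    assert back.n_ortho == model.n_ortho and back.classes == model.classes
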
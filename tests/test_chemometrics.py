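"""Scaling, NIPALS models, VIP, validation statistics and jack-knife."""

import numpy as np
import pytest
from scipy import stats

from aromakey import chemometrics as chem


# ---------------------------------------------------------------------------
# autoscaling
# ---------------------------------------------------------------------------

def test_unit_variance_basic():
    sx = chem.autoscale(np.array([[1.0], [2.0], [3.0]]))
    assert sx.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])


def test_constant_column_flagged():
    sx = chem.autoscale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
    assert sx.constant_columns[0] and not sx.constant_columns[1]
    assert np.all(sx.values[:, 0] == 0.0)


@pytest.mark.parametrize("mode", ["unit_variance", "pareto", "center_only"])
def test_inverse_round_trip(mode):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(5, 4)) * 10 + 3
    sx = chem.autoscale(X, mode)
    assert np.abs(sx.inverse() - X).max() < 1e-9
    if mode == "unit_variance":
        assert np.abs(sx.values.mean(axis=0)).max() < 1e-10
        assert np.abs(sx.values.var(axis=0, ddof=1) - 1).max() < 1e-8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_explains_everything():
    u = np.array([1.0, -2.0, 0.5, 3.0])
    v = np.array([2.0, 1.0, -1.0])
    X = np.outer(u, v)
    X -= X.mean(axis=0)
    m = chem.pca_fit(X, 2)
    assert m.explained_per_component[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_scores_orthogonal_and_variance_ordered():
    rng = np.random.default_rng(4)
    sx = chem.autoscale(rng.normal(size=(8, 5)))
    m = chem.pca_fit(sx.values, 4)
    gram = m.T.T @ m.T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
    assert all(a >= b - 1e-12 for a, b in
               zip(m.explained_per_component, m.explained_per_component[1:]))
    assert sum(m.explained_per_component) <= 1 + 1e-12


def test_pca_matches_svd_oracle():
    rng = np.random.default_rng(6)
    for _ in range(20):
        sx = chem.autoscale(rng.normal(size=(6, 5)))
        m = chem.pca_fit(sx.values, 3)
        U, S, _ = np.linalg.svd(sx.values, full_matrices=False)
        for a in range(3):
            t_svd = U[:, a] * S[a]
            err = min(np.abs(m.T[:, a] - t_svd).max(),
                      np.abs(m.T[:, a] + t_svd).max())
            assert err < 1e-8


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def test_pls_exact_linear_recovery():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(12, 4))
    Y = X @ np.array([[1.0], [-2.0], [0.5], [3.0]])
    sx, sy = chem.autoscale(X), chem.autoscale(Y)
    m = chem.pls_fit(sx.values, sy.values, 4)
    assert m.R2Y == pytest.approx(1.0, abs=1e-8)
    assert np.abs(sx.values @ m.B - sy.values).max() < 1e-8


def test_pls_first_weight_matches_eigen_oracle():
    rng = np.random.default_rng(9)
    X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 2))
    sx, sy = chem.autoscale(X), chem.autoscale(Y)
    m = chem.pls_fit(sx.values, sy.values, 1)
    M = sx.values.T @ sy.values @ sy.values.T @ sx.values
    w_eig = np.linalg.eigh(M)[1][:, -1]
    err = min(np.abs(m.W[:, 0] - w_eig).max(), np.abs(m.W[:, 0] + w_eig).max())
    assert err < 1e-8


def test_pls_predictions_match_sklearn_cross_check():
    """Independent route: fitted values agree with sklearn's NIPALS PLS."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(11)
    X, Y = rng.normal(size=(10, 5)), rng.normal(size=(10, 2))
    sx, sy = chem.autoscale(X), chem.autoscale(Y)
    ours = chem.pls_fit(sx.values, sy.values, 3)
    ref = PLSRegression(n_components=3, scale=False, tol=1e-12,
                        max_iter=5000).fit(sx.values, sy.values)
    assert sx.values @ ours.B == pytest.approx(ref.predict(sx.values),
                                               abs=1e-6)


def test_pls_zero_y_gives_zero_coefficients():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(6, 3))
    m = chem.pls_fit(chem.autoscale(X).values, np.zeros((6, 1)), 2)
    assert np.all(m.B == 0.0)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def test_opls_separable_classes_near_perfect_r2y():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 4), scale=0.01)
    X[:6, 0] += 10
    sx = chem.autoscale(X, "center_only")
    m = chem.opls_da_fit(sx.values, ["A"] * 6 + ["B"] * 6, n_orth=0)
    assert m.R2Y >= 0.99


def test_opls_recovers_planted_orthogonal_direction():
    rng = np.random.default_rng(13)
    n = 20
    y_dir = np.repeat([1.0, -1.0], n // 2)
    orth = np.sin(np.arange(n))          # structured, y-orthogonal-ish
    orth -= orth @ y_dir / (y_dir @ y_dir) * y_dir
    X = (np.outer(y_dir, [1, 1, 0, 0, 0])
         + 4 * np.outer(orth, [0, 0, 1, 1, 1])
         + rng.normal(size=(n, 5), scale=0.05))
    labels = ["A"] * (n // 2) + ["B"] * (n // 2)
    m = chem.opls_da_fit(chem.autoscale(X).values, labels, n_orth=1)
    t_o = m.T_orth[:, 0]
    r_orth = np.corrcoef(t_o, orth)[0, 1]
    r_pred = np.corrcoef(m.T[:, 0], y_dir)[0, 1]
    assert abs(r_orth) > 0.95
    assert abs(r_pred) > 0.95


def test_opls_orthogonal_scores_orthogonal_to_class_vector():
    rng = np.random.default_rng(14)
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.normal(size=(10, 6))
        labels = ["A"] * 5 + ["B"] * 5
        m = chem.opls_da_fit(chem.autoscale(X).values, labels, n_orth=2)
        y = m.meta["y"]
        if m.T_orth.size:
            assert np.abs(m.T_orth.T @ y).max() < 1e-8


def test_opls_null_q2_negative_in_median():
    q2s = []
    for seed in range(40):
        rng = np.random.default_rng(20_000 + seed)
        X = rng.normal(size=(12, 6))
        labels = rng.permutation(["A"] * 6 + ["B"] * 6)
        q2s.append(chem.opls_da_cv(chem.autoscale(X).values, labels,
                                   n_orth=0, folds=6))
    assert np.median(q2s) < 0


def test_q2_never_exceeds_r2y_on_training_fit():
    for seed in range(8):
        rng = np.random.default_rng(30_000 + seed)
        X = rng.normal(size=(12, 5))
        X[:6] += rng.normal(scale=1.0, size=5)
        labels = ["A"] * 6 + ["B"] * 6
        sx = chem.autoscale(X)
        m = chem.opls_da_fit(sx.values, labels, n_orth=1)
        q2 = chem.opls_da_cv(sx.values, labels, n_orth=1, folds=6)
        assert q2 <= m.R2Y + 1e-10


# ---------------------------------------------------------------------------
# cross-validated Q2
# ---------------------------------------------------------------------------

def test_q2_noise_free_linear_relation():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(14, 3))
    Y = X @ np.array([[2.0], [-1.0], [0.5]])
    sx, sy = chem.autoscale(X), chem.autoscale(Y)
    q2 = chem.q2_cross_validation(lambda a, b: chem.pls_fit(a, b, 3),
                                  sx.values, sy.values, folds=7)
    assert q2 > 0.99


def test_q2_leave_one_out_matches_hand_press():
    # 1 predictor, 1 response: a 1-component PLS1 fit equals least squares
    # through the centered origin; PRESS can be assembled by hand.
    x = np.array([[1.0], [2.0], [4.0]])
    y = np.array([[2.0], [4.0], [7.0]])
    sx, sy = chem.autoscale(x), chem.autoscale(y)
    xs, ys = sx.values[:, 0], sy.values[:, 0]
    press = 0.0
    for i in range(3):
        keep = np.arange(3) != i
        slope = (xs[keep] @ ys[keep]) / (xs[keep] @ xs[keep])
        press += (ys[i] - slope * xs[i]) ** 2
    expected = 1 - press / (ys @ ys)
    q2 = chem.q2_cross_validation(lambda a, b: chem.pls_fit(a, b, 1),
                                  sx.values, sy.values, folds=3)
    assert q2 == pytest.approx(expected, abs=1e-10)


def test_venetian_folds_deterministic():
    folds = chem.venetian_folds(12, 7)
    assert [list(f) for f in folds[:3]] == [[0, 7], [1, 8], [2, 9]]


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def test_vip_single_driver_limit():
    rng = np.random.default_rng(16)
    n, p = 20, 4
    x0 = rng.normal(size=n)
    X = np.zeros((n, p))
    X[:, 0] = x0
    Y = x0[:, None] * 2.0
    m = chem.pls_fit(X - X.mean(axis=0), Y - Y.mean(axis=0), 1)
    v = chem.vip(m)
    assert v[0] == pytest.approx(np.sqrt(p), abs=1e-8)
    assert np.abs(v[1:]).max() < 1e-8


def test_vip_normalization_identity():
    rng = np.random.default_rng(17)
    for seed in range(10):
        r = np.random.default_rng(seed)
        X, Y = r.normal(size=(9, 5)), r.normal(size=(9, 2))
        m = chem.pls_fit(chem.autoscale(X).values, chem.autoscale(Y).values, 3)
        v = chem.vip(m)
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=1e-8)


def test_vip_matches_brute_force_formula():
    rng = np.random.default_rng(18)
    X, Y = rng.normal(size=(8, 4)), rng.normal(size=(8, 1))
    m = chem.pls_fit(chem.autoscale(X).values, chem.autoscale(Y).values, 2)
    p, a = m.W.shape
    ssy = [float((m.C[:, j] @ m.C[:, j]) * (m.T[:, j] @ m.T[:, j]))
           for j in range(a)]
    expected = np.zeros(p)
    for j in range(p):
        acc = sum(ssy[c] * (m.W[j, c] / np.linalg.norm(m.W[:, c])) ** 2
                  for c in range(a))
        expected[j] = np.sqrt(p * acc / sum(ssy))
    assert chem.vip(m) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_minimum_p_with_strong_signal():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(12, 5), scale=0.05)
    X[:6, :2] += 8
    labels = ["A"] * 6 + ["B"] * 6
    res = chem.permutation_test(chem.autoscale(X).values, labels,
                                n_permutations=200, n_orth=0, folds=6, rng=1)
    assert res.p_value == pytest.approx(1 / 201)
    assert res.observed_q2 > max(res.permuted_q2)


def test_identity_permutation_reproduces_observed_q2():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(10, 4))
    labels = np.array(["A"] * 5 + ["B"] * 5)
    sx = chem.autoscale(X)
    q2_again = chem.opls_da_cv(sx.values, labels, n_orth=0, folds=5)
    res = chem.permutation_test(sx.values, labels, n_permutations=5,
                                n_orth=0, folds=5, rng=2)
    assert res.observed_q2 == pytest.approx(q2_again, abs=1e-12)


# ---------------------------------------------------------------------------
# CV-ANOVA
# ---------------------------------------------------------------------------

def test_cv_anova_null_self_comparison_is_unity():
    res = chem.cv_anova(press_model=5.0, press_null=5.0,
                        n_observations=12, n_model_components=0)
    assert res.F == pytest.approx(1.0)
    assert 0.3 < res.p_value < 0.7


def test_cv_anova_near_perfect_model_significant():
    res = chem.cv_anova(press_model=0.01, press_null=10.0,
                        n_observations=12, n_model_components=2)
    assert res.p_value < 0.05
    zero = chem.cv_anova(0.0, 10.0, 12, 2)
    assert np.isinf(zero.F) and zero.p_value == 0.0


def test_cv_anova_matches_hand_bookkeeping():
    # 8 observations, known PRESS values: assemble F and p by hand
    rng = np.random.default_rng(22)
    X = rng.normal(size=(8, 3))
    X[:4] += 2.0
    labels = ["A"] * 4 + ["B"] * 4
    sx = chem.autoscale(X)
    res = chem.cv_anova_opls(sx.values, labels, n_orth=0, folds=4)

    y_raw = np.array([0.0] * 4 + [1.0] * 4)
    press_model = press_null = 0.0
    for f in range(4):
        test = np.where(np.arange(8) % 4 == f)[0]
        train = np.setdiff1d(np.arange(8), test)
        m = chem.opls_da_fit(sx.values[train],
                             [labels[i] for i in train], n_orth=0)
        pred = m.predict(sx.values[test])[:, 0] + y_raw[train].mean()
        press_model += float(((y_raw[test] - pred) ** 2).sum())
        press_null += float(((y_raw[test] - y_raw[train].mean()) ** 2).sum())
    F = (press_null / 7) / (press_model / 6)
    assert res.F == pytest.approx(F, rel=1e-10)
    assert res.p_value == pytest.approx(float(stats.f.sf(F, 7, 6)), rel=1e-10)


# ---------------------------------------------------------------------------
# PLSR + correlation loadings
# ---------------------------------------------------------------------------

def test_identical_variable_and_attribute_share_a_point():
    rng = np.random.default_rng(23)
    base = rng.normal(size=(10,))
    X = np.column_stack([base, rng.normal(size=10)])
    Y = np.column_stack([base, rng.normal(size=10)])
    model, cl = chem.plsr_sensory(X, Y, ["x0", "x1"], ["y0", "y1"])
    assert cl.x_correlations[0] == pytest.approx(cl.y_correlations[0], abs=1e-9)
    assert cl.inner_radius == pytest.approx(np.sqrt(0.5))
    assert cl.outer_radius == 1.0


def test_correlation_loadings_inside_unit_circle():
    rng = np.random.default_rng(24)
    X, Y = rng.normal(size=(12, 5)), rng.normal(size=(12, 3))
    _, cl = chem.plsr_sensory(X, Y, list("abcde"), list("xyz"))
    radii = np.linalg.norm(np.vstack([cl.x_correlations, cl.y_correlations]),
                           axis=1)
    assert radii.max() <= 1 + 1e-9


def test_planted_pyrazines_fall_with_roasted_attribute(fixture_result,
                                                       fixture_truth):
    cl = fixture_result.correlation_loadings
    xcoord = dict(zip(cl.x_names, cl.x_correlations))
    ycoord = dict(zip(cl.y_names, cl.y_correlations))
    roasted = ycoord["roasted"]
    pyrazines = [n for (n, attr) in fixture_truth.correlation_signs
                 if attr == "roasted" and n in xcoord]
    assert len(pyrazines) >= 3
    for name in pyrazines:
        v = xcoord[name]
        cos = (v @ roasted) / (np.linalg.norm(v) * np.linalg.norm(roasted))
        assert cos > np.cos(np.deg2rad(45)), name


# ---------------------------------------------------------------------------
# jack-knife
# ---------------------------------------------------------------------------

def test_jackknife_noise_variable_not_significant():
    rng = np.random.default_rng(25)
    x0 = rng.normal(size=20)
    X = np.column_stack([x0, rng.normal(size=20)])
    Y = (x0 * 3.0 + rng.normal(scale=0.01, size=20))[:, None]
    res = chem.jackknife_significance(X, Y, n_components=1)
    assert res.significant[0, 0]
    assert not res.significant[1, 0]


def test_jackknife_exact_relation_near_zero_uncertainty():
    rng = np.random.default_rng(26)
    X = rng.normal(size=(10, 2))
    Y = (X @ np.array([1.0, -1.0]))[:, None]
    res = chem.jackknife_significance(X, Y, n_components=2)
    assert np.abs(res.uncertainties).max() < 1e-6
    assert res.significant.all()


def test_jackknife_matches_brute_force_loop():
    rng = np.random.default_rng(27)
    X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 2))
    res = chem.jackknife_significance(X, Y, n_components=2, alpha=0.05)

    def fit_b(Xf, Yf):
        sx, sy = chem.autoscale(Xf), chem.autoscale(Yf)
        B = chem.pls_fit(sx.values, sy.values, 2).B
        return B * sy.column_scales[None, :] / sx.column_scales[:, None]

    b = fit_b(X, Y)
    n = 5
    acc = np.zeros_like(b)
    for i in range(n):
        keep = np.arange(n) != i
        acc += (n - 1) / n * (fit_b(X[keep], Y[keep]) - b) ** 2
    s = np.sqrt(acc)
    assert res.coefficients == pytest.approx(b, abs=1e-10)
    assert res.uncertainties == pytest.approx(s, abs=1e-10)
    t_crit = stats.t.ppf(0.975, df=4)
    assert np.array_equal(res.significant, np.abs(b) > t_crit * s)
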
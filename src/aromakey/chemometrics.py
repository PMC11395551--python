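"""From-scratch multivariate core: PCA, PLS, OPLS-DA, VIP and validation.

All latent-variable models are fit by NIPALS on autoscaled data.
OPLS-DA follows the orthogonal-signal-correction construction: variation
orthogonal to the (centered) class vector is peeled off into dedicated
components before a single predictive component is fit, so the predictive
score axis carries all between-class separation.

Model quality is summarized the way the field's software reports it:

* ``R2X`` / ``R2Y`` — fraction of (scaled) X / Y variance explained by
  the fit;
* ``Q2 = 1 - PRESS / SS`` — cross-validated predictive ability with
  venetian-blind folds (observation *i* goes to fold ``i % folds``);
* VIP — variable importance in projection over the predictive
  components, normalized so that the mean squared VIP is 1;
* a label-permutation test (empirical p-value with the +1 correction)
  and a CV-ANOVA style F-test comparing cross-validated residuals of the
  model against the mean-only null;
* PLSR correlation loadings inside the 50 %/100 % explained-variance
  circles, with Martens' jack-knife uncertainty for coefficient
  significance.

Component signs are fixed so the largest-magnitude loading entry is
positive; given identical inputs, seeds and observation order every
result here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

_MAX_NIPALS_ITER = 5000
_NIPALS_TOL = 1e-28  # squared relative step; ~1e-14 in norm


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    values: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    scaling_mode: str
    constant_columns: np.ndarray  # boolean flags

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.column_means) / self.column_scales

    def inverse(self, values: Optional[np.ndarray] = None) -> np.ndarray:
        v = self.values if values is None else values
        return v * self.column_scales + self.column_means


def autoscale(X: np.ndarray, mode: str = "unit_variance") -> ScaledMatrix:
    """Center columns and scale them by sd (unit variance), √sd (pareto)
    or not at all (center_only). Constant columns get scale 1 and a flag."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("autoscale needs at least 2 observations")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    if mode == "unit_variance":
        scales = sd_safe
    elif mode == "pareto":
        scales = np.sqrt(sd_safe)
    elif mode == "center_only":
        scales = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return ScaledMatrix(
        values=(X - means) / scales,
        column_means=means,
        column_scales=scales,
        scaling_mode=mode,
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# latent models
# ---------------------------------------------------------------------------

@dataclass
class LatentModel:
    kind: str                       # pca | pls | opls_da | plsr
    T: np.ndarray                   # predictive scores, n × a
    P: np.ndarray                   # X loadings, p × a
    W: Optional[np.ndarray] = None  # X weights (PLS family), p × a
    C: Optional[np.ndarray] = None  # Y weights, m × a
    B: Optional[np.ndarray] = None  # regression coefficients, p × m
    T_orth: Optional[np.ndarray] = None
    P_orth: Optional[np.ndarray] = None
    W_orth: Optional[np.ndarray] = None
    R2X: float = 0.0
    R2Y: Optional[float] = None
    Q2: Optional[float] = None
    explained_per_component: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.T.shape[1]

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        """Predicted (scaled, centered) Y for PLS-family models."""
        if self.B is None:
            raise ValueError("model has no regression coefficients")
        X = np.asarray(X_scaled, dtype=float)
        if self.W_orth is not None and self.W_orth.shape[1]:
            X = remove_orthogonal(X, self.W_orth, self.P_orth)
        return X @ self.B


def _fix_sign(p: np.ndarray, *vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Flip a component so its largest-|loading| entry is positive."""
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return tuple(-v for v in (p, *vectors))
    return (p, *vectors)


def pca_fit(X_scaled: np.ndarray, k: int) -> LatentModel:
    """NIPALS principal component analysis of a scaled matrix."""
    X = np.array(X_scaled, dtype=float)
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    ss_tot = float((X ** 2).sum())
    T = np.zeros((n, k))
    P = np.zeros((p, k))
    explained = []
    for a in range(k):
        col = int(np.argmax((X ** 2).sum(axis=0)))
        t = X[:, col].copy()
        if not np.any(t):
            explained.append(0.0)  # rank exhausted: zero-variance component
            continue
        for _ in range(_MAX_NIPALS_ITER):
            pv = X.T @ t / (t @ t)
            pv /= np.linalg.norm(pv)
            t_new = X @ pv
            if np.sum((t_new - t) ** 2) < _NIPALS_TOL * max(t_new @ t_new, 1e-300):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(f"PCA NIPALS failed on component {a + 1}")
        pv, t = _fix_sign(pv, t)
        T[:, a], P[:, a] = t, pv
        X -= np.outer(t, pv)
        explained.append(float((t @ t) / ss_tot) if ss_tot > 0 else 0.0)
    return LatentModel(
        kind="pca", T=T, P=P,
        R2X=float(sum(explained)),
        explained_per_component=tuple(explained),
    )


def pls_fit(
    X_scaled: np.ndarray,
    Y_scaled: np.ndarray,
    n_components: int,
) -> LatentModel:
    """NIPALS PLS regression (PLS1 when Y has a single column).

    Components deflate both blocks; ``B`` reproduces the fitted Ŷ via
    ``B = W (PᵀW)⁻¹ Cᵀ``.
    """
    X = np.array(X_scaled, dtype=float)
    Y = np.atleast_2d(np.array(Y_scaled, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    m = Y.shape[1]
    a_max = min(n - 1, p)
    if n_components > a_max:
        raise ValueError(f"n_components={n_components} exceeds {a_max}")
    ss_x = float((X ** 2).sum())
    ss_y = float((Y ** 2).sum())

    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    explained_x = []
    for a in range(n_components):
        if not np.any(Y):
            break  # nothing left to model; trailing components dropped
        u = Y[:, int(np.argmax((Y ** 2).sum(axis=0)))].copy()
        t = np.zeros(n)
        for _ in range(_MAX_NIPALS_ITER):
            w = X.T @ u / (u @ u)
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                break
            w /= norm_w
            t_new = X @ w
            c = Y.T @ t_new / (t_new @ t_new)
            u = Y @ c / (c @ c)
            if np.sum((t_new - t) ** 2) < _NIPALS_TOL * max(t_new @ t_new, 1e-300):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(f"PLS NIPALS failed on component {a + 1}")
        if not np.any(t):
            break
        pv = X.T @ t / (t @ t)
        c = Y.T @ t / (t @ t)
        pv, t, w, c = _fix_sign(pv, t, w, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, pv, c
        X -= np.outer(t, pv)
        Y -= np.outer(t, c)
        explained_x.append(float((t @ t) * (pv @ pv) / ss_x) if ss_x else 0.0)

    used = len(explained_x)
    T, W, P, C = T[:, :used], W[:, :used], P[:, :used], C[:, :used]
    if used:
        B = W @ np.linalg.pinv(P.T @ W) @ C.T
    else:
        B = np.zeros((p, m))
    ss_res = float((Y ** 2).sum())  # Y is fully deflated here
    r2y = 1.0 - ss_res / ss_y if ss_y > 0 else 0.0
    return LatentModel(
        kind="pls", T=T, P=P, W=W, C=C, B=B,
        R2X=float(sum(explained_x)),
        R2Y=float(r2y),
        explained_per_component=tuple(explained_x),
        meta={"ssy_per_component": _ssy_per_component(T, C)},
    )


def _ssy_per_component(T: np.ndarray, C: np.ndarray) -> list[float]:
    """Y sum of squares explained by each component: ‖c_a‖²·(t_aᵀt_a)."""
    return [float((C[:, a] @ C[:, a]) * (T[:, a] @ T[:, a]))
            for a in range(T.shape[1])]


def remove_orthogonal(
    X: np.ndarray,
    W_orth: np.ndarray,
    P_orth: np.ndarray,
) -> np.ndarray:
    """Filter y-orthogonal variation out of (new) data, component-wise."""
    X = np.array(X, dtype=float)
    for a in range(W_orth.shape[1]):
        t = X @ W_orth[:, a]
        X -= np.outer(t, P_orth[:, a])
    return X


def encode_two_class(labels: Sequence) -> np.ndarray:
    """Centered 0/1 indicator for exactly two classes (sorted label order)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    y = (labels == classes[1]).astype(float)
    return y - y.mean()


def opls_da_fit(
    X_scaled: np.ndarray,
    class_labels: Sequence,
    n_orth: int = 1,
) -> LatentModel:
    """OPLS-DA: orthogonal components + one predictive component.

    ``class_labels`` must contain exactly two classes; the response is
    the centered class indicator. Each orthogonal score vector is exactly
    orthogonal to the class vector by construction.
    """
    X = np.array(X_scaled, dtype=float)
    y = encode_two_class(class_labels)
    n, p = X.shape
    for lbl, cnt in zip(*np.unique(np.asarray(class_labels), return_counts=True)):
        if cnt < 2:
            import warnings
            warnings.warn(f"class {lbl!r} has fewer than 2 observations; "
                          "cross-validation folds will be degenerate")
    ss_x = float((X ** 2).sum())
    ss_y = float(y @ y)

    T_orth = np.zeros((n, n_orth))
    P_orth = np.zeros((p, n_orth))
    W_orth = np.zeros((p, n_orth))
    r2x_orth = []
    used_orth = 0
    for _ in range(n_orth):
        w = X.T @ y / (y @ y)
        norm_w = np.linalg.norm(w)
        if norm_w == 0:
            break
        w /= norm_w
        t = X @ w
        pv = X.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < 1e-12:
            break  # no y-orthogonal structure left
        w_o /= norm_wo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        p_o, t_o, w_o = _fix_sign(p_o, t_o, w_o)
        T_orth[:, used_orth] = t_o
        P_orth[:, used_orth] = p_o
        W_orth[:, used_orth] = w_o
        X -= np.outer(t_o, p_o)
        r2x_orth.append(float((t_o @ t_o) * (p_o @ p_o) / ss_x) if ss_x else 0.0)
        used_orth += 1
    T_orth = T_orth[:, :used_orth]
    P_orth = P_orth[:, :used_orth]
    W_orth = W_orth[:, :used_orth]

    # final single predictive component on the filtered X
    w = X.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = X @ w
    pv = X.T @ t / (t @ t)
    c = float(y @ t / (t @ t))
    pv, t, w = _fix_sign(pv, t, w)
    c_signed = float(y @ t / (t @ t))
    y_hat = t * c_signed
    r2y = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_y if ss_y > 0 else 0.0
    r2x_pred = float((t @ t) * (pv @ pv) / ss_x) if ss_x else 0.0

    B = np.outer(w, [c_signed])
    return LatentModel(
        kind="opls_da",
        T=t[:, None], P=pv[:, None], W=w[:, None],
        C=np.array([[c_signed]]), B=B,
        T_orth=T_orth, P_orth=P_orth, W_orth=W_orth,
        R2X=float(r2x_pred + sum(r2x_orth)),
        R2Y=float(r2y),
        explained_per_component=(r2x_pred, *r2x_orth),
        meta={
            "y": y,
            "n_orth": used_orth,
            "ssy_per_component": [float((t @ t) * c_signed ** 2)],
        },
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def venetian_folds(n: int, folds: int) -> list[np.ndarray]:
    """Deterministic venetian-blind fold assignment (observation i → i % folds)."""
    assignment = np.arange(n) % folds
    return [np.where(assignment == f)[0] for f in range(folds)]


def q2_cross_validation(
    fit: Callable[[np.ndarray, np.ndarray], LatentModel],
    X_scaled: np.ndarray,
    Y: np.ndarray,
    folds: int = 7,
) -> float:
    """Q2 = 1 − PRESS/SS with venetian-blind folds.

    ``fit`` builds a model from training (X, Y); predictions for held-out
    rows come from ``model.predict``. Y is centered per training fold is
    *not* re-done here: pass Y already centered/scaled consistently with
    the model builder.
    """
    X = np.asarray(X_scaled, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    press = 0.0
    for test_idx in venetian_folds(n, folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit(X[train_idx], Y[train_idx])
        pred = model.predict(X[test_idx])
        press += float(((Y[test_idx] - pred) ** 2).sum())
    ss = float((Y ** 2).sum())
    return 1.0 - press / ss if ss > 0 else 0.0


def opls_da_cv(
    X_scaled: np.ndarray,
    class_labels: Sequence,
    n_orth: int = 1,
    folds: int = 7,
) -> float:
    """Cross-validated Q2 of an OPLS-DA model (labels re-encoded per fold)."""
    labels = np.asarray(class_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    y_raw = (labels == classes[1]).astype(float)

    X = np.asarray(X_scaled, dtype=float)
    n = X.shape[0]
    folds = min(folds, n)
    press = 0.0
    for test_idx in venetian_folds(n, folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(set(labels[train_idx].tolist())) < 2:
            import warnings
            warnings.warn("a training fold lost a class; skipping fold")
            continue
        model = opls_da_fit(X[train_idx], labels[train_idx], n_orth=n_orth)
        pred = model.predict(X[test_idx])[:, 0]  # centered-indicator space
        y_hat = pred + y_raw[train_idx].mean()
        press += float(((y_raw[test_idx] - y_hat) ** 2).sum())
    ss = float(((y_raw - y_raw.mean()) ** 2).sum())
    return 1.0 - press / ss if ss > 0 else 0.0


def auto_orth_components(
    X_scaled: np.ndarray,
    class_labels: Sequence,
    folds: int = 7,
    max_orth: int = 3,
) -> int:
    """Add orthogonal components while cross-validated Q2 increases."""
    best_n, best_q2 = 0, opls_da_cv(X_scaled, class_labels, 0, folds)
    for n_orth in range(1, max_orth + 1):
        q2 = opls_da_cv(X_scaled, class_labels, n_orth, folds)
        if q2 > best_q2 + 1e-12:
            best_n, best_q2 = n_orth, q2
        else:
            break
    return best_n


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection over predictive components.

    ``VIP_j = sqrt( p * Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )`` so that
    the mean squared VIP is exactly 1.
    """
    if model.W is None:
        raise ValueError("VIP requires a PLS-family model")
    W = model.W
    p, a = W.shape
    ssy = np.asarray(model.meta.get("ssy_per_component",
                                    _ssy_per_component(model.T, model.C)))
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W ** 2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    correlations: np.ndarray       # |corr(y_perm, y)| abscissae
    r2y_intercept: float
    q2_intercept: float
    p_value: float


def permutation_test(
    X_scaled: np.ndarray,
    class_labels: Sequence,
    n_permutations: int = 200,
    n_orth: int = 1,
    folds: int = 7,
    rng: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    The observed model's R2Y and Q2 are compared against ``n`` refits
    under uniformly permuted labels; ``p = (1 + #{Q2_perm ≥ Q2_obs}) /
    (n + 1)``. Permuted R2Y/Q2 are regressed on the absolute correlation
    between permuted and original labels (observed model anchored at
    correlation 1) and the intercepts reported.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(class_labels)
    y = encode_two_class(labels)
    obs = opls_da_fit(X_scaled, labels, n_orth=n_orth)
    obs_q2 = opls_da_cv(X_scaled, labels, n_orth=n_orth, folds=folds)

    r2s, q2s, corrs = [], [], []
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        lab_p = labels[perm]
        y_p = y[perm]
        denom = np.linalg.norm(y) * np.linalg.norm(y_p)
        corrs.append(abs(float(y @ y_p) / denom) if denom else 0.0)
        model = opls_da_fit(X_scaled, lab_p, n_orth=n_orth)
        q2 = opls_da_cv(X_scaled, lab_p, n_orth=n_orth, folds=folds)
        r2s.append(model.R2Y)
        q2s.append(q2)
        if q2 >= obs_q2:
            n_ge += 1

    xs = np.array(corrs + [1.0])
    r2_line = np.polyfit(xs, np.array(r2s + [obs.R2Y]), 1)
    q2_line = np.polyfit(xs, np.array(q2s + [obs_q2]), 1)
    return PermutationResult(
        n_permutations=n_permutations,
        observed_r2y=float(obs.R2Y),
        observed_q2=float(obs_q2),
        permuted_r2y=np.array(r2s),
        permuted_q2=np.array(q2s),
        correlations=np.array(corrs),
        r2y_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
        p_value=(1 + n_ge) / (n_permutations + 1),
    )


# ---------------------------------------------------------------------------
# CV-ANOVA
# ---------------------------------------------------------------------------

@dataclass
class CVANOVAResult:
    F: float
    df1: int
    df2: int
    p_value: float


def cv_anova(
    press_model: float,
    press_null: float,
    n_observations: int,
    n_model_components: int,
) -> CVANOVAResult:
    """F-test on cross-validated residuals: mean-only null vs model.

    ``F = (PRESS_null / df1) / (PRESS_model / df2)`` with ``df1 = n − 1``
    and ``df2 = n − 1 − k`` for a k-component model, so a model with no
    components scores F = 1 against itself. A perfect model (zero
    cross-validated residuals) reports F = +inf, p = 0.
    """
    df1 = n_observations - 1
    df2 = max(n_observations - 1 - n_model_components, 1)
    if press_model <= 0:
        return CVANOVAResult(F=float("inf"), df1=df1, df2=df2, p_value=0.0)
    F = (press_null / df1) / (press_model / df2)
    p = float(stats.f.sf(F, df1, df2))
    return CVANOVAResult(F=float(F), df1=df1, df2=df2, p_value=p)


def cv_anova_opls(
    X_scaled: np.ndarray,
    class_labels: Sequence,
    n_orth: int = 1,
    folds: int = 7,
) -> CVANOVAResult:
    """CV-ANOVA for an OPLS-DA model via its venetian-blind PRESS."""
    labels = np.asarray(class_labels)
    y = encode_two_class(labels)
    ss = float(y @ y)
    q2 = opls_da_cv(X_scaled, labels, n_orth=n_orth, folds=folds)
    press_model = (1.0 - q2) * ss
    # mean-only null cross-validated the same way
    n = len(y)
    folds_n = min(folds, n)
    press_null = 0.0
    for test_idx in venetian_folds(n, folds_n):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        mu = y[train_idx].mean()
        press_null += float(((y[test_idx] - mu) ** 2).sum())
    return cv_anova(press_model, press_null, n, 1 + n_orth)


# ---------------------------------------------------------------------------
# PLSR vs sensory attributes
# ---------------------------------------------------------------------------

@dataclass
class CorrelationLoadings:
    x_names: tuple[str, ...]
    y_names: tuple[str, ...]
    x_correlations: np.ndarray  # len(x_names) × 2
    y_correlations: np.ndarray  # len(y_names) × 2
    inner_radius: float = float(np.sqrt(0.5))
    outer_radius: float = 1.0


def correlation_loadings(
    model: LatentModel,
    X_scaled: np.ndarray,
    Y_scaled: np.ndarray,
    x_names: Sequence[str],
    y_names: Sequence[str],
) -> CorrelationLoadings:
    """Pearson correlations of every variable with the first two factors."""
    if model.n_components < 2:
        raise ValueError("correlation loadings need at least 2 factors")
    T = model.T[:, :2]

    def corr_block(M):
        out = np.zeros((M.shape[1], 2))
        for j in range(M.shape[1]):
            for a in range(2):
                sd = M[:, j].std() * T[:, a].std()
                out[j, a] = (np.mean((M[:, j] - M[:, j].mean())
                                     * (T[:, a] - T[:, a].mean())) / sd
                             if sd > 0 else 0.0)
        return out

    X = np.asarray(X_scaled, dtype=float)
    Y = np.atleast_2d(np.asarray(Y_scaled, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    return CorrelationLoadings(
        x_names=tuple(x_names),
        y_names=tuple(y_names),
        x_correlations=corr_block(X),
        y_correlations=corr_block(Y),
    )


def plsr_sensory(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: Sequence[str],
    y_names: Sequence[str],
    scaling: str = "unit_variance",
) -> tuple[LatentModel, CorrelationLoadings]:
    """Two-factor PLS2 of compound concentrations against sensory means.

    Rows of X and Y must be aligned observations (sample × replicate).
    Returns the fitted model (with per-block explained variance in
    ``meta``) and the correlation-loading coordinates.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PLSR needs at least 3 observations")
    sx = autoscale(X, scaling)
    sy = autoscale(Y, scaling)
    model = pls_fit(sx.values, sy.values, n_components=2)
    model.kind = "plsr"
    # explained Y variance per block for reporting
    y_hat = sx.values @ model.B
    ss_y = float((sy.values ** 2).sum())
    model.meta["r2x_cum"] = model.R2X
    model.meta["r2y_cum"] = 1.0 - float(((sy.values - y_hat) ** 2).sum()) / ss_y
    model.meta["x_scaler"] = sx
    model.meta["y_scaler"] = sy
    loadings = correlation_loadings(model, sx.values, sy.values, x_names, y_names)
    return model, loadings


# ---------------------------------------------------------------------------
# jack-knife coefficient significance
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    coefficients: np.ndarray   # p × m
    uncertainties: np.ndarray  # p × m
    t_ratios: np.ndarray       # p × m
    significant: np.ndarray    # boolean p × m
    alpha: float


def jackknife_significance(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 2,
    alpha: float = 0.05,
    scaling: str = "unit_variance",
) -> JackknifeResult:
    """Martens' jack-knife uncertainty of PLS regression coefficients.

    Leave-one-observation-out refits give perturbed coefficients
    ``b_(−i)``; the standard uncertainty is
    ``s_b = sqrt( Σ_i g (b_(−i) − b)² )`` with ``g = (n−1)/n``, and a
    coefficient is significant when ``|b| > t_{1−α/2, n−1} · s_b``.
    Scaling is refit inside every fold (each sub-model sees its own
    autoscaled data) and coefficients are compared in the original
    units, so a deterministic exact relation has ~zero uncertainty.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if n < 3:
        raise ValueError("jack-knife needs at least 3 observations")

    def fit_b(Xf, Yf):
        sx = autoscale(Xf, scaling)
        sy = autoscale(Yf, scaling)
        a = min(n_components, Xf.shape[0] - 1, Xf.shape[1])
        B = pls_fit(sx.values, sy.values, a).B
        # back to original units: y = x @ B_raw + const
        return B * sy.column_scales[None, :] / sx.column_scales[:, None]

    b_full = fit_b(X, Y)
    g = (n - 1) / n
    acc = np.zeros_like(b_full)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            b_i = fit_b(X[keep], Y[keep])
        except Exception as exc:  # noqa: BLE001 - report the failing fold
            raise ConvergenceError(f"jack-knife refit failed leaving out "
                                   f"observation {i}") from exc
        acc += g * (b_i - b_full) ** 2
    s = np.sqrt(acc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ratio = np.where(s > 0, np.abs(b_full) / s,
                           np.where(b_full == 0, 0.0, np.inf))
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return JackknifeResult(
        coefficients=b_full,
        uncertainties=s,
        t_ratios=t_ratio,
        significant=t_ratio > t_crit,
        alpha=alpha,
    )
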
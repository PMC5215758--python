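"""Shape/texture statistics: PCA, covariate regression, scores, prediction.

Two complementary regression directions are used.  The *multivariate*
regression of a high-dimensional data block (shape coordinates or registered
RGB values) on a single covariate needs no variable reduction: its
coefficient vector b (one simple regression per column) is the pattern of
change per covariate unit and is used both to visualize the covariate effect
(mean + multiple of b) and to score individuals by projecting their centered
data onto b — scores equivalent, for a single covariate, to the first
dimension of a partial least squares analysis.  The *multiple* regression of
the covariate on the data requires reduction (principal components) or
regularization (ridge), since p far exceeds n.  All prediction accuracies are
corrected by leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCAModel:
    """Centered SVD-based PCA, valid for p >> n."""

    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (p, m), orthonormal columns
    eigenvalues: np.ndarray  # (m,), nonincreasing
    variance_fractions: np.ndarray  # (m,), sums to 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings


@dataclass
class CovariateEffectModel:
    """Coefficient vector of the multivariate regression of a block on one covariate."""

    covariate_name: str
    x_mean: float
    b: np.ndarray  # (p,), change in the block per covariate unit
    data_mean: np.ndarray  # (p,)
    r_within: float = float("nan")
    p_perm: float | None = None


@dataclass
class PredictionReport:
    """Within-sample and leave-one-out cross-validated prediction of a covariate."""

    method: str
    r_within: float
    r_cv: float
    predictions_cv: np.ndarray  # (n,), each made with that specimen held out
    extra: dict = field(default_factory=dict)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float((ac * bc).sum() / denom)


def fit_pca(X: np.ndarray) -> PCAModel:
    """PCA of an (n, p) data matrix via the SVD of the centered data.

    Keeps all min(n-1, p) components; variance fractions sum to 1 over them.
    Sign convention: the largest-absolute entry of each loading column is
    positive, so ordinations are reproducible across runs and platforms.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("X must be (n>=3, p)")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("constant data matrix: PCA undefined")
    n, p = X.shape
    m = min(n - 1, p)
    if p > n:
        # Gram trick: eigendecompose the n x n matrix instead of p x p
        G = Xc @ Xc.T
        lam, U = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1][:m]
        lam = np.maximum(lam[order], 0.0)
        U = U[:, order]
        keep = lam > max(lam[0], 1.0) * 1e-12
        lam, U = lam[keep], U[:, keep]
        loadings = Xc.T @ (U / np.sqrt(lam))
        sv2 = lam
    else:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:m].T
        sv2 = s[:m] ** 2
    # fixed sign convention
    flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flips[flips == 0] = 1.0
    loadings = loadings * flips
    eigenvalues = sv2 / (n - 1)
    total = Xc.var(axis=0, ddof=1).sum()
    fractions = eigenvalues / total
    return PCAModel(mean=mean, loadings=loadings, eigenvalues=eigenvalues,
                    variance_fractions=fractions)


def regress_on_covariate(X: np.ndarray, x: np.ndarray,
                         covariate_name: str = "covariate") -> CovariateEffectModel:
    """Multivariate regression of every column of X on the covariate x.

    b_j = cov(X_j, x) / var(x); the model predicts row mean + (x - x_mean) b.
    ``r_within`` is the correlation of the effect scores with x.
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if X.shape[0] != x.shape[0] or X.shape[0] < 3:
        raise ValueError("X rows and x must match, n >= 3")
    xc = x - x.mean()
    ss = (xc**2).sum()
    if ss == 0.0:
        raise ValueError("constant covariate")
    data_mean = X.mean(axis=0)
    b = (X - data_mean).T @ xc / ss
    model = CovariateEffectModel(covariate_name=covariate_name, x_mean=float(x.mean()),
                                 b=b, data_mean=data_mean)
    model.r_within = _corr(effect_scores(X, model), x)
    return model


def effect_scores(X: np.ndarray, model: CovariateEffectModel) -> np.ndarray:
    """Projections of centered rows onto the unit coefficient vector.

    For a single covariate these equal (up to sign and scale) the first-
    dimension scores of a partial least squares analysis of (X, x).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norm = np.linalg.norm(model.b)
    if norm == 0.0:
        raise ValueError("zero coefficient vector")
    return (X - model.data_mean) @ (model.b / norm)


def reconstruct_at(model: CovariateEffectModel, x_value: float) -> np.ndarray:
    """Predicted data vector at a covariate value: mean + (x - x_mean) b.

    Affine in x_value; at the covariate mean it returns the data mean exactly.
    Texture reconstructions are clipped to [0, 1] at render time only.
    """
    return model.data_mean + (float(x_value) - model.x_mean) * model.b


def loocv_scores(X: np.ndarray, x: np.ndarray, covariate_name: str = "covariate"
                 ) -> PredictionReport:
    """Leave-one-out cross-validated prediction of x from effect scores.

    For each specimen the multivariate regression is refitted without it; the
    held-out specimen is scored on the refitted axis, and its covariate is
    predicted by the simple regression of x on scores fitted within the
    training fold.  ``r_cv`` is the correlation of held-out predictions with x.
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 for leave-one-out")
    full = regress_on_covariate(X, x, covariate_name)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        m = regress_on_covariate(X[keep], x[keep], covariate_name)
        s_train = effect_scores(X[keep], m)
        s_i = float(effect_scores(X[i], m)[0])
        beta, alpha = np.polyfit(s_train, x[keep], 1)
        preds[i] = alpha + beta * s_i
    return PredictionReport(method="scores", r_within=full.r_within,
                            r_cv=_corr(preds, x), predictions_cv=preds)


def _lstsq_fit_predict(S_train: np.ndarray, x_train: np.ndarray,
                       S_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multiple regression with intercept; returns (train fit, test predictions)."""
    A = np.column_stack([np.ones(S_train.shape[0]), S_train])
    coef = np.linalg.lstsq(A, x_train, rcond=None)[0]
    fit = A @ coef
    At = np.column_stack([np.ones(np.atleast_2d(S_test).shape[0]), np.atleast_2d(S_test)])
    return fit, At @ coef


def pcr_predict(X: np.ndarray, x: np.ndarray, n_pcs: int,
                strict_cv: bool = True) -> PredictionReport:
    """Principal component regression of the covariate on the first n_pcs PCs.

    With ``strict_cv`` (default) the PCA itself is refitted inside every
    leave-one-out fold, so component choice cannot leak the held-out specimen.
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= n_pcs <= min(n - 2, p):
        raise ValueError(f"n_pcs must be in [1, {min(n - 2, p)}]")
    pca = fit_pca(X)
    S = pca.transform(X)[:, :n_pcs]
    fit_full, _ = _lstsq_fit_predict(S, x, S[:1])
    r_within = _corr(fit_full, x)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if strict_cv:
            pca_i = fit_pca(X[keep])
            S_tr = pca_i.transform(X[keep])[:, :n_pcs]
            S_te = pca_i.transform(X[i])[:, :n_pcs]
        else:
            S_tr, S_te = S[keep], S[i:i + 1]
        _, pred = _lstsq_fit_predict(S_tr, x[keep], S_te)
        preds[i] = pred[0]
    return PredictionReport(method=f"pcr({n_pcs})", r_within=r_within,
                            r_cv=_corr(preds, x), predictions_cv=preds,
                            extra={"n_pcs": n_pcs, "strict_cv": strict_cv})


def _ridge_coefs(Xc: np.ndarray, xc: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge coefficients on centered data, dual (kernel) form when p > n."""
    n, p = Xc.shape
    if p > n:
        G = Xc @ Xc.T
        dual = np.linalg.solve(G + alpha * np.eye(n), xc)
        return Xc.T @ dual
    return np.linalg.solve(Xc.T @ Xc + alpha * np.eye(p), Xc.T @ xc)


def ridge_predict(X: np.ndarray, x: np.ndarray, alpha: float) -> PredictionReport:
    """Ridge regression of the covariate on all variables, LOO cross-validated.

    alpha is on the scale of the centered Gram matrix; the intercept is not
    penalized (data are centered internally).  As alpha grows the coefficient
    vector turns toward the cross-covariance X_c' x_c, i.e. the strongly
    regularized multiple regression becomes the multivariate regression
    direction used for the effect scores.
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n, p = X.shape
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha == 0 and p >= n:
        raise ValueError("alpha = 0 with p >= n is underdetermined")
    Xm = X.mean(axis=0)
    xm = x.mean()
    beta = _ridge_coefs(X - Xm, x - xm, alpha)
    fit = (X - Xm) @ beta + xm
    r_within = _corr(fit, x)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xk, xk = X[keep], x[keep]
        Xkm, xkm = Xk.mean(axis=0), xk.mean()
        bk = _ridge_coefs(Xk - Xkm, xk - xkm, alpha)
        preds[i] = (X[i] - Xkm) @ bk + xkm
    return PredictionReport(method=f"ridge({alpha:g})", r_within=r_within,
                            r_cv=_corr(preds, x), predictions_cv=preds,
                            extra={"alpha": alpha, "coef": beta})


def combine_scores(blocks: list[np.ndarray], x: np.ndarray,
                   collinearity_tol: float = 1e-10) -> PredictionReport:
    """Predict the covariate from the effect scores of several data blocks.

    Each block's multivariate regression (and hence its score axis) is
    refitted inside every leave-one-out fold before the multiple regression of
    x on the score columns.  Score columns that are numerically collinear with
    earlier ones are dropped with a warning.
    """
    if len(blocks) < 1:
        raise ValueError("need at least one block")
    X_blocks = [np.asarray(B, dtype=float) for B in blocks]
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]

    def _score_cols(Bs: list[np.ndarray], xs: np.ndarray, B_tests: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
        cols_tr, cols_te = [], []
        for B, Bt in zip(Bs, B_tests):
            m = regress_on_covariate(B, xs)
            cols_tr.append(effect_scores(B, m))
            cols_te.append(effect_scores(Bt, m))
        S_tr = np.column_stack(cols_tr)
        S_te = np.column_stack(cols_te)
        # drop columns collinear with earlier ones
        keep: list[int] = []
        for j in range(S_tr.shape[1]):
            sub = S_tr[:, keep + [j]]
            if keep and np.linalg.svd(sub - sub.mean(axis=0), compute_uv=False)[-1] < collinearity_tol:
                warnings.warn(f"dropping collinear score block {j}", stacklevel=2)
                continue
            keep.append(j)
        return S_tr[:, keep], S_te[:, keep]

    S_full, _ = _score_cols(X_blocks, x, [B[:1] for B in X_blocks])
    fit_full, _ = _lstsq_fit_predict(S_full, x, S_full[:1])
    r_within = _corr(fit_full, x)
    preds = np.empty(n)
    for i in range(n):
        keep_rows = np.arange(n) != i
        S_tr, S_te = _score_cols([B[keep_rows] for B in X_blocks], x[keep_rows],
                                 [B[i:i + 1] for B in X_blocks])
        _, pred = _lstsq_fit_predict(S_tr, x[keep_rows], S_te)
        preds[i] = pred[0]
    return PredictionReport(method="combined", r_within=r_within,
                            r_cv=_corr(preds, x), predictions_cv=preds,
                            extra={"n_blocks": len(blocks)})


def permutation_test(X: np.ndarray, x: np.ndarray, n_perm: int = 999,
                     seed: int | None = None) -> float:
    """Permutation p-value for the multivariate regression of X on x.

    Statistic: the within-sample correlation of the effect scores with the
    covariate.  p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T  # scores against a permuted covariate are G @ xperm_c

    def stat(xs: np.ndarray) -> float:
        s = G @ (xs - xs.mean())
        return _corr(s, xs)

    observed = stat(x)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(x)) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def hue_center(texture_vector: np.ndarray) -> np.ndarray:
    """Remove per-pixel brightness: center each pixel's three channel values.

    Operates on a pixel-major (R,G,B within pixel) texture vector or
    coefficient vector; after centering, each pixel's channel values sum to
    zero, so only hue differences remain.  Idempotent.
    """
    v = np.asarray(texture_vector, dtype=float)
    if v.size % 3 != 0:
        raise ValueError("texture vector length must be divisible by 3")
    px = v.reshape(-1, 3)
    out = px - px.mean(axis=1, keepdims=True)
    return out.reshape(v.shape)
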
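"""Latent-variable models: NIPALS PCA, two-class PLS-DA, OPLS-DA, VIP,
cross-validated Q2, permutation testing and a CV-ANOVA approximation.

All fitting routines expect a column-centered (and usually unit-variance
scaled) matrix ``X``.  PLS-DA is the single-response (PLS1) algorithm on a
centered 0/1 group indicator, the strictly two-group setting of this
workflow.  OPLS-DA splits the variation into one predictive component and a
chosen number of components orthogonal to the response.

VIP follows the standard definition

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

with ``SS_a`` the response variance explained by component ``a``; the mean
of the squared VIPs is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data import OmniblockError, ValidationError

__all__ = [
    "LatentModel",
    "ValidationResult",
    "fit_pca",
    "fit_plsda",
    "fit_oplsda",
    "compute_vip",
    "cross_validate",
    "permutation_test",
    "cv_anova",
    "choose_components",
    "encode_binary",
]

_EPS = np.finfo(float).eps


class ConvergenceError(OmniblockError):
    pass


@dataclass
class LatentModel:
    kind: str                       # "pca", "plsda" or "oplsda"
    A: int                          # number of predictive components
    weights: np.ndarray             # p x A X-weights (unit norm columns); = loadings for PCA
    loadings: np.ndarray            # p x A X-loadings
    scores: np.ndarray              # n x A score vectors
    y_loadings: np.ndarray | None = None   # length-A response loadings (PLS/OPLS)
    ss_y: np.ndarray | None = None         # per-component explained response SS
    r2x: float = float("nan")
    r2y: float | None = None
    q2: float | None = None
    ortho_weights: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    y_mean: float = 0.0
    classes: tuple = ()

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b with y_hat = X b (predictive part only)."""
        if self.kind == "pca":
            raise ValidationError("PCA model has no regression coefficients")
        W, P, c = self.weights, self.loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, c)


@dataclass
class ValidationResult:
    q2: float
    q2_folds: list[float]
    press: float
    ss_tot: float
    n: int
    A: int
    perm_r2y: np.ndarray | None = None
    perm_q2: np.ndarray | None = None
    perm_p: float | None = None
    f_stat: float | None = None
    df1: int | None = None
    df2: int | None = None
    f_p: float | None = None


def encode_binary(y) -> tuple[np.ndarray, tuple]:
    """Encode two-class labels as a centered 0/1 response."""
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) != 2:
        raise ValidationError(f"exactly 2 classes required, got {len(classes)}")
    ind = (y == classes[1]).astype(float)
    return ind - ind.mean(), classes


def _sign_fix(p: np.ndarray, *vectors: np.ndarray) -> None:
    """Deterministic sign convention: largest-|loading| entry positive."""
    i = int(np.argmax(np.abs(p)))
    if p[i] < 0:
        p *= -1
        for v in vectors:
            v *= -1


def fit_pca(X: np.ndarray, A: int, max_iter: int = 1000, tol: float = 1e-12) -> LatentModel:
    """NIPALS PCA of a centered matrix; missing values are skipped.

    Components are extracted by iterative regression with missing-value
    masking and are returned ordered by decreasing explained variance, with
    the largest-|loading| entry of each component positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if A > min(n, p) - 1:
        raise ValidationError(f"A={A} exceeds min(dim) - 1 = {min(n, p) - 1}")
    mask = np.isfinite(X)
    Xf = np.where(mask, X, 0.0)
    total_ss = float(np.sum(Xf**2))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    ss = np.zeros(A)
    for a in range(A):
        col_var = np.sum(Xf**2, axis=0)
        t = Xf[:, int(np.argmax(col_var))].copy()
        if np.linalg.norm(t) < _EPS:
            raise ConvergenceError(f"component {a}: residual matrix is zero")
        for _ in range(max_iter):
            denom_p = mask.T.astype(float) @ (t**2)
            pvec = (Xf.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            nrm = np.linalg.norm(pvec)
            if nrm < _EPS:
                raise ConvergenceError(f"component {a}: degenerate loading")
            pvec /= nrm
            denom_t = mask.astype(float) @ (pvec**2)
            t_new = (Xf @ pvec) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), _EPS):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(f"PCA NIPALS did not converge on component {a}")
        _sign_fix(pvec, t)
        T[:, a] = t
        P[:, a] = pvec
        ss[a] = float(t @ t)
        Xf = np.where(mask, Xf - np.outer(t, pvec), 0.0)
    order = np.argsort(-ss)
    T, P, ss = T[:, order], P[:, order], ss[order]
    r2x = float(ss.sum() / total_ss) if total_ss > 0 else 0.0
    return LatentModel(kind="pca", A=A, weights=P, loadings=P, scores=T, r2x=r2x,
                       ss_y=ss)


def fit_plsda(X: np.ndarray, y, A: int) -> LatentModel:
    """Two-class PLS-DA (NIPALS PLS1) on a centered/scaled matrix.

    ``y`` holds the two group labels; it is encoded as a centered indicator.
    ``R2Y = 1 - SS_res / SS_tot`` of the fitted response.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("PLS-DA requires a complete matrix; impute or drop missing")
    yc, classes = encode_binary(y)
    n, p = X.shape
    if A < 1 or A > min(n - 1, p):
        raise ValidationError(f"invalid number of components A={A}")
    Xd = X.copy()
    yd = yc.copy()
    ss_tot_x = float(np.sum(X**2))
    ss_tot = float(yd @ yd)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    C = np.zeros(A)
    ss_y = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _EPS * max(1.0, np.linalg.norm(yd)):
            raise ConvergenceError(f"component {a}: X carries no covariance with y")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ConvergenceError(f"component {a}: degenerate score")
        c = float(t @ yd) / tt
        pvec = (Xd.T @ t) / tt
        _sign_fix(pvec, w, t)
        c = float(t @ yd) / tt  # recompute: sign convention may have flipped t
        Xd -= np.outer(t, pvec)
        yd = yd - c * t
        W[:, a], P[:, a], T[:, a], C[a] = w, pvec, t, c
        ss_y[a] = c * c * tt
    r2y = 1.0 - float(yd @ yd) / ss_tot
    r2x = 1.0 - float(np.sum(Xd**2)) / ss_tot_x if ss_tot_x > 0 else 0.0
    return LatentModel(
        kind="plsda", A=A, weights=W, loadings=P, scores=T, y_loadings=C,
        ss_y=ss_y, r2x=r2x, r2y=r2y, classes=classes,
    )


def fit_oplsda(X: np.ndarray, y, n_orthogonal: int = 1) -> LatentModel:
    """OPLS-DA: ``n_orthogonal`` response-orthogonal components, then one
    predictive component fitted on the deflated matrix.

    With ``n_orthogonal = 0`` the model coincides exactly with single
    component PLS-DA.  The predictive score is orthogonal to every
    orthogonal score by construction.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("OPLS-DA requires a complete matrix")
    yc, classes = encode_binary(y)
    n, p = X.shape
    rank_bound = min(n - 1, p)
    if n_orthogonal < 0 or n_orthogonal >= rank_bound:
        raise ValidationError(
            f"n_orthogonal={n_orthogonal} must lie in [0, rank(X)) = [0, {rank_bound})"
        )
    Xd = X.copy()
    ss_tot_x = float(np.sum(X**2))
    Wo = np.zeros((p, n_orthogonal))
    Po = np.zeros((p, n_orthogonal))
    To = np.zeros((n, n_orthogonal))
    for a in range(n_orthogonal):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ConvergenceError(f"orthogonal component {a}: no covariance left")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        pvec = (Xd.T @ t) / tt
        w_o = pvec - float(w @ pvec) * w
        nw_o = np.linalg.norm(w_o)
        if nw_o < _EPS:
            raise ConvergenceError(
                f"orthogonal component {a}: no systematic orthogonal variation"
            )
        w_o /= nw_o
        t_o = Xd @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < _EPS:
            raise ConvergenceError(f"orthogonal component {a}: degenerate score")
        p_o = (Xd.T @ t_o) / tt_o
        _sign_fix(p_o, w_o, t_o)
        Xd -= np.outer(t_o, p_o)
        Wo[:, a], Po[:, a], To[:, a] = w_o, p_o, t_o
    pred = fit_plsda(Xd, y, A=1)
    return LatentModel(
        kind="oplsda", A=1, weights=pred.weights, loadings=pred.loadings,
        scores=pred.scores, y_loadings=pred.y_loadings, ss_y=pred.ss_y,
        r2x=float(pred.scores[:, 0] @ pred.scores[:, 0]) / ss_tot_x if ss_tot_x > 0 else 0.0,
        r2y=pred.r2y, ortho_weights=Wo, ortho_loadings=Po, ortho_scores=To,
        classes=classes,
    )


def compute_vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection over the predictive components."""
    if model.kind == "pca":
        raise ValidationError("VIP is defined for PLS-DA/OPLS-DA models only")
    W = model.weights
    ss = model.ss_y
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    num = (wn**2) @ ss
    return np.sqrt(p * num / ss.sum())


def _center_scale(X: np.ndarray, mode: str):
    mean = X.mean(axis=0)
    if mode == "none":
        scale = np.ones(X.shape[1])
    else:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        scale = sd if mode == "unit_variance" else np.sqrt(sd)
    return mean, scale


def cross_validate(
    X: np.ndarray,
    y,
    A: int,
    n_folds: int = 7,
    seed: int = 0,
    scale: str = "none",
    max_refolds: int = 10,
) -> ValidationResult:
    """Stratified ``n_folds``-fold cross-validated Q2 of a PLS-DA model.

    Each training fold is centered/scaled independently (``scale`` as in
    :func:`omniblock.preprocess.scale_for_model`; default none, for matrices
    already scaled upstream).  ``Q2 = 1 - PRESS / SS_tot`` with PRESS
    accumulated from held-out predictions.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValidationError("two classes required")
    y_ind = (y == classes[1]).astype(float)
    ss_tot = float(np.sum((y_ind - y_ind.mean()) ** 2))
    last_err: Exception | None = None
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        press = 0.0
        q2_folds = []
        try:
            for train, test in skf.split(X, y):
                if len(set(y[train].tolist())) < 2:
                    raise ValidationError("fold lost a class")
                mean, sc = _center_scale(X[train], scale)
                Xtr = (X[train] - mean) / sc
                model = fit_plsda(Xtr, y[train], A=min(A, min(len(train) - 1, X.shape[1])))
                b = model.coefficients
                ytr = y_ind[train]
                yhat = ((X[test] - mean) / sc) @ b + ytr.mean()
                resid = y_ind[test] - yhat
                fold_press = float(resid @ resid)
                press += fold_press
                fold_ss = float(np.sum((y_ind[test] - y_ind.mean()) ** 2))
                q2_folds.append(1.0 - fold_press / fold_ss if fold_ss > 0 else np.nan)
            q2 = 1.0 - press / ss_tot
            return ValidationResult(q2=q2, q2_folds=q2_folds, press=press,
                                    ss_tot=ss_tot, n=len(y), A=A)
        except (ValidationError, ConvergenceError) as err:  # refold and retry
            last_err = err
            continue
    raise OmniblockError(f"cross-validation failed after {max_refolds} refolds: {last_err}")


def permutation_test(
    X: np.ndarray,
    y,
    A: int,
    n_permutations: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    scale: str = "none",
) -> ValidationResult:
    """Label-permutation null for Q2 (and R2Y) of a PLS-DA model.

    ``p = (1 + #{Q2_perm >= Q2_obs}) / (n_permutations + 1)`` -- the add-one
    estimator, so the smallest attainable p is ``1/(n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    obs = cross_validate(X, y, A, n_folds=n_folds, seed=seed, scale=scale)
    rng = np.random.default_rng(seed)
    mean, sc = _center_scale(X, scale)
    Xs = (X - mean) / sc
    perm_q2 = np.empty(n_permutations)
    perm_r2y = np.empty(n_permutations)
    for k in range(n_permutations):
        yp = rng.permutation(y)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = cross_validate(X, yp, A, n_folds=n_folds, seed=sub_seed, scale=scale)
        perm_q2[k] = res.q2
        try:
            perm_r2y[k] = fit_plsda(Xs, yp, A=A).r2y
        except ConvergenceError:
            perm_r2y[k] = np.nan
    p = (1 + int(np.sum(perm_q2 >= obs.q2))) / (n_permutations + 1)
    obs.perm_q2 = perm_q2
    obs.perm_r2y = perm_r2y
    obs.perm_p = p
    return obs


def cv_anova(result: ValidationResult) -> tuple[float, int, int, float]:
    """PRESS-based F approximation to CV-ANOVA.

    ``F = ((SS_tot - PRESS) / A) / (PRESS / (n - A - 1))``; p from the F
    distribution with ``(A, n - A - 1)`` degrees of freedom.  Documented as
    an approximation to the cross-validated ANOVA of the commercial tool.
    """
    df1 = result.A
    df2 = result.n - result.A - 1
    if df2 <= 0:
        raise ValidationError("n - A - 1 must be positive for CV-ANOVA")
    explained = max(result.ss_tot - result.press, 0.0)
    if result.press <= 0:
        f = np.inf
        p = 0.0
    else:
        f = (explained / df1) / (result.press / df2)
        p = float(stats.f.sf(f, df1, df2))
    result.f_stat, result.df1, result.df2, result.f_p = float(f), df1, df2, p
    return float(f), df1, df2, p


def choose_components(
    X: np.ndarray, y, max_A: int = 5, n_folds: int = 7, seed: int = 0, scale: str = "none"
) -> int:
    """Largest A <= max_A for which every incremental Q2 gain is positive."""
    best = 1
    prev_q2 = -np.inf
    bound = min(max_A, min(np.asarray(X).shape[0] - 2, np.asarray(X).shape[1]))
    for A in range(1, bound + 1):
        q2 = cross_validate(X, y, A, n_folds=n_folds, seed=seed, scale=scale).q2
        if q2 > prev_q2:
            best = A
            prev_q2 = q2
        else:
            break
    return best
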
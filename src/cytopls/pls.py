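"""Orthogonalized PLS-DA / PLS regression for cytokine signature modeling.

Partial least squares (PLS) builds latent variables (LVs) — linear
combinations of the predictors — that maximize covariance between the
predictor matrix X (cytokine concentrations) and a response y (a coded group
label for discriminant analysis, or a continuous covariate such as culture
age for regression).  This module implements, from first principles:

- autoscaling (mean-center, unit variance, n-1 denominator),
- NIPALS extraction of PLS1 components with deflation,
- leave-one-out cross-validation with scaling refit inside each fold,
- LV-count selection by minimum LOO error (ties toward fewer LVs),
- a post-hoc prediction-preserving orthogonalization that rotates the score
  space so LV1 carries the maximal response covariation,
- a permutation test comparing the model's LOO performance with the mean and
  SD of a label-shuffled null,
- VIP (variable importance in projection) scores with the VIP > 1 key-set.

Discriminant analysis codes the two classes as -1/+1 (centered), with the
class boundary at the code midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "PLSError",
    "Scaling",
    "PLSModel",
    "CVResult",
    "PermutationResult",
    "VIPTable",
    "PLSDAResult",
    "PLSRResult",
    "autoscale",
    "nipals_pls",
    "orthogonalize",
    "predict",
    "predict_labels",
    "encode_labels",
    "loo_cv",
    "select_num_lvs",
    "permutation_test",
    "vip",
    "fit_plsda",
    "fit_plsr",
]


class PLSError(ValueError):
    """Raised on invalid designs or non-convergent fits."""


@dataclass(frozen=True)
class Scaling:
    """Column means and standard deviations of the training predictors."""

    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.means.shape[0]:
            raise PLSError(
                f"expected {self.means.shape[0]} predictor columns, got {X.shape[-1]}"
            )
        return (X - self.means) / self.sds


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 model.

    ``W`` holds the unit-norm NIPALS weight vectors (kept un-rotated even in
    an orthogonalized model, since VIP is defined on them), ``P``/``T``/``q``
    the predictor loadings, scores and response loadings (rotated when
    ``orthogonalized``), ``b`` the regression coefficients on the autoscaled
    predictors, and ``y_mean`` the training response mean (predictions are
    ``scale(X) @ b + y_mean``).
    """

    A: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    b: np.ndarray
    y_mean: float = 0.0
    orthogonalized: bool = False


@dataclass(frozen=True)
class CVResult:
    """LOO errors per candidate LV count and the selected count."""

    errors_by_A: np.ndarray
    A_star: int


@dataclass(frozen=True)
class PermutationResult:
    """Observed performance vs the label-permutation null.

    ``p_value`` is the one-tailed normal-approximation p built from the null
    mean and SD (upper tail for accuracy, lower tail for MSE);
    ``p_empirical`` is the rank-based p ``(1 + #{null at least as good}) /
    (n_perm + 1)`` reported alongside for robustness.
    """

    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    p_value: float
    p_empirical: float


@dataclass(frozen=True)
class VIPTable:
    """Per-predictor VIP scores and the VIP > 1 key set."""

    vip: np.ndarray
    predictor_names: list[str]

    @property
    def key_predictors(self) -> list[str]:
        return [n for n, v in zip(self.predictor_names, self.vip) if v > 1.0]


@dataclass(frozen=True)
class PLSDAResult:
    """Full PLS-DA bundle: model, CV, permutation significance, VIP."""

    model: PLSModel
    scaling: Scaling
    cv: CVResult
    accuracy: float
    permutation: PermutationResult
    vip_table: VIPTable
    classes: tuple
    predictor_names: list[str]
    dropped_predictors: list[str] = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        return self.model.T

    @property
    def lv1_loadings(self) -> np.ndarray:
        return self.model.P[:, 0]


@dataclass(frozen=True)
class PLSRResult:
    """Full PLS-regression bundle with MSE-based CV and lower-tail null."""

    model: PLSModel
    scaling: Scaling
    cv: CVResult
    mse: float
    q2: float
    permutation: PermutationResult
    vip_table: VIPTable
    predictor_names: list[str]
    dropped_predictors: list[str] = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        return self.model.T

    @property
    def lv1_loadings(self) -> np.ndarray:
        return self.model.P[:, 0]


def autoscale(
    X: np.ndarray, predictor_names: list[str] | None = None
) -> tuple[np.ndarray, Scaling]:
    """Mean-center and unit-variance scale each column (sd with n-1 denominator)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        names = (
            [predictor_names[j] for j in bad]
            if predictor_names is not None
            else bad.tolist()
        )
        raise PLSError(f"zero-variance predictor(s): {names}")
    return (X - means) / sds, Scaling(means, sds)


def _nipals_core(Z, y, A, tol, max_iter):
    """Sequential NIPALS extraction with deflation; returns W, T, P, q.

    For a univariate response the inner power iteration converges after a
    single pass; the loop and tolerance are retained as the convergence
    contract.
    """
    n, p = Z.shape
    Za = Z.copy()
    ya = y.astype(float).copy()
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    q = np.empty(A)
    for a in range(A):
        w = Za.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-13:
            raise PLSError(f"NIPALS component {a + 1}: no residual covariance with y")
        w /= nw
        for _ in range(max_iter):
            t = Za @ w
            tt = t @ t
            qa = (ya @ t) / tt
            w_new = Za.T @ (ya * qa)
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - np.sign(w_new @ w) * w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise PLSError(f"NIPALS did not converge for component {a + 1}")
        t = Za @ w
        tt = t @ t
        pa = Za.T @ t / tt
        qa = (ya @ t) / tt
        Za -= np.outer(t, pa)
        ya -= qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
    return W, T, P, q


def _coefficients(W, P, q):
    # b = W (P'W)^-1 q maps autoscaled X directly to centered predictions
    return W @ np.linalg.solve(P.T @ W, q)


def nipals_pls(
    Z: np.ndarray,
    y: np.ndarray,
    A: int,
    *,
    tol: float = 1e-12,
    max_iter: int = 100,
    y_mean: float = 0.0,
) -> PLSModel:
    """Fit an A-component PLS1 model on autoscaled Z and centered y."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if not 1 <= A <= min(n - 1, p):
        raise PLSError(f"A={A} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    W, T, P, q = _nipals_core(Z, y, A, tol, max_iter)
    b = _coefficients(W, P, q)
    return PLSModel(A=A, W=W, P=P, T=T, q=q, b=b, y_mean=y_mean)


def orthogonalize(model: PLSModel, y: np.ndarray | None = None) -> PLSModel:
    """Rotate the fitted score space so LV1 carries the response covariation.

    The orthonormalized scores U = T diag(||t_a||)^-1 are rotated so the
    first column is proportional to the centered fitted values y-hat, which
    (a) maximizes |cov(LV1, y)| over all rotations of the score space, since
    y-hat is the projection of y onto it, and (b) makes LV2..A exactly
    uncorrelated with y-hat.  Loadings and response loadings are counter-
    rotated, so training predictions are unchanged.  A 1-component model is
    returned as-is (flag set).  VIP must be computed on the un-rotated model.
    """
    if model.orthogonalized:
        return model
    if model.A == 1:
        return replace(model, orthogonalized=True)
    norms = np.linalg.norm(model.T, axis=0)
    U = model.T / norms
    r1 = norms * model.q  # = D^{1/2} q, proportional to U' y-hat
    nr = np.linalg.norm(r1)
    if nr < 1e-13:
        raise PLSError("degenerate model: fitted values are identically zero")
    r1 = r1 / nr
    R, _ = np.linalg.qr(np.column_stack([r1, np.eye(model.A)]))
    R = R[:, : model.A]
    if R[:, 0] @ r1 < 0:
        R[:, 0] = -R[:, 0]
    T_new = U @ R
    P_new = (model.P * norms) @ R
    q_new = R.T @ (norms * model.q)
    return replace(model, T=T_new, P=P_new, q=q_new, orthogonalized=True)


def predict(model: PLSModel, scaling: Scaling, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new samples: scale(X) @ b + training y mean."""
    Z = scaling.transform(np.atleast_2d(np.asarray(X_new, dtype=float)))
    return Z @ model.b + model.y_mean


def predict_labels(
    model: PLSModel, scaling: Scaling, X_new: np.ndarray, classes: tuple
) -> np.ndarray:
    """Assign each sample the class whose -1/+1 code is nearest to y-hat."""
    yhat = predict(model, scaling, X_new)
    return np.where(yhat > 0.0, classes[1], classes[0])


def encode_labels(labels) -> tuple[np.ndarray, tuple]:
    """Code a two-level label vector as -1/+1 (levels in sorted order)."""
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) != 2:
        raise PLSError(f"PLS-DA requires exactly 2 class levels, got {len(classes)}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    return y, classes


def _fit_fold(X, y, A):
    """Autoscale + center + fit; the minimal unit refit inside every CV fold."""
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if not np.all(sds > 0):
        raise PLSError(
            f"zero-variance predictor inside CV fold: columns "
            f"{np.flatnonzero(~(sds > 0)).tolist()}"
        )
    Z = (X - means) / sds
    ym = y.mean()
    W, _, P, q = _nipals_core(Z, y - ym, A, 1e-12, 100)
    b = _coefficients(W, P, q)
    return means, sds, ym, b


def loo_cv(X: np.ndarray, y: np.ndarray, A: int, *, classification: bool) -> float:
    """Leave-one-out error at a fixed LV count.

    Each fold refits autoscaling and the PLS model on the n-1 remaining
    samples (no leakage) and predicts the held-out sample.  Returns the
    misclassified fraction (classification, -1/+1 coded y) or the mean
    squared prediction error (regression).  Folds run in sample order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise PLSError("LOO CV requires n >= 4")
    idx = np.arange(n)
    err = 0.0
    for i in range(n):
        m = idx != i
        y_tr = y[m]
        if classification and (np.all(y_tr > 0) or np.all(y_tr < 0)):
            raise PLSError(f"fold {i}: training labels are single-class")
        means, sds, ym, b = _fit_fold(X[m], y_tr, A)
        yhat = ((X[i] - means) / sds) @ b + ym
        if classification:
            err += (yhat > 0.0) != (y[i] > 0.0)
        else:
            err += (yhat - y[i]) ** 2
    return float(err) / n


def select_num_lvs(
    X: np.ndarray, y: np.ndarray, A_max: int | None = None, *, classification: bool
) -> CVResult:
    """Choose the LV count minimizing LOO error; ties go to fewer LVs."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cap = min(n - 2, p)
    A_max = cap if A_max is None else min(A_max, cap)
    if A_max < 1:
        raise PLSError("no admissible LV count (need n >= 4 and p >= 1)")
    errors = np.array(
        [loo_cv(X, y, A, classification=classification) for A in range(1, A_max + 1)]
    )
    return CVResult(errors_by_A=errors, A_star=int(np.argmin(errors)) + 1)


def _null_pvalue(
    observed: float, null: np.ndarray, *, classification: bool
) -> tuple[float, float]:
    """Normal-approximation and empirical rank p against a permutation null.

    Classification compares accuracies on the upper tail; regression compares
    MSEs on the lower tail.  An observed value equal to the null mean gives
    p = 0.5 (z = 0).  A degenerate null (sd = 0) yields p = 1 when the
    observed value is no better than the null, else a floor of
    1/(n_perm + 1) with a warning.
    """
    null = np.asarray(null, dtype=float)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    better = null >= observed if classification else null <= observed
    p_emp = float((1 + better.sum()) / (null.size + 1))
    if sd == 0.0:
        if (classification and observed <= mean) or (
            not classification and observed >= mean
        ):
            return 1.0, p_emp
        warnings.warn(
            "degenerate permutation null (sd = 0); reporting floor p-value",
            stacklevel=2,
        )
        return 1.0 / (null.size + 1), p_emp
    z = (observed - mean) / sd
    p = float(stats.norm.sf(z) if classification else stats.norm.cdf(z))
    return min(max(p, np.finfo(float).tiny), 1.0), p_emp


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    A_star: int,
    *,
    n_perm: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    classification: bool = True,
    reselect_lvs: bool = False,
    A_max: int | None = None,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated model.

    Each iteration shuffles y against the unchanged predictor rows and reruns
    the full LOO CV (at the fixed ``A_star`` by default; ``reselect_lvs``
    repeats LV selection per permutation).  The p-value compares the observed
    LOO accuracy (upper tail) or MSE (lower tail) with a normal distribution
    parameterized by the null sample mean and SD; the empirical rank p is
    reported alongside.
    """
    if n_perm < 20:
        raise PLSError("n_perm must be >= 20")
    if rng is None:
        if seed is None:
            raise PLSError("permutation_test requires an explicit seed or rng")
        rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def performance(yv, A):
        e = loo_cv(X, yv, A, classification=classification)
        return 1.0 - e if classification else e

    def run(yv):
        if reselect_lvs:
            A = select_num_lvs(X, yv, A_max, classification=classification).A_star
        else:
            A = A_star
        return performance(yv, A)

    observed = performance(y, A_star)
    null = np.empty(n_perm)
    for i in range(n_perm):
        while True:
            yp = rng.permutation(y)
            if not classification or (np.any(yp[:-1] != yp[0])):
                break
        try:
            null[i] = run(yp)
        except PLSError:
            # a permutation can make some LOO fold single-class; redraw
            null[i] = run(rng.permutation(y))
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    p, p_emp = _null_pvalue(observed, null, classification=classification)
    return PermutationResult(
        observed=observed,
        null_values=null,
        null_mean=mean,
        null_sd=sd,
        p_value=p,
        p_empirical=p_emp,
    )


def vip(model: PLSModel, predictor_names: list[str] | None = None) -> VIPTable:
    """VIP scores: each predictor's normalized contribution across all LVs.

    VIP_j = sqrt( p * sum_a[SSY_a * w_ja^2] / sum_a SSY_a ) with unit-norm
    weight vectors and SSY_a = q_a^2 * t_a' t_a (the response variance each
    component explains).  The squared scores average to 1, so VIP > 1 marks
    an above-average contribution.  Defined on the sequential NIPALS
    components: pass the un-rotated model.
    """
    if model.orthogonalized:
        raise PLSError("VIP is defined on the pre-orthogonalization fit")
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    scores = np.sqrt(p * (model.W**2 @ ssy) / ssy.sum())
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    return VIPTable(vip=scores, predictor_names=list(predictor_names))


def _extract_xy(data, predictor_names):
    """Accept a CleanTable, DataFrame or ndarray and resolve unusable columns.

    Predictors containing any missing cell are dropped (logged, never
    imputed), as are predictors that would have zero variance in some LOO
    fold (>= n-1 identical values — e.g. an analyte censored to 0 in every
    or all-but-one sample), since every fold refits the autoscaling.
    """
    matrix = getattr(data, "matrix", data)
    if hasattr(matrix, "columns"):  # DataFrame
        names = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = (
            list(predictor_names)
            if predictor_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
    n = X.shape[0]
    keep = ~np.isnan(X).any(axis=0)
    for j in np.flatnonzero(keep):
        _, counts = np.unique(X[:, j], return_counts=True)
        if counts.max() >= n - 1:
            keep[j] = False
    dropped = [nm for nm, k in zip(names, keep) if not k]
    X = X[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    if X.shape[0] < 4 or X.shape[1] < 2:
        raise PLSError("need n >= 4 samples and p >= 2 usable predictors")
    return X, names, dropped


def fit_plsda(
    data,
    labels,
    *,
    n_perm: int = 1000,
    seed=None,
    A_max: int | None = None,
    predictor_names: list[str] | None = None,
) -> PLSDAResult:
    """End-to-end PLS-DA: scale, select LVs by LOO, refit, orthogonalize,
    permutation-test, and score VIP.

    ``data`` may be a CleanTable, a samples x analytes DataFrame, or an
    ndarray.  ``accuracy`` is 1 - LOO classification error at the selected
    LV count; the orthogonalized model's LV1 loadings are the signed
    signature.  A seed (or rng) is mandatory for the permutation test.
    """
    X, names, dropped = _extract_xy(data, predictor_names)
    y, classes = encode_labels(labels)
    for c in classes:
        if int((np.asarray(labels) == c).sum()) < 2:
            raise PLSError(f"class {c!r} has fewer than 2 samples")
    n, p = X.shape
    cap = min(n - 2, p, 5)
    A_max = cap if A_max is None else min(A_max, cap)

    Z, scaling = autoscale(X, names)
    cv = select_num_lvs(X, y, A_max, classification=True)
    model = nipals_pls(Z, y - y.mean(), cv.A_star, y_mean=float(y.mean()))
    vip_table = vip(model, names)
    model = orthogonalize(model)
    perm = permutation_test(
        X, y, cv.A_star, n_perm=n_perm, seed=seed, classification=True
    )
    return PLSDAResult(
        model=model,
        scaling=scaling,
        cv=cv,
        accuracy=float(1.0 - cv.errors_by_A[cv.A_star - 1]),
        permutation=perm,
        vip_table=vip_table,
        classes=classes,
        predictor_names=names,
        dropped_predictors=dropped,
    )


def fit_plsr(
    data,
    y,
    *,
    n_perm: int = 1000,
    seed=None,
    A_max: int | None = None,
    predictor_names: list[str] | None = None,
) -> PLSRResult:
    """End-to-end PLS regression on a continuous response.

    Same pipeline as :func:`fit_plsda` with MSE-based LV selection and a
    lower-tail permutation null on the LOO MSE.  ``q2`` is the
    cross-validated R^2 (1 - PRESS/TSS).
    """
    X, names, dropped = _extract_xy(data, predictor_names)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 3:
        raise PLSError("PLS regression requires a response with >= 3 distinct values")
    n, p = X.shape
    cap = min(n - 2, p, 5)
    A_max = cap if A_max is None else min(A_max, cap)

    Z, scaling = autoscale(X, names)
    cv = select_num_lvs(X, y, A_max, classification=False)
    model = nipals_pls(Z, y - y.mean(), cv.A_star, y_mean=float(y.mean()))
    vip_table = vip(model, names)
    model = orthogonalize(model)
    perm = permutation_test(
        X, y, cv.A_star, n_perm=n_perm, seed=seed, classification=False
    )
    mse = float(cv.errors_by_A[cv.A_star - 1])
    tss = float(np.mean((y - y.mean()) ** 2))
    return PLSRResult(
        model=model,
        scaling=scaling,
        cv=cv,
        mse=mse,
        q2=float(1.0 - mse / tss) if tss > 0 else float("nan"),
        permutation=perm,
        vip_table=vip_table,
        predictor_names=names,
        dropped_predictors=dropped,
    )
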
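"""Feature reduction for voxel matrices: Aggregate Selection and kernel PLS.

Two complementary reductions of the subjects x voxels feature matrix:

* **Aggregate Selection (AS)** — three univariate/multivariate ranking
  criteria (Fisher score, two-sample t statistic, sparse L1-regularized
  logistic regression) are aggregated through a modified analytic hierarchy
  process (AHP): each criterion's scores define a pairwise comparison matrix
  whose principal eigenvector is a normalized ranking; the eigenvectors form
  the columns of a performance matrix, which multiplied by a criterion
  weight vector (default 1/3 each) yields the final feature ranking.
* **Kernel PLS (kPLS)** — components are extracted iteratively as dominant
  eigenvectors of the product ``K_X K_y`` of the (centered, deflated) data
  and label kernels; per-feature explanatory weights ``w_i`` and
  per-component contributions ``gamma_l`` summarize the fit.

Consistency of a comparison matrix ``M`` of order ``n`` with principal
eigenvalue ``lambda_max`` is measured by the consistency index
``CI = (lambda_max - n)/(n - 1)`` and the consistency ratio ``CR = CI/RI``
with ``RI`` the random-consistency index.  Ratio-built matrices
(``M_ij = s_i / s_j``) are transitive and perfectly consistent by
construction, so ``CR = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .io_volumes import ValidationError, Volume

__all__ = [
    "FeatureMatrix",
    "ComparisonMatrix",
    "PerformanceMatrix",
    "AggregateSelection",
    "KPLSModel",
    "fisher_score",
    "ttest_score",
    "sbmlr_score",
    "positivize_scores",
    "ranking_eigenvector",
    "build_comparison_matrix",
    "consistency_ratio",
    "random_index",
    "aggregate_select",
    "kpls_fit",
    "kpls_transform",
    "CRITERIA",
]


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Subjects x features value matrix with binary labels.

    ``y`` is coded 0/1; ``feature_ids`` are stable identifiers (for voxel
    features, ``"i_j_k"`` coordinates of the flattened grid).
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (subjects x features)")
        if len(self.y) != self.X.shape[0]:
            raise ValidationError("y length must match number of subjects")
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValidationError("feature_ids length must match D")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValidationError("labels must be coded 0/1")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_two_classes(self, min_per_class: int = 2) -> None:
        counts = np.bincount(self.y, minlength=2)
        if (counts < min_per_class).any():
            raise ValidationError(
                f"need >= {min_per_class} subjects per class, got counts "
                f"{counts.tolist()}"
            )

    @classmethod
    def from_volumes(
        cls, volumes: Sequence[Volume], positive_class: str
    ) -> "FeatureMatrix":
        """Flatten cohort voxel grids into a feature matrix.

        ``positive_class`` names the label coded 1 (e.g. the patient
        class); all other labels are coded 0.
        """
        if not volumes:
            raise ValidationError("empty cohort")
        shape = volumes[0].shape
        for v in volumes:
            if v.shape != shape:
                raise ValidationError("cohort volumes disagree in shape")
        X = np.stack([v.voxels.ravel() for v in volumes])
        y = np.array(
            [1 if v.label == positive_class else 0 for v in volumes]
        )
        ii, jj, kk = np.unravel_index(np.arange(X.shape[1]), shape)
        ids = np.array([f"{i}_{j}_{k}" for i, j, k in zip(ii, jj, kk)])
        subject_ids = np.array([v.subject_id for v in volumes])
        return cls(X=X, y=y, feature_ids=ids, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# ranking criteria


def fisher_score(fm: FeatureMatrix) -> np.ndarray:
    """Per-feature Fisher discriminant score.

    ``score_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2`` with
    class sizes ``n_c``, class means ``mu_cj`` and (population) class
    variances ``sigma_cj^2``.  Degenerate features: 0/0 -> 0; a positive
    numerator over a zero denominator (perfect separator with zero
    within-class variance) gets the largest finite score + 1 as a sentinel.
    """
    fm.require_two_classes()
    mu = fm.X.mean(axis=0)
    num = np.zeros(fm.n_features)
    den = np.zeros(fm.n_features)
    for c in (0, 1):
        Xc = fm.X[fm.y == c]
        nc = Xc.shape[0]
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    scores = np.zeros(fm.n_features)
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    sentinel = ~ok & (num > 0)
    if sentinel.any():
        finite_max = scores[ok].max() if ok.any() else 0.0
        scores[sentinel] = finite_max + 1.0
    return scores


def ttest_score(fm: FeatureMatrix) -> np.ndarray:
    """Per-feature |Welch two-sample t statistic|.

    Features constant within both classes score 0 when class means agree
    and the sentinel (largest finite score + 1) when they differ.
    """
    fm.require_two_classes()
    X0, X1 = fm.X[fm.y == 0], fm.X[fm.y == 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(X1, X0, equal_var=False).statistic
    scores = np.abs(t)
    bad = ~np.isfinite(scores)
    if bad.any():
        diff = np.abs(X1.mean(axis=0) - X0.mean(axis=0))
        finite_max = scores[~bad].max() if (~bad).any() else 0.0
        scores[bad] = np.where(diff[bad] > 0, finite_max + 1.0, 0.0)
    return scores


def sbmlr_score(
    fm: FeatureMatrix,
    reg: float | Sequence[float] | None = None,
    k_in: int = 3,
    seed: int = 0,
    max_iter: int = 2000,
) -> np.ndarray:
    """Sparse-logistic-regression feature importances.

    An L1-penalized (binary) logistic regression is fitted on internally
    standardized features; importance is the absolute fitted coefficient,
    so most scores are exactly zero at adequate regularization.  ``reg`` is
    the inverse penalty C: a float fixes it, a sequence is searched by
    inner stratified CV (log-loss), and ``None`` uses the default grid
    (0.1, 1.0).
    """
    fm.require_two_classes()
    scaler = StandardScaler()
    Xs = scaler.fit_transform(fm.X)
    if reg is None:
        reg = (0.1, 1.0)

    def fit(C: float) -> LogisticRegression:
        model = LogisticRegression(
            l1_ratio=1.0,
            C=C,
            solver="liblinear",
            random_state=seed,
            max_iter=max_iter,
            tol=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            try:
                model.fit(Xs, fm.y)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"sparse logistic regression failed to converge "
                    f"(C={C}, max_iter={max_iter}): {exc}"
                ) from exc
        return model

    if np.isscalar(reg):
        best_C = float(reg)  # type: ignore[arg-type]
    else:
        grid = [float(c) for c in reg]  # type: ignore[union-attr]
        counts = np.bincount(fm.y, minlength=2)
        n_splits = min(k_in, int(counts.min()))
        if n_splits < 2 or len(grid) == 1:
            best_C = grid[-1]
        else:
            cv = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=seed
            )
            losses = []
            for C in grid:
                fold_losses = []
                for tr, te in cv.split(Xs, fm.y):
                    m = LogisticRegression(
                        l1_ratio=1.0,
                        C=C,
                        solver="liblinear",
                        random_state=seed,
                        max_iter=max_iter,
                    )
                    m.fit(Xs[tr], fm.y[tr])
                    p = np.clip(m.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                    yt = fm.y[te]
                    fold_losses.append(
                        -np.mean(yt * np.log(p) + (1 - yt) * np.log(1 - p))
                    )
                losses.append(np.mean(fold_losses))
            best_C = grid[int(np.argmin(losses))]
    return np.abs(fit(best_C).coef_.ravel())


CRITERIA: dict[str, Callable[..., np.ndarray]] = {
    "fisher": fisher_score,
    "ttest": ttest_score,
    "sbmlr": sbmlr_score,
}


# ---------------------------------------------------------------------------
# AHP machinery

#: Saaty random-consistency indices for matrix orders 1..15
_SAATY_RI = (
    0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41,
    1.45, 1.49, 1.51, 1.48, 1.56, 1.57, 1.59,
)


def random_index(n: int) -> float:
    """Random-consistency index RI(n); asymptotic 1.98*(n-2)/n for n > 15."""
    if n < 1:
        raise ValidationError("matrix order must be >= 1")
    if n <= 15:
        return _SAATY_RI[n - 1]
    return 1.98 * (n - 2) / n


def positivize_scores(scores: np.ndarray) -> np.ndarray:
    """Shift-and-floor scores to strict positivity for ratio matrices.

    ``s'_j = s_j - min(s) + delta`` with ``delta = 1e-6 * range(s)``.  A
    constant score vector carries no ranking information and maps to the
    uniform vector of ones (uniform eigenvector downstream).
    """
    scores = np.asarray(scores, dtype=np.float64)
    rng = float(scores.max() - scores.min())
    if rng == 0.0:
        return np.ones_like(scores)
    delta = 1e-6 * rng
    return scores - scores.min() + delta


@dataclass
class ComparisonMatrix:
    """Square positive reciprocal pairwise-comparison matrix.

    Carries the principal eigenpair and the consistency analytics
    ``CI = (lambda_max - n)/(n - 1)`` and ``CR = CI/RI``.  ``eigvec`` is
    normalized to sum 1 (the ranking vector).
    """

    M: np.ndarray
    lambda_max: float
    eigvec: np.ndarray
    CI: float
    CR: float
    RI: float

    @property
    def order(self) -> int:
        return self.M.shape[0]


def _principal_eigenpair(M: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = scipy.linalg.eig(M)
    i = int(np.argmax(vals.real))
    lam = float(vals[i].real)
    vec = vecs[:, i].real
    vec = np.abs(vec)  # Perron vector of a positive matrix is positive
    return lam, vec / vec.sum()


def consistency_ratio(
    M: np.ndarray, lambda_max: float | None = None, atol: float = 1e-12
) -> float:
    """Consistency ratio CR = CI / RI of a pairwise-comparison matrix.

    A consistent set of judgments has CR not exceeding 0.1; CR = 0 means
    perfect consistency.  When CI vanishes (within ``atol``) CR is 0 by
    convention even for orders whose RI is 0.
    """
    M = np.asarray(M, dtype=np.float64)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("comparison matrix must be square")
    if n < 2:
        raise ValidationError("consistency ratio requires order >= 2")
    if lambda_max is None:
        lambda_max, _ = _principal_eigenpair(M)
    ci = (lambda_max - n) / (n - 1)
    ri = random_index(n)
    if abs(ci) <= atol:
        return 0.0
    if ri == 0.0:
        raise ValidationError(
            f"RI({n}) = 0 but CI = {ci:.3g} != 0; CR undefined"
        )
    return ci / ri


def build_comparison_matrix(scores: np.ndarray) -> ComparisonMatrix:
    """Ratio comparison matrix ``M_ij = s_i / s_j`` from criterion scores.

    Scores are positivized first (see :func:`positivize_scores`).  The
    resulting matrix is reciprocal and perfectly consistent (transitive) by
    construction, its principal eigenvalue equals the order, and its
    principal eigenvector is the normalized positivized score vector —
    hence CR = 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or len(scores) < 2:
        raise ValidationError("need a 1-D vector of >= 2 scores")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if np.all(scores == 0):
        raise ValidationError("all-zero score vector")
    s = positivize_scores(scores)
    M = s[:, None] / s[None, :]
    lam, vec = _principal_eigenpair(M)
    n = M.shape[0]
    ci = (lam - n) / (n - 1)
    cr = consistency_ratio(M, lambda_max=lam)
    return ComparisonMatrix(
        M=M, lambda_max=lam, eigvec=vec, CI=ci, CR=cr, RI=random_index(n)
    )


def ranking_eigenvector(scores: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the ratio comparison matrix, closed form.

    For ``M_ij = s_i / s_j`` the matrix is rank one with principal
    eigenvector proportional to ``s``; the normalized positivized score
    vector is therefore returned directly, which stays tractable for voxel
    dimensions where the explicit D x D matrix would not fit in memory.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    s = positivize_scores(scores)
    return s / s.sum()


@dataclass
class PerformanceMatrix:
    """Features x criteria matrix of eigenvector-derived ranking scores.

    Each column is a normalized principal eigenvector (sums to 1); the
    final ranking is ``S @ weights`` with the criterion importance weights
    (default equal, summing to 1).
    """

    S: np.ndarray
    criterion_names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.S.shape[1] != len(self.criterion_names):
            raise ValidationError("one column per criterion required")
        if len(self.weights) != len(self.criterion_names):
            raise ValidationError("one weight per criterion required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("criterion weights must sum to 1")
        colsums = self.S.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValidationError("performance-matrix columns must sum to 1")

    def final_scores(self) -> np.ndarray:
        return self.S @ self.weights


@dataclass
class AggregateSelection:
    """Result of Aggregate Selection: ranked features and provenance."""

    selected_ids: np.ndarray
    selected_indices: np.ndarray
    final_scores: np.ndarray  # all D features, aggregation order preserved
    performance: PerformanceMatrix
    criterion_scores: dict[str, np.ndarray]


def aggregate_select(
    fm: FeatureMatrix,
    k: int,
    weights: Sequence[float] | None = None,
    criteria: Sequence[str] = ("fisher", "ttest", "sbmlr"),
    seed: int = 0,
    sbmlr_reg: float | Sequence[float] | None = None,
) -> AggregateSelection:
    """Aggregate-Selection feature ranking and top-``k`` selection.

    Per criterion: raw scores -> ratio comparison matrix -> normalized
    principal eigenvector -> one performance-matrix column.  The final
    score is the performance matrix times the criterion weight vector
    (default 1/len(criteria) each, avoiding bias toward any criterion);
    the top-``k`` features by final score are returned, ties broken by
    feature id (stable order).
    """
    if k < 1 or k > fm.n_features:
        raise ValidationError(
            f"k must be in [1, {fm.n_features}], got {k}"
        )
    if weights is None:
        weights = np.full(len(criteria), 1.0 / len(criteria))
    weights = np.asarray(weights, dtype=np.float64)
    crit_scores: dict[str, np.ndarray] = {}
    columns = []
    for name in criteria:
        if name not in CRITERIA:
            raise ValidationError(f"unknown criterion {name!r}")
        try:
            if name == "sbmlr":
                raw = sbmlr_score(fm, reg=sbmlr_reg, seed=seed)
            else:
                raw = CRITERIA[name](fm)
        except Exception as exc:
            raise RuntimeError(f"criterion {name!r} failed: {exc}") from exc
        crit_scores[name] = raw
        columns.append(ranking_eigenvector(raw))
    perf = PerformanceMatrix(
        S=np.column_stack(columns),
        criterion_names=tuple(criteria),
        weights=weights,
    )
    final = perf.final_scores()
    # stable top-k: sort by (-score, feature_id)
    order = np.lexsort((fm.feature_ids, -final))
    top = np.sort(order[:k])
    return AggregateSelection(
        selected_ids=fm.feature_ids[top],
        selected_indices=top,
        final_scores=final,
        performance=perf,
        criterion_scores=crit_scores,
    )


# ---------------------------------------------------------------------------
# kernel PLS


def _gram(
    A: np.ndarray,
    B: np.ndarray,
    kernel: str,
    gamma: float | None,
) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        d2 = pairwise_distances(A, B, metric="sqeuclidean")
        return np.exp(-gamma * d2)
    raise ValidationError(f"unknown kernel {kernel!r}")


def _median_heuristic(X: np.ndarray) -> float:
    """RBF bandwidth gamma = 1/(2 m^2) with m the median pairwise distance."""
    d = pairwise_distances(X, metric="euclidean")
    iu = np.triu_indices_from(d, k=1)
    med = float(np.median(d[iu])) if len(iu[0]) else 1.0
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


@dataclass
class KPLSModel:
    """Fitted kernel-PLS extractor.

    ``T`` (subjects x h) are the extracted components: each ``t_l`` is the
    unit-norm dominant eigenvector of the current deflated ``K_X K_y``,
    sign-oriented so its correlation with the labels is non-negative.  The
    model stores the dual coefficients needed to project new subjects, the
    per-feature explanatory weights ``w`` (larger = more explanatory
    power), correlation loadings ``v`` (features x h), label correlations
    ``psi`` per component, and component contributions ``gamma``
    (class-size-weighted means of the class centroids on each component).
    """

    kernel: str
    gamma_kernel: float | None
    h: int
    T: np.ndarray
    eigenvalues: np.ndarray
    alphas: np.ndarray  # subjects x h dual coefficients: t_l = K^(l) alpha_l
    deflation_rows: np.ndarray  # h x subjects: b_l = t_l^T K^(l)
    X_train: np.ndarray
    y_train: np.ndarray
    K_row_means: np.ndarray
    K_mean: float
    w: np.ndarray
    v: np.ndarray
    psi: np.ndarray
    gamma: np.ndarray
    class_counts: np.ndarray
    class_means: np.ndarray  # classes x h: m_il
    feature_ids: np.ndarray

    def scatter_diagnostics(self) -> tuple[np.ndarray, np.ndarray]:
        """Inter- and intra-class scatter matrices (S1, S2) of the
        component scores — the discriminative-form diagnostics."""
        grand = self.T.mean(axis=0)
        S1 = np.zeros((self.h, self.h))
        S2 = np.zeros((self.h, self.h))
        for c, n_c in enumerate(self.class_counts):
            Tc = self.T[self.y_train == c]
            mc = Tc.mean(axis=0)
            d = (mc - grand)[:, None]
            S1 += n_c * (d @ d.T)
            centered = Tc - mc
            S2 += centered.T @ centered
        return S1, S2


class ReducedRankWarning(UserWarning):
    """Fewer kPLS components were extractable than requested."""


def kpls_fit(
    fm: FeatureMatrix,
    h: int = 10,
    kernel: str = "rbf",
    gamma: float | None = None,
    corr_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> KPLSModel:
    """Fit kernel PLS with ``h`` components.

    The data kernel is double-centered; the label kernel is
    ``K_y = y_c y_c^T`` with centered labels.  Components are extracted
    iteratively: the dominant eigenvector of the current ``K_X K_y`` is the
    component ``t_l`` (unit norm), after which both kernels are deflated by
    the projection ``P = I - t_l t_l^T``, making successive components
    mutually orthogonal.  If the kernels are rank deficient and fewer than
    ``h`` informative components exist, a :class:`ReducedRankWarning` is
    issued and the achievable components are returned.

    The default kernel is Gaussian with the median-pairwise-distance
    bandwidth heuristic; a linear kernel is available (and makes the first
    component coincide with classical PLS).
    """
    fm.require_two_classes()
    N = fm.n_subjects
    if h < 1 or h > N - 1:
        raise ValidationError(f"h must be in [1, {N - 1}], got {h}")
    if kernel == "rbf" and gamma is None:
        gamma = _median_heuristic(fm.X)
    K_raw = _gram(fm.X, fm.X, kernel, gamma)
    row_means = K_raw.mean(axis=0)
    k_mean = float(K_raw.mean())
    H = np.eye(N) - np.full((N, N), 1.0 / N)
    K = H @ K_raw @ H
    yc = fm.y - fm.y.mean()
    Ky = np.outer(yc, yc)

    if corr_fn is None:
        corr_fn = lambda a, b: float(np.corrcoef(a, b)[0, 1])

    T, alphas, brows, lams = [], [], [], []
    for _ in range(h):
        lam, t = _leading_real_eig(K @ Ky)
        if lam <= 1e-10 * max(1.0, abs(np.trace(K @ Ky))) or not np.isfinite(lam):
            break
        t = t / np.linalg.norm(t)
        if corr_fn(fm.y.astype(float), t) < 0:
            t = -t
        alpha = Ky @ t / lam  # K @ alpha == t by the eigen relation
        T.append(t)
        alphas.append(alpha)
        brows.append(t @ K)
        lams.append(lam)
        P = np.eye(N) - np.outer(t, t)
        K = P @ K @ P
        Ky = P @ Ky @ P
    n_found = len(T)
    if n_found == 0:
        raise ValidationError("kernel is degenerate: no component extractable")
    if n_found < h:
        warnings.warn(
            f"rank-deficient kernel: extracted {n_found} of {h} requested "
            f"components",
            ReducedRankWarning,
        )
    T_arr = np.column_stack(T)

    # explanatory weights, Eq-style: w_i = D * sum_l psi_l v_il^2 / sum_l psi_l
    psi = np.array([max(corr_fn(fm.y.astype(float), t), 0.0) for t in T])
    v = _corr_loadings(fm.X, T_arr)
    denom = psi.sum()
    if denom > 0:
        w = fm.n_features * (v**2 @ psi) / denom
    else:
        w = np.zeros(fm.n_features)

    counts = np.bincount(fm.y, minlength=2).astype(float)
    class_means = np.stack(
        [T_arr[fm.y == c].mean(axis=0) for c in (0, 1)]
    )
    gamma_l = (counts[:, None] * class_means).sum(axis=0) / counts.sum()

    return KPLSModel(
        kernel=kernel,
        gamma_kernel=gamma,
        h=n_found,
        T=T_arr,
        eigenvalues=np.array(lams),
        alphas=np.column_stack(alphas),
        deflation_rows=np.stack(brows),
        X_train=fm.X.copy(),
        y_train=fm.y.copy(),
        K_row_means=row_means,
        K_mean=k_mean,
        w=w,
        v=v,
        psi=psi,
        gamma=gamma_l,
        class_counts=counts,
        class_means=class_means,
        feature_ids=fm.feature_ids,
    )


def _leading_real_eig(A: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = scipy.linalg.eig(A)
    i = int(np.argmax(vals.real))
    return float(vals[i].real), vecs[:, i].real


def _corr_loadings(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Pearson correlation of each feature column with each component."""
    Xc = X - X.mean(axis=0)
    Tc = T - T.mean(axis=0)
    sx = Xc.std(axis=0)
    st = Tc.std(axis=0)
    num = Xc.T @ Tc / X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / np.outer(sx, st)
    out[~np.isfinite(out)] = 0.0
    return out


def kpls_transform(model: KPLSModel, X_new: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Project new subjects onto the fitted components.

    Applies the training centering to the test kernel and replays the
    per-component deflation, so transforming the training set reproduces
    ``model.T`` exactly (up to round-off).
    """
    if isinstance(X_new, FeatureMatrix):
        X_new = X_new.X
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.X_train.shape[1]:
        raise ValidationError(
            f"expected {model.X_train.shape[1]} features, got shape "
            f"{X_new.shape}"
        )
    Kt_raw = _gram(X_new, model.X_train, model.kernel, model.gamma_kernel)
    N = model.X_train.shape[0]
    # double centering with training statistics
    Kt = (
        Kt_raw
        - Kt_raw.mean(axis=1, keepdims=True)
        - model.K_row_means[None, :]
        + model.K_mean
    )
    scores = np.empty((X_new.shape[0], model.h))
    for l in range(model.h):
        t = model.T[:, l]
        t_new = Kt @ model.alphas[:, l]
        scores[:, l] = t_new
        # deflate the test kernel consistently with training deflation
        Kt = (Kt - np.outer(t_new, model.deflation_rows[l])) @ (
            np.eye(N) - np.outer(t, t)
        )
    return scores


# ---------------------------------------------------------------------------
# CSV exports


def selection_to_frame(sel: AggregateSelection, shape=None):
    """Selected features as a DataFrame (feature_id, voxel coords, scores)."""
    import pandas as pd

    rows = {
        "feature_id": sel.selected_ids,
        "final_score": sel.final_scores[sel.selected_indices],
    }
    ids = [str(f) for f in sel.selected_ids]
    if all(s.count("_") == 2 for s in ids):
        coords = np.array([[int(p) for p in s.split("_")] for s in ids])
        rows["i"], rows["j"], rows["k"] = coords.T
    for name, scores in sel.criterion_scores.items():
        rows[f"score_{name}"] = scores[sel.selected_indices]
    return pd.DataFrame(rows)


def kpls_scores_to_frame(model: KPLSModel, subject_ids=None):
    """Component-score matrix T as a DataFrame (one column per component)."""
    import pandas as pd

    cols = {f"t{l + 1}": model.T[:, l] for l in range(model.h)}
    frame = pd.DataFrame(cols)
    if subject_ids is not None:
        frame.insert(0, "subject_id", list(subject_ids))
    return frame
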
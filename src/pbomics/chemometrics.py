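"""PCA and NIPALS partial least squares with SIMCA-style validation.

The multivariate core of the pipeline: principal components analysis for
unsupervised inspection, PLS regression of a spectral or transcriptomic
X-block on a response (dose, or a single metabolite), cross-validated Q²
computed by the leave-every-7th-sample rule, Y-permutation validation, and
repeated leave-out dose prediction.

Everything here is written from first principles on top of numpy; the
scaling conventions (mean centering, Pareto or unit-variance scaling) follow
standard chemometrics practice:

* Pareto scaling divides a centered column by the square root of its
  standard deviation — it tempers, without flattening, the dominance of
  intense spectral regions, and is the usual choice for binned NMR data.
* Unit-variance scaling divides by the standard deviation itself and is
  preferred for peak tables where every feature is an identified compound.

Q² is the cross-validated analogue of R²:  ``Q² = 1 - PRESS/SS`` where PRESS
is the squared prediction error for samples held out of the fit and SS the
residual sum of squares before the component was added.  A model is trusted
only when its Q² clearly exceeds the Q² distribution obtained after randomly
permuting the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalingSpec",
    "PCAResult",
    "PLSModel",
    "ValidationResult",
    "scale_matrix",
    "fit_pca",
    "fit_pls",
    "q2_cv",
    "permutation_validate",
    "predict_left_out",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class ScalingSpec:
    """Column centering/scaling choice for a data block."""

    center: bool = True
    mode: str = "none"  # none | pareto | unit_variance

    def __post_init__(self) -> None:
        if self.mode not in ("none", "pareto", "unit_variance"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")


def _column_sd(X: np.ndarray) -> np.ndarray:
    return X.std(axis=0, ddof=1)


def scale_matrix(
    X: np.ndarray, spec: ScalingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale a samples x features matrix.

    Zero-variance columns cannot be scaled and are dropped (their indices
    are returned so callers can log them).

    Returns
    -------
    (scaled, centers, scales, dropped_columns)
        ``scaled`` has zero-variance columns removed when a scaling mode is
        active; ``centers``/``scales`` align with the *kept* columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if X.shape[0] < 2:
        raise ValueError("scaling requires at least 2 samples")
    sd = _column_sd(X)
    if spec.mode != "none":
        dropped = np.flatnonzero(sd == 0)
        if dropped.size == X.shape[1]:
            raise ValueError("every column has zero variance; nothing to scale")
        keep = np.flatnonzero(sd != 0)
        X = X[:, keep]
        sd = sd[keep]
    else:
        dropped = np.array([], dtype=int)
    centers = X.mean(axis=0) if spec.center else np.zeros(X.shape[1])
    if spec.mode == "pareto":
        scales = np.sqrt(sd)
    elif spec.mode == "unit_variance":
        scales = sd.copy()
    else:
        scales = np.ones(X.shape[1])
    return (X - centers) / scales, centers, scales, dropped


@dataclass
class PCAResult:
    scores: np.ndarray  # n x a
    loadings: np.ndarray  # p x a, orthonormal columns
    r2x: np.ndarray  # per-component fraction of total variance


def fit_pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal components of an already centered/scaled matrix.

    Components are the right singular vectors of X ordered by decreasing
    explained variance; scores are the projections ``X @ loadings``.
    ``n_components`` beyond the numerical rank is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    total = float(np.sum(s**2))
    load = Vt[:n_components].T
    return PCAResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=load,
        r2x=(s[:n_components] ** 2) / total,
    )


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model with its preprocessing frozen in.

    Weights ``W`` (p x a), X-loadings ``P`` (p x a), X-scores ``T`` (n x a)
    and Y-loadings ``Q`` (m x a) follow the usual NIPALS notation; the
    stored centers/scales let the model predict new raw samples.
    """

    n_components: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    Q: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    r2x: np.ndarray = field(default_factory=lambda: np.array([]))
    r2y: np.ndarray = field(default_factory=lambda: np.array([]))
    q2: np.ndarray | None = None
    q2_cum: float | None = None

    @property
    def r2y_cum(self) -> float:
        return float(np.sum(self.r2y))

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict responses for new samples on the original Y scale."""
        a_max = n_components if n_components is not None else self.n_components
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xd = (X - self.x_center) / self.x_scale
        Yhat = np.zeros((X.shape[0], self.Q.shape[0]))
        for a in range(a_max):
            t = Xd @ self.W[:, a]
            Yhat += np.outer(t, self.Q[:, a])
            Xd = Xd - np.outer(t, self.P[:, a])
        Yhat = Yhat * self.y_scale + self.y_center
        return Yhat[:, 0] if Yhat.shape[1] == 1 else Yhat


def _as_2d_y(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    x_scaling: ScalingSpec = ScalingSpec(center=True, mode="none"),
    y_scaling: ScalingSpec = ScalingSpec(center=True, mode="none"),
) -> PLSModel:
    """Fit a PLS model by NIPALS with deflation of X and Y.

    The weight vector of each component is seeded from X'u (u initialised
    from the Y column of largest variance), so the fit is deterministic.
    For a single response the inner loop converges in one pass and the
    one-component prediction coincides with the closed-form regression on
    the score ``t = X w``.

    Scaling defaults to plain mean centering: apply Pareto/UV scaling
    upstream via :func:`scale_matrix` or pass a spec here.
    """
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d_y(Y)
    if X.shape[0] != Y2.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.allclose(Y2, Y2[0], atol=0):
        raise ValueError("Y is constant; PLS target undefined")

    Xs, xc, xsc, dropped = scale_matrix(X, x_scaling)
    if dropped.size:
        warnings.warn(f"dropped {dropped.size} zero-variance X columns", stacklevel=2)
    ysd = _column_sd(Y2)
    yc = Y2.mean(axis=0) if y_scaling.center else np.zeros(Y2.shape[1])
    if y_scaling.mode == "unit_variance":
        ysc = np.where(ysd == 0, 1.0, ysd)
    elif y_scaling.mode == "pareto":
        ysc = np.where(ysd == 0, 1.0, np.sqrt(ysd))
    else:
        ysc = np.ones(Y2.shape[1])
    Ys = (Y2 - yc) / ysc

    n, p = Xs.shape
    m = Ys.shape[1]
    a_max = min(n_components, n - 1 if x_scaling.center else n, p)
    Xd, Yd = Xs.copy(), Ys.copy()
    ss_x_tot = float(np.sum(Xs**2))
    ss_y_tot = float(np.sum(Ys**2))
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    Q = np.zeros((m, a_max))
    r2x = np.zeros(a_max)
    r2y = np.zeros(a_max)
    # covariance scale for detecting a vanishing weight vector
    w_floor = 1e-14 * max(np.sqrt(ss_x_tot * ss_y_tot), 1e-300)
    extracted = a_max
    for a in range(a_max):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        stop = False
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw <= w_floor:
                # residual X carries no covariance with residual Y: the
                # component is undefined and R2Y stops growing here
                stop = True
                break
            w = w / nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            if m == 1:  # PLS1: the first pass is already the fixed point
                break
            u_new = Yd @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= _NIPALS_TOL * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        if stop:
            extracted = a
            break
        t = Xd @ w
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_load, t, q
        r2x[a] = tt * float(p_load @ p_load) / ss_x_tot
        r2y[a] = tt * float(q @ q) / ss_y_tot
    return PLSModel(
        n_components=extracted,
        W=W[:, :extracted],
        P=P[:, :extracted],
        T=T[:, :extracted],
        Q=Q[:, :extracted],
        x_center=xc,
        x_scale=xsc,
        y_center=yc,
        y_scale=ysc,
        r2x=r2x[:extracted],
        r2y=r2y[:extracted],
    )


def _segment_masks(n: int, n_segments: int) -> list[np.ndarray]:
    idx = np.arange(n)
    return [idx % n_segments == k for k in range(n_segments)]


def q2_cv(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_segments: int = 7,
    x_scaling: ScalingSpec = ScalingSpec(center=True, mode="none"),
) -> tuple[np.ndarray, float]:
    """Cross-validated Q² by the round-robin "leave every 7th sample" rule.

    Segment ``k`` holds the samples whose index is congruent to ``k`` modulo
    ``n_segments`` in input order.  For each component count ``a`` the model
    is refitted without each segment (preprocessing recomputed on the
    training samples only) and the held-out responses predicted:

        PRESS_a = sum over samples of (y - yhat_without_its_segment)^2
        Q²_a    = 1 - PRESS_a / SS_{a-1}

    with SS_0 the total sum of squares of centered Y and SS_{a-1} the
    residual sum of squares of the full-data model after a-1 components.
    The cumulative Q² is ``1 - prod_a(PRESS_a / SS_{a-1})``.

    Returns (per-component Q², cumulative Q²).
    """
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d_y(Y)
    n = X.shape[0]
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n < n_segments:
        raise ValueError(f"{n} samples cannot fill {n_segments} segments")

    full = fit_pls(X, Y2, n_components, x_scaling=x_scaling)
    a_max = full.n_components
    # residual SS of centered Y after each component count of the full model
    Ys = (Y2 - full.y_center) / full.y_scale
    ss = [float(np.sum(Ys**2))]
    resid = Ys.copy()
    for a in range(a_max):
        resid = resid - np.outer(full.T[:, a], full.Q[:, a])
        ss.append(float(np.sum(resid**2)))

    press = np.zeros(a_max)
    masks = _segment_masks(n, n_segments)
    for mask in masks:
        sub = fit_pls(X[~mask], Y2[~mask], a_max, x_scaling=x_scaling)
        for a in range(a_max):
            if a < sub.n_components:
                yhat = _as_2d_y(sub.predict(X[mask], n_components=a + 1))
            else:  # rank-deficient training fold: reuse its deepest model
                yhat = _as_2d_y(sub.predict(X[mask], n_components=sub.n_components))
            press[a] += float(np.sum(((Y2[mask] - yhat) / full.y_scale) ** 2))

    q2 = np.array([1.0 - press[a] / ss[a] for a in range(a_max)])
    q2_cum = 1.0 - float(np.prod([press[a] / ss[a] for a in range(a_max)]))
    return q2, q2_cum


@dataclass
class ValidationResult:
    """Outcome of a Y-permutation validation run.

    ``permuted`` rows are (|correlation of permuted Y with original Y|, R²Y,
    cumulative Q²), one per permutation; the unpermuted model sits at
    correlation 1 in (real_r2, real_q2).
    """

    real_r2: float
    real_q2: float
    permuted: np.ndarray  # n_permutations x 3
    n_permutations: int
    seed: int


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.ravel(a), np.ravel(b)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def permutation_validate(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_permutations: int = 200,
    seed: int = 0,
    n_segments: int = 7,
    x_scaling: ScalingSpec = ScalingSpec(center=True, mode="none"),
) -> ValidationResult:
    """Compare the real model against models fit to row-permuted responses.

    Each iteration permutes the rows of Y uniformly at random, refits, and
    records the |correlation| of the permuted response with the original,
    the training R²Y and the cross-validated Q².  A robust model's real Q²
    should exceed the whole permuted distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d_y(Y)
    rng = np.random.default_rng(seed)
    full = fit_pls(X, Y2, n_components, x_scaling=x_scaling)
    _, real_q2 = q2_cv(X, Y2, n_components, n_segments, x_scaling)
    rows = np.zeros((n_permutations, 3))
    for i in range(n_permutations):
        perm = rng.permutation(Y2.shape[0])
        Yp = Y2[perm]
        try:
            sub = fit_pls(X, Yp, n_components, x_scaling=x_scaling)
            _, q2p = q2_cv(X, Yp, n_components, n_segments, x_scaling)
            r2p = sub.r2y_cum
        except ValueError:  # permutation produced a degenerate fit
            r2p, q2p = 0.0, 0.0
        rows[i] = (abs(_flat_corr(Yp, Y2)), r2p, q2p)
    return ValidationResult(
        real_r2=full.r2y_cum,
        real_q2=real_q2,
        permuted=rows,
        n_permutations=n_permutations,
        seed=seed,
    )


def predict_left_out(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    seed: int = 0,
    n_repeats: int = 5,
    x_scaling: ScalingSpec = ScalingSpec(center=True, mode="none"),
) -> np.ndarray:
    """Repeatedly predict each sample's response from models that never saw it.

    Samples are partitioned into ``n_folds`` random folds; each fold is
    predicted by a model fitted on the remaining samples, and the whole
    procedure repeats ``n_repeats`` times with fresh random folds.

    Returns an (n_repeats x n_samples) array of held-out predictions;
    summarise per dose group as mean +/- SD across repeats to check that
    predicted dose tracks the true dose.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d_y(Y)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"{n} samples cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_repeats, n))
    for r in range(n_repeats):
        assignment = rng.permutation(np.arange(n) % n_folds)
        for k in range(n_folds):
            mask = assignment == k
            if np.allclose(Y2[~mask], Y2[~mask][0], atol=0):
                raise ValueError(
                    f"fold {k} leaves a constant response in training; cannot fit"
                )
            sub = fit_pls(X[~mask], Y2[~mask], n_components, x_scaling=x_scaling)
            out[r, mask] = np.ravel(_as_2d_y(sub.predict(X[mask]))[:, 0])
    return out
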
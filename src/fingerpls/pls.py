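"""PLS1 regression with mean-centering and cross-validated rank selection.

The model is univariate-response partial least squares fitted by NIPALS
deflation.  Both predictors and response are mean-centered before fitting
(no variance scaling); the regression vector ``b`` is folded back to the
original variable space so that prediction is the affine map
``(x - x_means) @ b + y_mean``.

Model quality is summarised by the usual chemometric figures of merit:
R² (calibration), Q² (external validation), RMSEC, RMSEP and RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "ModelMetrics",
    "CVResult",
    "pls1_fit",
    "pls_predict",
    "metrics",
    "kfold_cv",
    "select_n_latent",
    "save_model",
    "load_model",
]

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """A fitted mean-centered PLS1 model.

    Attributes
    ----------
    x_means, y_mean
        Centering state (column means of the training X, mean of y).
    x_scales
        Per-column scale divisors; unit by default (centering-only
        preprocessing).
    weights
        ``p x A`` matrix W of unit-norm NIPALS weight vectors.
    x_loadings
        ``p x A`` matrix P.
    y_loadings
        Length-``A`` vector q.
    scores
        ``n x A`` training score matrix T (mutually orthogonal columns).
    coef
        Regression vector b in the original (centered) variable space,
        ``b = W (PᵀW)⁻¹ q``.
    n_components
        Number of latent variables A.
    """

    x_means: np.ndarray
    y_mean: float
    x_scales: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    n_components: int
    fitted_values: np.ndarray = field(repr=False, default=None)

    @property
    def n_features(self) -> int:
        return self.x_means.shape[0]


@dataclass
class ModelMetrics:
    """Figures of merit for one PLS model (activity units for the RMSEs)."""

    r_squared: float | None = None
    q_squared: float | None = None
    rmsec: float | None = None
    rmsep: float | None = None
    rmsecv: float | None = None


@dataclass
class CVResult:
    """RMSECV per candidate number of latent variables.

    ``rmsecv[i]`` corresponds to ``candidates[i]`` latent variables; the
    fold assignment (one integer label per sample) and the seed are kept
    so the partition can be reproduced.
    """

    candidates: np.ndarray
    rmsecv: np.ndarray
    fold_assignment: np.ndarray
    k: int
    seed: int


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    return X, y


def pls1_fit(X, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    Uses the NIPALS deflation scheme, which is deterministic for a single
    response (the weight vector of each component is ``Xᵀy`` of the
    deflated matrices, normalised — no iteration or random start is
    needed).

    Raises
    ------
    ValueError
        If ``n_components`` is out of range, or the response has zero
        variance, or X deflates to zero before ``n_components`` components
        are extracted.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 2:
        raise ValueError("at least two samples are required")
    max_lv = min(n - 1, p)
    if not 1 <= n_components <= max_lv:
        raise ValueError(
            f"n_components must be in [1, {max_lv}] for a {n}x{p} matrix, "
            f"got {n_components}"
        )
    y_std = float(np.std(y))
    if y_std <= _EPS:
        raise ValueError("response has zero variance; nothing to regress on")

    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_means
    yc = y - y_mean

    x_norm = float(np.linalg.norm(Xc))
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))

    Xd = Xc.copy()
    yd = yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        w_norm = np.linalg.norm(w)
        if w_norm <= _EPS * max(x_norm, 1.0):
            raise ValueError(
                f"X-y covariance exhausted after {a} latent variables; "
                f"requested {n_components}"
            )
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS * max(x_norm, 1.0) ** 2:
            raise ValueError(
                f"degenerate score vector at latent variable {a + 1}"
            )
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t

    # fold scores back into a single regression vector: b = W (PᵀW)⁻¹ q
    coef = W @ np.linalg.solve(P.T @ W, q)
    fitted = Xc @ coef + y_mean
    return PLSModel(
        x_means=x_means,
        y_mean=y_mean,
        x_scales=np.ones(p),
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        n_components=n_components,
        fitted_values=fitted,
    )


def pls_predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict activities for new samples: ``(x - x_means) @ b + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} variables, "
            f"got {X_new.shape[1]}"
        )
    return (X_new - model.x_means) @ model.coef + model.y_mean


def rmse(y_true, y_pred) -> float:
    """Root mean square error with divisor n (population form)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def metrics(
    y_true,
    y_pred,
    context: str = "calibration",
    reference_mean: float | None = None,
) -> ModelMetrics:
    """Compute the figure of merit appropriate to ``context``.

    ``context`` is one of ``calibration`` (fills R² and RMSEC),
    ``validation`` (Q² and RMSEP) or ``cv`` (RMSECV only).  The
    determination coefficient is ``1 - SS_res / SS_ref`` with
    ``SS_ref = Σ (y - ȳ_ref)²``.  For Q² the reference mean ȳ_ref
    defaults to the mean of ``y_true`` itself, but in a prediction
    setting the calibration-set mean should be passed via
    ``reference_mean`` (the pipeline does this).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    if context not in ("calibration", "validation", "cv"):
        raise ValueError(f"unknown context {context!r}")

    err = rmse(y_true, y_pred)
    if context == "cv":
        return ModelMetrics(rmsecv=err)

    ref = float(np.mean(y_true)) if reference_mean is None else float(reference_mean)
    ss_ref = float(np.sum((y_true - ref) ** 2))
    if ss_ref <= _EPS:
        raise ValueError("reference set has zero variance; R²/Q² undefined")
    det = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_ref
    if context == "calibration":
        return ModelMetrics(r_squared=det, rmsec=err)
    return ModelMetrics(q_squared=det, rmsep=err)


def _kfold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    labels = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for fold, idx in enumerate(np.array_split(perm, k)):
        labels[idx] = fold
    return labels


def max_candidate_lv(n: int, p: int, k: int, cap: int = 15) -> int:
    """Largest number of latent variables the k-fold scan may consider.

    Bounded by the smallest training fold (``n - ceil(n/k)`` samples need
    one more row than latent variables), the variable count, and a fixed
    ceiling that keeps the scan short.
    """
    smallest_train = n - int(np.ceil(n / k))
    return min(cap, smallest_train - 1, p)


def kfold_cv(
    X,
    y,
    n_components_max: int | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of RMSECV over candidate latent-variable counts.

    Folds are a seeded uniform random partition with sizes differing by at
    most one.  For each candidate count the held-out predictions from all
    folds are pooled into a single RMSECV.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    ceiling = max_candidate_lv(n, p, k)
    if ceiling < 1:
        raise ValueError("too few samples per fold to fit any latent variable")
    if n_components_max is None:
        n_components_max = ceiling
    if not 1 <= n_components_max <= ceiling:
        raise ValueError(
            f"n_components_max must be in [1, {ceiling}], got {n_components_max}"
        )

    rng = np.random.default_rng(seed)
    labels = _kfold_assignment(n, k, rng)
    candidates = np.arange(1, n_components_max + 1)
    sq_err = np.zeros(len(candidates))

    for fold in range(k):
        test = labels == fold
        train = ~test
        for i, a in enumerate(candidates):
            model = pls1_fit(X[train], y[train], int(a))
            pred = pls_predict(model, X[test])
            sq_err[i] += float(np.sum((y[test] - pred) ** 2))

    return CVResult(
        candidates=candidates,
        rmsecv=np.sqrt(sq_err / n),
        fold_assignment=labels,
        k=k,
        seed=seed,
    )


def select_n_latent(cv: CVResult) -> int:
    """Number of latent variables minimising RMSECV (ties to the smaller)."""
    if len(cv.rmsecv) == 0:
        raise ValueError("empty cross-validation result")
    return int(cv.candidates[int(np.argmin(cv.rmsecv))])


def save_model(model: PLSModel, path) -> None:
    """Serialise a model to a plain-text key/matrix file (round-trippable)."""
    with open(path, "w") as fh:
        fh.write(f"n_components\t{model.n_components}\n")
        fh.write(f"y_mean\t{model.y_mean!r}\n")
        for name in ("x_means", "x_scales", "y_loadings", "coef"):
            vec = np.asarray(getattr(model, name)).ravel()
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")
        for name in ("weights", "x_loadings", "scores"):
            mat = np.asarray(getattr(model, name))
            fh.write(f"{name}\t{mat.shape[0]}\t{mat.shape[1]}\n")
            for row in mat:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_model(path) -> PLSModel:
    """Inverse of :func:`save_model`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    it = iter(lines)
    fields: dict[str, object] = {}
    n_components = int(next(it).split("\t")[1])
    fields["y_mean"] = float(next(it).split("\t")[1])
    for name in ("x_means", "x_scales", "y_loadings", "coef"):
        parts = next(it).split("\t")
        assert parts[0] == name, f"expected {name}, found {parts[0]}"
        fields[name] = np.array([float(v) for v in parts[1:]])
    for name in ("weights", "x_loadings", "scores"):
        head = next(it).split("\t")
        assert head[0] == name
        rows, cols = int(head[1]), int(head[2])
        mat = np.array(
            [[float(v) for v in next(it).split("\t")] for _ in range(rows)]
        )
        fields[name] = mat.reshape(rows, cols)
    model = PLSModel(
        x_means=fields["x_means"],
        y_mean=fields["y_mean"],
        x_scales=fields["x_scales"],
        weights=fields["weights"],
        x_loadings=fields["x_loadings"],
        y_loadings=fields["y_loadings"],
        scores=fields["scores"],
        coef=fields["coef"],
        n_components=n_components,
    )
    model.fitted_values = model.scores @ model.y_loadings + model.y_mean
    return model
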
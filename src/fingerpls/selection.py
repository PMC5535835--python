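"""Variable ranking (VIP, scaled regression coefficients) and subset scanning.

VIP (variable importance in projection) follows the standard Wold
definition: the importance of variable j in an A-component PLS1 model is

    VIP_j = sqrt( p * Σ_a SS_a (w_ja / ||w_a||)²  /  Σ_a SS_a ),

with SS_a = q_a² t_aᵀt_a the response variance captured by component a.
The scores satisfy the exact identity Σ_j VIP_j² = p.

RC ranks variables by the magnitude of the regression coefficient on the
autoscaled representation, computed as b_j · sd(x_j) from the centered
model — multiplying a coefficient by its variable's spread makes
coefficients of differently-scaled components comparable.

``subset_scan`` walks nested top-k subsets of a ranking (k = 1..20 by
default), refits with per-subset cross-validated latent-variable counts,
and scores each subset by external-validation Q² on a fixed
Kennard–Stone split.  The winning size is the most parsimonious subset
whose Q² is within a tolerance of the maximum (a one-standard-error-style
rule): with a small external validation set, Q² differences along the
post-peak plateau are sampling noise, and a strict argmax would pick an
arbitrary plateau member.  The tolerance is ``parsimony`` times the
residual fraction ``1 - max Q²`` (zero tolerance recovers the strict
argmax; exact ties always resolve to the smaller subset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import (
    kfold_cv,
    max_candidate_lv,
    metrics,
    pls1_fit,
    pls_predict,
    select_n_latent,
)
from .resampling import SplitResult

__all__ = [
    "RankedVariables",
    "SubsetScanResult",
    "vip_scores",
    "scaled_coefficients",
    "subset_scan",
    "select_best_subset",
    "parsimonious_best_k",
    "DEFAULT_PARSIMONY",
]


@dataclass
class RankedVariables:
    """Per-component importance scores and the implied descending rank order."""

    method: str  # "RC" or "VIP"
    scores: np.ndarray
    order: np.ndarray  # component indices, most important first

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


DEFAULT_PARSIMONY = 0.25


def parsimonious_best_k(k_grid: np.ndarray, q_squared: np.ndarray,
                        parsimony: float = DEFAULT_PARSIMONY) -> int:
    """Smallest k whose Q² is within ``parsimony * (1 - max Q²)`` of the max."""
    if parsimony < 0:
        raise ValueError("parsimony must be non-negative")
    mx = float(np.max(q_squared))
    tol = parsimony * (1.0 - mx)
    return int(k_grid[int(np.argmax(q_squared >= mx - tol))])


@dataclass
class SubsetScanResult:
    """Q²/RMSEP over nested top-k subsets of one ranking."""

    method: str
    k_grid: np.ndarray
    q_squared: np.ndarray
    rmsep: np.ndarray
    n_lv: np.ndarray
    order: np.ndarray  # full ranking the subsets are prefixes of
    best_k: int

    def members(self, k: int) -> np.ndarray:
        return self.order[:k]

    @property
    def best_members(self) -> np.ndarray:
        return self.order[: self.best_k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "q_squared": self.q_squared,
                "rmsep": self.rmsep,
                "n_lv": self.n_lv,
                "members": [
                    ";".join(str(i) for i in self.order[:k]) for k in self.k_grid
                ],
            }
        )


def _stable_desc_order(values: np.ndarray) -> np.ndarray:
    # descending, ties broken toward the lower component index
    return np.argsort(-values, kind="stable")


def vip_scores(model) -> RankedVariables:
    """Wold VIP scores of a fitted PLS1 model (Σ VIP² = p exactly)."""
    W = model.weights
    T = model.scores
    q = model.y_loadings
    p = W.shape[0]
    ss = q**2 * np.einsum("ia,ia->a", T, T)  # per-component explained y-SS
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    w_norm2 = np.sum(W**2, axis=0)
    vip = np.sqrt(p * (W**2 / w_norm2) @ ss / total)
    return RankedVariables(method="VIP", scores=vip, order=_stable_desc_order(vip))


def scaled_coefficients(model, x_sds) -> RankedVariables:
    """Regression coefficients rescaled by the per-variable SD, ranked by |RC|."""
    x_sds = np.asarray(x_sds, dtype=float).ravel()
    if x_sds.shape[0] != model.n_features:
        raise ValueError(
            f"{x_sds.shape[0]} SDs supplied for {model.n_features} variables"
        )
    if np.any(x_sds <= 0):
        j = int(np.flatnonzero(x_sds <= 0)[0])
        raise ValueError(f"variable {j} has zero variance; RC undefined")
    rc = model.coef * x_sds
    return RankedVariables(
        method="RC", scores=rc, order=_stable_desc_order(np.abs(rc))
    )


def subset_scan(
    X,
    y,
    ranking: RankedVariables,
    split: SplitResult,
    k_max: int = 20,
    cv_folds: int = 10,
    seed: int = 0,
    parsimony: float = DEFAULT_PARSIMONY,
) -> SubsetScanResult:
    """Score nested top-k subsets of a ranking by external-validation Q².

    For each k in 1..k_max the predictor matrix is restricted to the
    ranking's top k components, the latent-variable count is re-selected
    by ``cv_folds``-fold cross-validation on the calibration rows (capped
    at k), the model is refitted on the calibration rows and Q²/RMSEP are
    computed on the validation rows (Q² referenced to the calibration
    mean).  The split is fixed before the scan so Q² values are
    comparable across k.  ``best_k`` is the parsimonious winner (see
    :func:`parsimonious_best_k`); set ``parsimony=0`` for a strict
    argmax.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if not 1 <= k_max <= p:
        raise ValueError(f"k_max must be in [1, {p}], got {k_max}")
    cal, val = split.calibration_indices, split.validation_indices
    if val.size < 2:
        raise ValueError("validation set too small to compute Q²")

    ks = np.arange(1, k_max + 1)
    q2 = np.empty(len(ks))
    rmsep = np.empty(len(ks))
    nlv = np.empty(len(ks), dtype=int)
    for i, k in enumerate(ks):
        cols = ranking.top(int(k))
        Xk_cal, Xk_val = X[np.ix_(cal, cols)], X[np.ix_(val, cols)]
        ceiling = max_candidate_lv(cal.size, int(k), cv_folds)
        cv = kfold_cv(Xk_cal, y[cal], n_components_max=ceiling, k=cv_folds, seed=seed)
        a = select_n_latent(cv)
        model = pls1_fit(Xk_cal, y[cal], a)
        pred = pls_predict(model, Xk_val)
        m = metrics(y[val], pred, context="validation", reference_mean=model.y_mean)
        q2[i], rmsep[i], nlv[i] = m.q_squared, m.rmsep, a

    best_k = parsimonious_best_k(ks, q2, parsimony)
    return SubsetScanResult(
        method=ranking.method,
        k_grid=ks,
        q_squared=q2,
        rmsep=rmsep,
        n_lv=nlv,
        order=ranking.order.copy(),
        best_k=best_k,
    )


def select_best_subset(scan: SubsetScanResult) -> np.ndarray:
    """Component indices of the winning subset (parsimonious max-Q², ties to smaller k)."""
    if scan.k_grid.size == 0:
        raise ValueError("empty subset scan")
    return scan.best_members
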
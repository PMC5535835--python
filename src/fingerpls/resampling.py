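"""Sample-set partitioning and Monte-Carlo cross-validation outlier screening.

Two resampling procedures used around the PLS1 calibration:

* Kennard–Stone partitioning — a deterministic max–min Euclidean-distance
  design that picks a representative calibration subset (80% by default)
  and leaves the remainder as the external validation set;
* MCCV outlier screening — many random train/test splits; each sample
  accumulates a distribution of held-out prediction residuals, summarised
  per sample by the mean absolute residual and the SD of signed
  residuals.  Samples whose statistic exceeds 2.5x the across-sample
  average on either axis are flagged (four-zone rule: normal / X / Y / XY).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import kfold_cv, pls1_fit, pls_predict, select_n_latent

__all__ = [
    "SplitResult",
    "MccvConfig",
    "MccvResult",
    "kennard_stone_split",
    "mccv_scan",
    "classify_outliers",
]

ZONES = ("normal", "X", "Y", "XY")


@dataclass
class SplitResult:
    """Calibration/validation index sets from Kennard–Stone partitioning."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        self.calibration_indices = np.asarray(self.calibration_indices, dtype=int)
        self.validation_indices = np.asarray(self.validation_indices, dtype=int)


@dataclass
class MccvConfig:
    """Settings for the Monte-Carlo cross-validation outlier scan.

    ``n_lv`` is either a fixed latent-variable count reused for every
    split, or ``"cv"`` to select it once on the full data by 10-fold
    cross-validation before the scan starts.  ``min_holdout`` is the
    smallest acceptable number of held-out predictions per sample.
    """

    n_iterations: int = 2000
    train_fraction: float = 0.8
    n_lv: int | str = "cv"
    threshold_multiplier: float = 2.5
    min_holdout: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if isinstance(self.n_lv, str) and self.n_lv != "cv":
            raise ValueError("n_lv must be an integer or 'cv'")


@dataclass
class MccvResult:
    """Per-sample held-out residual summaries and outlier flags."""

    sample_index: np.ndarray
    mean_abs_residual: np.ndarray
    mean_signed_residual: np.ndarray
    residual_sd: np.ndarray
    holdout_count: np.ndarray
    n_lv: int
    config: MccvConfig
    x_threshold: float | None = None
    y_threshold: float | None = None
    zones: np.ndarray | None = None  # strings from ZONES, set by classify_outliers

    @property
    def outlier_flags(self) -> np.ndarray:
        if self.zones is None:
            raise ValueError("run classify_outliers first")
        return self.zones != "normal"

    def to_frame(self) -> pd.DataFrame:
        """Per-sample statistics (plot-ready for a four-zone scatter)."""
        df = pd.DataFrame(
            {
                "sample_index": self.sample_index,
                "mean_abs_residual": self.mean_abs_residual,
                "mean_signed_residual": self.mean_signed_residual,
                "residual_sd": self.residual_sd,
                "holdout_count": self.holdout_count,
            }
        )
        if self.zones is not None:
            df["zone"] = self.zones
        return df


def kennard_stone_split(X, fraction: float = 0.8) -> SplitResult:
    """Deterministic Kennard–Stone calibration/validation partition.

    The first two calibration picks are the pair of samples at maximal
    Euclidean distance; every subsequent pick maximises its minimum
    distance to the already-selected set.  Ties are broken toward the
    lower sample index.  The calibration set has ``floor(fraction * n)``
    members; the rest form the validation set.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three samples to partition")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_cal = int(np.floor(fraction * n))
    if n_cal < 2:
        raise ValueError(f"calibration set of {n_cal} samples is too small")

    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    # farthest pair; np.argmax returns the first (lowest-index) maximiser
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    selected = [min(i, j), max(i, j)]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        np.minimum(min_d2, d2[nxt], out=min_d2)
        min_d2[nxt] = -np.inf

    cal = np.sort(np.array(selected, dtype=int))
    val = np.setdiff1d(np.arange(n), cal)
    return SplitResult(calibration_indices=cal, validation_indices=val, fraction=fraction)


def mccv_scan(X, y, config: MccvConfig | None = None) -> MccvResult:
    """Monte-Carlo cross-validation residual scan.

    For each of ``config.n_iterations`` seeded random splits, a PLS1
    model is fitted on a ``train_fraction`` subset and signed residuals
    ``ŷ − y`` are recorded for the held-out samples.  Per sample, the
    mean absolute residual, the mean signed residual and the SD of
    signed residuals are returned together with the holdout counts.

    Raises
    ------
    ValueError
        If the expected or realised holdout coverage of any sample falls
        below ``config.min_holdout`` (the starved sample is named).
    """
    if config is None:
        config = MccvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_train = int(np.floor(config.train_fraction * n))
    n_test = n - n_train
    if n_train < 2 or n_test < 1:
        raise ValueError(f"train fraction {config.train_fraction} leaves an empty set")
    expected = config.n_iterations * n_test / n
    if expected < config.min_holdout:
        raise ValueError(
            f"expected holdout coverage {expected:.0f} per sample is below "
            f"the configured minimum {config.min_holdout}; increase "
            "n_iterations or lower train_fraction"
        )

    if config.n_lv == "cv":
        n_lv = select_n_latent(kfold_cv(X, y, k=min(10, n_train), seed=config.seed))
    else:
        n_lv = int(config.n_lv)
    n_lv = min(n_lv, n_train - 1, p)

    rng = np.random.default_rng(config.seed)
    res_sum = np.zeros(n)
    res_abs_sum = np.zeros(n)
    res_sq_sum = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(config.n_iterations):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = pls1_fit(X[train], y[train], n_lv)
        resid = pls_predict(model, X[test]) - y[test]
        res_sum[test] += resid
        res_abs_sum[test] += np.abs(resid)
        res_sq_sum[test] += resid**2
        counts[test] += 1

    starved = np.flatnonzero(counts < config.min_holdout)
    if starved.size:
        raise ValueError(
            f"sample {starved[0]} was held out only {counts[starved[0]]} "
            f"times (minimum {config.min_holdout})"
        )
    mean_signed = res_sum / counts
    mean_abs = res_abs_sum / counts
    # SD of signed residuals about their per-sample mean (ddof=1)
    var = (res_sq_sum - counts * mean_signed**2) / (counts - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return MccvResult(
        sample_index=np.arange(n),
        mean_abs_residual=mean_abs,
        mean_signed_residual=mean_signed,
        residual_sd=sd,
        holdout_count=counts,
        n_lv=n_lv,
        config=config,
    )


def classify_outliers(
    result: MccvResult,
    multiplier: float | None = None,
    use_signed_mean: bool = False,
) -> MccvResult:
    """Apply the four-zone 2.5x rule to an MCCV scan.

    The X-axis statistic is the per-sample mean residual (absolute by
    default, signed magnitude behind ``use_signed_mean``); the Y-axis
    statistic is the per-sample residual SD.  Thresholds are
    ``multiplier`` times the across-sample arithmetic mean of each
    statistic; a sample exceeding only the X threshold lands in zone
    ``X``, only the Y threshold in zone ``Y``, both in ``XY``.  Returns
    the result with thresholds and zones filled in.
    """
    if multiplier is None:
        multiplier = result.config.threshold_multiplier
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    x_stat = (
        np.abs(result.mean_signed_residual)
        if use_signed_mean
        else result.mean_abs_residual
    )
    y_stat = result.residual_sd
    x_thr = multiplier * float(np.mean(x_stat))
    y_thr = multiplier * float(np.mean(y_stat))
    over_x = x_stat > x_thr
    over_y = y_stat > y_thr
    zones = np.where(
        over_x & over_y, "XY", np.where(over_x, "X", np.where(over_y, "Y", "normal"))
    )
    result.x_threshold = x_thr
    result.y_threshold = y_thr
    result.zones = zones.astype(object)
    return result
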
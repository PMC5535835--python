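"""End-to-end composition–activity workflow.

Stage order mirrors the analysis the package implements:

1. load (or synthesise) the relative-concentration matrix X and the
   quercetin-equivalent activity vector y;
2. Kennard–Stone 80/20 partition, 10-fold CV latent-variable selection,
   full PLS1 model with R²/Q²/RMSEC/RMSEP/RMSECV;
3. MCCV outlier scan (2000 random 80% splits by default) and the
   four-zone 2.5x rule; flagged samples are removed in a single pass;
4. Kennard–Stone re-partition of the reduced data and a refit;
5. VIP and RC rankings from the post-outlier model, nested top-k subset
   scans (k = 1..20), and refits on the best VIP subset, best RC subset
   and their intersection ("common" components).

The report therefore carries five model-summary rows: full,
post-outlier, RC-selected, VIP-selected and common.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatography, dpph
from .pls import kfold_cv, max_candidate_lv, metrics, pls1_fit, pls_predict, select_n_latent
from .resampling import MccvConfig, classify_outliers, kennard_stone_split, mccv_scan
from .selection import scaled_coefficients, select_best_subset, subset_scan, vip_scores
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "config_from_dict"]

log = logging.getLogger("fingerpls")

MODEL_ROWS = ("full", "post_outlier", "rc_selected", "vip_selected", "common")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``synthetic`` is set (a :class:`SyntheticConfig`) or
    ``peak_table_path`` plus one of ``activity_path`` /
    ``assay_plate_path`` point at input files.  All stage randomness is
    derived from ``seed``.
    """

    synthetic: SyntheticConfig | None = None
    peak_table_path: str | None = None
    internal_standard_id: str | None = None
    activity_path: str | None = None
    assay_plate_path: str | None = None
    split_fraction: float = 0.8
    cv_folds: int = 10
    mccv: MccvConfig = field(default_factory=MccvConfig)
    k_max: int = 20
    methods: tuple[str, ...] = ("RC", "VIP", "common")
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and self.peak_table_path is None:
            raise ValueError("configure either synthetic generation or input paths")
        bad = set(self.methods) - {"RC", "VIP", "common"}
        if bad:
            raise ValueError(f"unknown ranking methods {sorted(bad)}")
        if "common" in self.methods and not {"RC", "VIP"} <= set(self.methods):
            raise ValueError("'common' requires both 'RC' and 'VIP'")


@dataclass
class PipelineReport:
    """Stage outputs of one run."""

    models: pd.DataFrame  # one row per model summary
    outliers: pd.DataFrame  # per-sample MCCV statistics + zones
    selected: dict[str, list[str]]  # method -> component ids
    scans: dict[str, pd.DataFrame]  # method -> subset-scan table
    seed: int
    removed_sample_ids: list[str]

    def to_text(self) -> str:
        lines = [f"fingerpls pipeline report (seed={self.seed})", ""]
        lines.append(self.models.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        flagged = self.outliers[self.outliers["zone"] != "normal"]
        lines.append(f"outliers removed ({len(flagged)}): "
                     + (", ".join(flagged["sample_id"]) if len(flagged) else "none"))
        for method, ids in self.selected.items():
            lines.append(f"{method} selected components ({len(ids)}): " + ", ".join(ids))
        lines.append("")
        return "\n".join(lines)


def _load_inputs(config: PipelineConfig):
    """Return (X DataFrame, y ActivityVector) per the configured source."""
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        X = ds.peak_table.to_frame()
        return X, ds.activity, ds
    table = chromatography.read_peak_table(
        config.peak_table_path, internal_standard_id=config.internal_standard_id
    )
    if config.internal_standard_id is not None:
        X = chromatography.normalize_to_internal_standard(table)
    else:
        X = table.to_frame()
    if config.activity_path is not None:
        activity = dpph.read_activity(config.activity_path)
    elif config.assay_plate_path is not None:
        plate = dpph.read_assay_plate(config.assay_plate_path)
        activity = dpph.plate_to_activity(plate)
    else:
        raise ValueError("file mode needs activity_path or assay_plate_path")
    if list(X.index) != list(activity.sample_ids):
        raise ValueError("peak table and activity sample ids disagree")
    return X, activity, None


def _model_row(X, y, fraction, cv_folds, seed):
    """KS split + CV-selected PLS1 fit; returns (summary dict, split, model)."""
    split = kennard_stone_split(X, fraction)
    cal, val = split.calibration_indices, split.validation_indices
    ceiling = max_candidate_lv(cal.size, X.shape[1], cv_folds)
    cv = kfold_cv(X[cal], y[cal], n_components_max=ceiling, k=cv_folds, seed=seed)
    n_lv = select_n_latent(cv)
    model = pls1_fit(X[cal], y[cal], n_lv)
    cal_m = metrics(y[cal], model.fitted_values, context="calibration")
    val_m = metrics(
        y[val], pls_predict(model, X[val]),
        context="validation", reference_mean=model.y_mean,
    )
    row = {
        "n_samples": X.shape[0],
        "n_variables": X.shape[1],
        "n_lv": n_lv,
        "r_squared": cal_m.r_squared,
        "q_squared": val_m.q_squared,
        "rmsec": cal_m.rmsec,
        "rmsep": val_m.rmsep,
        "rmsecv": float(cv.rmsecv[int(np.argmin(cv.rmsecv))]),
    }
    return row, split, model


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and return (and optionally write) the report."""
    seed = config.seed
    X_df, activity, _ds = _load_inputs(config)
    X = X_df.to_numpy(dtype=float)
    y = activity.activity
    sample_ids = list(X_df.index)
    component_ids = list(X_df.columns)
    log.info("stage=load seed=%d shape=%dx%d", seed, *X.shape)

    rows: dict[str, dict] = {}
    rows["full"], _, _ = _model_row(X, y, config.split_fraction, config.cv_folds, seed)
    log.info("stage=full_model nLV=%d R2=%.4f", rows["full"]["n_lv"], rows["full"]["r_squared"])

    mccv_cfg = dataclasses.replace(config.mccv, seed=seed + 1)
    scan = mccv_scan(X, y, mccv_cfg)
    scan = classify_outliers(scan)
    outlier_df = scan.to_frame()
    outlier_df.insert(0, "sample_id", sample_ids)
    keep = ~scan.outlier_flags
    removed_ids = [s for s, k in zip(sample_ids, keep) if not k]
    log.info("stage=mccv iterations=%d flagged=%d", mccv_cfg.n_iterations, len(removed_ids))

    Xr, yr = X[keep], y[keep]
    rows["post_outlier"], split_r, model_r = _model_row(
        Xr, yr, config.split_fraction, config.cv_folds, seed
    )
    log.info("stage=post_outlier shape=%dx%d nLV=%d", *Xr.shape, rows["post_outlier"]["n_lv"])

    selected: dict[str, list[str]] = {}
    scans: dict[str, pd.DataFrame] = {}
    best: dict[str, np.ndarray] = {}
    cal = split_r.calibration_indices
    if "RC" in config.methods:
        rc = scaled_coefficients(model_r, Xr[cal].std(axis=0, ddof=1))
        rc_scan = subset_scan(Xr, yr, rc, split_r, k_max=config.k_max,
                              cv_folds=config.cv_folds, seed=seed)
        best["RC"] = select_best_subset(rc_scan)
        scans["RC"] = rc_scan.to_frame()
    if "VIP" in config.methods:
        vip = vip_scores(model_r)
        vip_scan = subset_scan(Xr, yr, vip, split_r, k_max=config.k_max,
                               cv_folds=config.cv_folds, seed=seed)
        best["VIP"] = select_best_subset(vip_scan)
        scans["VIP"] = vip_scan.to_frame()

    def _selected_row(cols: np.ndarray) -> dict:
        Xk_cal = Xr[np.ix_(cal, cols)]
        ceiling = max_candidate_lv(cal.size, cols.size, config.cv_folds)
        cv = kfold_cv(Xk_cal, yr[cal], n_components_max=ceiling,
                      k=config.cv_folds, seed=seed)
        n_lv = select_n_latent(cv)
        model = pls1_fit(Xk_cal, yr[cal], n_lv)
        val = split_r.validation_indices
        cal_m = metrics(yr[cal], model.fitted_values, context="calibration")
        val_m = metrics(
            yr[val], pls_predict(model, Xr[np.ix_(val, cols)]),
            context="validation", reference_mean=model.y_mean,
        )
        return {
            "n_samples": Xr.shape[0],
            "n_variables": int(cols.size),
            "n_lv": n_lv,
            "r_squared": cal_m.r_squared,
            "q_squared": val_m.q_squared,
            "rmsec": cal_m.rmsec,
            "rmsep": val_m.rmsep,
            "rmsecv": float(cv.rmsecv[int(np.argmin(cv.rmsecv))]),
        }

    if "RC" in best:
        rows["rc_selected"] = _selected_row(best["RC"])
        selected["RC"] = [component_ids[i] for i in best["RC"]]
    if "VIP" in best:
        rows["vip_selected"] = _selected_row(best["VIP"])
        selected["VIP"] = [component_ids[i] for i in best["VIP"]]
    if "common" in config.methods and "RC" in best and "VIP" in best:
        # intersection, kept in VIP rank order
        rc_set = set(best["RC"].tolist())
        common = np.array([i for i in best["VIP"] if i in rc_set], dtype=int)
        if common.size >= 1:
            rows["common"] = _selected_row(common)
        else:
            rows["common"] = {k: np.nan for k in rows["full"]}
            rows["common"].update(n_samples=Xr.shape[0], n_variables=0)
        selected["common"] = [component_ids[i] for i in common]

    order = [r for r in MODEL_ROWS if r in rows]
    models = pd.DataFrame([rows[r] for r in order], index=order)
    models.index.name = "model"

    report = PipelineReport(
        models=models,
        outliers=outlier_df,
        selected=selected,
        scans=scans,
        seed=seed,
        removed_sample_ids=removed_ids,
    )
    if config.output_dir is not None:
        _write_report(report, config, X_df, activity)
    return report


def _write_report(report: PipelineReport, config: PipelineConfig,
                  X_df: pd.DataFrame, activity) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.models.to_csv(out / "model_summaries.csv")
    report.outliers.to_csv(out / "mccv_statistics.csv", index=False)
    for method, df in report.scans.items():
        df.to_csv(out / f"subset_scan_{method.lower()}.csv", index=False)
    with open(out / "selected_components.txt", "w") as fh:
        for method, ids in report.selected.items():
            fh.write(f"{method}\t" + "\t".join(ids) + "\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(report.to_text())
    if config.synthetic is not None:
        X_df.to_csv(out / "peak_table.csv")
        dpph.write_activity(activity, out / "activity.csv")
    log.info("stage=write out=%s", out)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed (YAML) mapping."""
    raw = dict(raw)
    synth = raw.pop("synthetic", None)
    if synth is not None:
        if "informative_indices" in synth:
            synth["informative_indices"] = tuple(synth["informative_indices"])
        if "effect_sizes" in synth and synth["effect_sizes"] is not None:
            synth["effect_sizes"] = tuple(synth["effect_sizes"])
        if "outlier_spec" in synth:
            synth["outlier_spec"] = tuple(
                (int(s), str(d), float(m)) for s, d, m in synth["outlier_spec"]
            )
        if "activity_range" in synth:
            synth["activity_range"] = tuple(synth["activity_range"])
        synth = SyntheticConfig(**synth)
    mccv = raw.pop("mccv", None)
    mccv = MccvConfig(**mccv) if mccv is not None else MccvConfig()
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return PipelineConfig(synthetic=synth, mccv=mccv, **raw)
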
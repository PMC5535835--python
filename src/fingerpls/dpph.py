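"""DPPH radical-scavenging quantitation.

The DPPH radical absorbs at 517 nm; antioxidants bleach it, so sample
absorbance falls as scavenging activity rises.  Activity is expressed as
the quercetin-equivalent concentration (µg/mL QE) read off a linear
standard curve fitted to a quercetin dilution series (5–50 µg/mL by
default).  Replicate sample absorbances are averaged on the absorbance
scale before conversion and their spread is propagated through the curve
slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayPlate",
    "ActivityVector",
    "fit_standard_curve",
    "quercetin_equivalent",
    "plate_to_activity",
    "read_assay_plate",
    "write_assay_plate",
    "read_activity",
    "write_activity",
]

DEFAULT_CONCENTRATION_GRID = np.arange(5.0, 55.0, 5.0)  # µg/mL, 5–50 step 5


@dataclass
class StandardCurve:
    """Linear absorbance-vs-concentration calibration.

    ``slope`` is in AU per (µg/mL) and is negative for a bleaching assay;
    a non-negative fitted slope triggers a warning rather than an error so
    that pathological plates can still be inspected.
    """

    slope: float
    intercept: float
    r_squared: float
    concentration_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONCENTRATION_GRID.copy()
    )


@dataclass
class AssayPlate:
    """Absorbance readings at 517 nm: sample replicates plus standard wells.

    ``absorbances`` maps each sample id to its replicate readings;
    ``standards`` is a list of (concentration µg/mL, absorbance AU) wells.
    """

    sample_ids: list[str]
    absorbances: dict[str, np.ndarray]
    standards: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.absorbances = {
            str(k): np.asarray(v, dtype=float).ravel()
            for k, v in self.absorbances.items()
        }
        missing = [s for s in self.sample_ids if s not in self.absorbances]
        if missing:
            raise ValueError(f"no absorbance wells for samples {missing}")
        if len({c for c, _ in self.standards}) < 2:
            raise ValueError("at least two distinct standard concentrations needed")
        for s, a in self.absorbances.items():
            if np.any(a < 0):
                raise ValueError(f"negative absorbance for sample {s!r}")


@dataclass
class ActivityVector:
    """Per-sample scavenging activity in quercetin equivalents (µg/mL)."""

    sample_ids: list[str]
    activity: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.activity = np.asarray(self.activity, dtype=float).ravel()
        if len(self.sample_ids) != self.activity.shape[0]:
            raise ValueError("sample ids and activities differ in length")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float).ravel()
            if self.replicate_sd.shape != self.activity.shape:
                raise ValueError("replicate SDs and activities differ in length")
            if np.any(self.replicate_sd < 0):
                raise ValueError("replicate SD must be non-negative")


def fit_standard_curve(standards) -> StandardCurve:
    """Ordinary least-squares line of absorbance on concentration.

    ``standards`` is an iterable of (concentration, absorbance) pairs.
    Warns (without failing) when the fitted slope is non-negative, which
    contradicts the bleaching chemistry of the assay.
    """
    pairs = [(float(c), float(a)) for c, a in standards]
    conc = np.array([c for c, _ in pairs])
    absb = np.array([a for _, a in pairs])
    if np.unique(conc).size < 2:
        raise ValueError(
            "standard-curve fit needs at least two distinct concentrations"
        )
    fit = stats.linregress(conc, absb)
    if fit.slope >= 0:
        warnings.warn(
            "standard-curve slope is non-negative; DPPH absorbance should "
            "decrease with antioxidant concentration",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        concentration_grid=np.unique(conc),
    )


def quercetin_equivalent(absorbance, curve: StandardCurve):
    """Convert absorbance(s) to µg/mL quercetin equivalents.

    Scalar in, scalar out; for an array of replicate readings the mean
    absorbance is converted and the replicate SD is propagated as
    ``sd(absorbance) / |slope|``, returning ``(QE, sd_QE)``.
    """
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope; conversion undefined")
    a = np.asarray(absorbance, dtype=float)
    if a.ndim == 0:
        return float((a - curve.intercept) / curve.slope)
    qe = float((a.mean() - curve.intercept) / curve.slope)
    sd = float(a.std(ddof=1) / abs(curve.slope)) if a.size > 1 else 0.0
    return qe, sd


def plate_to_activity(plate: AssayPlate, curve: StandardCurve | None = None) -> ActivityVector:
    """Quantify a whole plate: fit the curve (unless given), convert samples."""
    if curve is None:
        curve = fit_standard_curve(plate.standards)
    activity = np.empty(len(plate.sample_ids))
    sd = np.empty(len(plate.sample_ids))
    for i, s in enumerate(plate.sample_ids):
        activity[i], sd[i] = quercetin_equivalent(plate.absorbances[s], curve)
    return ActivityVector(
        sample_ids=list(plate.sample_ids), activity=activity, replicate_sd=sd
    )


def write_assay_plate(plate: AssayPlate, path) -> None:
    """Write wells as CSV: well_type, id_or_concentration, absorbance."""
    rows = []
    for c, a in plate.standards:
        rows.append(("standard", repr(c), a))
    for s in plate.sample_ids:
        for a in plate.absorbances[s]:
            rows.append(("sample", s, a))
    pd.DataFrame(
        rows, columns=["well_type", "id_or_concentration", "absorbance"]
    ).to_csv(path, index=False)


def read_assay_plate(path) -> AssayPlate:
    df = pd.read_csv(path, dtype={"id_or_concentration": str})
    for col in ("well_type", "id_or_concentration", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"assay plate {path} lacks column {col!r}")
    std = df[df["well_type"] == "standard"]
    smp = df[df["well_type"] == "sample"]
    standards = [
        (float(c), float(a))
        for c, a in zip(std["id_or_concentration"], std["absorbance"])
    ]
    sample_ids = list(dict.fromkeys(smp["id_or_concentration"]))
    absorbances = {
        s: smp.loc[smp["id_or_concentration"] == s, "absorbance"].to_numpy()
        for s in sample_ids
    }
    return AssayPlate(sample_ids=sample_ids, absorbances=absorbances, standards=standards)


def write_activity(activity: ActivityVector, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": activity.sample_ids,
            "activity_ugml_qe": activity.activity,
        }
    )
    if activity.replicate_sd is not None:
        df["replicate_sd_ugml"] = activity.replicate_sd
    df.to_csv(path, index=False)


def read_activity(path) -> ActivityVector:
    df = pd.read_csv(path)
    for col in ("sample_id", "activity_ugml_qe"):
        if col not in df.columns:
            raise ValueError(f"activity table {path} lacks column {col!r}")
    sd = (
        df["replicate_sd_ugml"].to_numpy()
        if "replicate_sd_ugml" in df.columns
        else None
    )
    return ActivityVector(
        sample_ids=list(df["sample_id"].astype(str)),
        activity=df["activity_ugml_qe"].to_numpy(),
        replicate_sd=sd,
    )
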
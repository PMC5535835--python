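"""Peak-table I/O and GC-MS quantitation conventions.

Two conventions from quantitative fingerprint work are implemented here:

* internal-standard normalisation — each component's peak area is divided
  by the area of a spiked reference compound (undecane in the motivating
  assay) integrated on the same total ion chromatogram, giving unitless
  relative concentrations that are invariant to per-injection scaling;
* temperature-programmed retention indices — the van den Dool–Kratz
  linear interpolation between the bracketing n-alkanes of a C8–C20
  ladder.

Peak tables travel as CSV with a mandatory sample-id column, one column
per component, and an optional retention-time header row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "AlkaneLadder",
    "read_peak_table",
    "write_peak_table",
    "normalize_to_internal_standard",
    "retention_index",
    "read_alkane_ladder",
    "write_alkane_ladder",
]

SAMPLE_ID_COLUMN = "sample_id"
_RT_ROW_ID = "__retention_time__"


@dataclass
class PeakTable:
    """Sample x component peak areas with optional retention times.

    ``areas`` is an ``n_samples x n_components`` array of non-negative
    detector counts.  ``internal_standard_id`` names the column used by
    :func:`normalize_to_internal_standard`; it may be ``None`` for tables
    that are already normalised.
    """

    sample_ids: list[str]
    component_ids: list[str]
    areas: np.ndarray
    retention_times: np.ndarray | None = None
    internal_standard_id: str | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.component_ids = [str(c) for c in self.component_ids]
        n, p = self.areas.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if p != len(self.component_ids):
            raise ValueError(
                f"{len(self.component_ids)} component ids for {p} matrix columns"
            )
        if len(set(self.component_ids)) != p:
            raise ValueError("duplicate component ids")
        if not np.all(np.isfinite(self.areas)):
            raise ValueError("peak areas contain missing or non-finite values")
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be non-negative")
        if self.retention_times is not None:
            self.retention_times = np.asarray(self.retention_times, dtype=float)
            if self.retention_times.shape != (p,):
                raise ValueError("one retention time per component required")
        if (
            self.internal_standard_id is not None
            and self.internal_standard_id not in self.component_ids
        ):
            raise ValueError(
                f"internal-standard column {self.internal_standard_id!r} "
                "not present in the table"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.areas.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.areas, index=self.sample_ids, columns=self.component_ids
        )
        df.index.name = SAMPLE_ID_COLUMN
        return df


@dataclass
class AlkaneLadder:
    """Retention times of the n-alkane standards (carbon numbers 8..20)."""

    carbon_numbers: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_numbers = np.asarray(self.carbon_numbers, dtype=int)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        if self.carbon_numbers.shape != self.retention_times.shape:
            raise ValueError("carbon numbers and retention times differ in length")
        if len(self.carbon_numbers) < 2:
            raise ValueError("a ladder needs at least two alkanes")
        if np.any(np.diff(self.carbon_numbers) <= 0):
            raise ValueError("carbon numbers must be strictly increasing")
        if np.any(np.diff(self.retention_times) <= 0):
            raise ValueError("alkane retention times must be strictly increasing")


def write_peak_table(table: PeakTable, path) -> None:
    """Write a peak table as CSV (sample-id column first, '.' decimals).

    When the table carries retention times they are stored as an extra
    first data row with the reserved sample id ``__retention_time__``.
    """
    df = table.to_frame()
    if table.retention_times is not None:
        rt = pd.DataFrame(
            [table.retention_times], index=[_RT_ROW_ID], columns=table.component_ids
        )
        rt.index.name = SAMPLE_ID_COLUMN
        df = pd.concat([rt, df])
    df.to_csv(path)


def read_peak_table(path, internal_standard_id: str | None = None) -> PeakTable:
    """Read a CSV peak table written by :func:`write_peak_table`.

    Raises a descriptive error for malformed rows, duplicate component
    ids, non-numeric areas, or (when ``internal_standard_id`` is given)
    an absent internal-standard column.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed peak table {path}: {exc}") from exc
    # pandas mangles duplicate header names (c1, c1.1); check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate component ids in {path}: {dupes}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric peak area in {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing peak areas in {path} for samples {bad}")
    retention_times = None
    if _RT_ROW_ID in df.index:
        retention_times = df.loc[_RT_ROW_ID].to_numpy()
        df = df.drop(index=_RT_ROW_ID)
    if internal_standard_id is not None and internal_standard_id not in df.columns:
        raise ValueError(
            f"peak table {path} lacks the internal-standard column "
            f"{internal_standard_id!r}"
        )
    return PeakTable(
        sample_ids=list(df.index.astype(str)),
        component_ids=list(df.columns.astype(str)),
        areas=df.to_numpy(),
        retention_times=retention_times,
        internal_standard_id=internal_standard_id,
    )


def normalize_to_internal_standard(
    table: PeakTable, drop_internal_standard: bool = True
) -> pd.DataFrame:
    """Relative concentrations: each area divided by the internal-standard area.

    Entry (i, j) becomes ``area(i, j) / area(i, IS)``; the internal-standard
    column itself is identically 1 and is dropped by default, since a
    constant column carries no information for downstream modelling.

    Raises
    ------
    ValueError
        If no internal standard is configured or its area is not strictly
        positive in every sample (the offending sample is named).
    """
    if table.internal_standard_id is None:
        raise ValueError("peak table has no internal-standard column configured")
    j = table.component_ids.index(table.internal_standard_id)
    is_areas = table.areas[:, j]
    bad = np.flatnonzero(is_areas <= 0)
    if bad.size:
        raise ValueError(
            f"internal-standard area is not positive for sample "
            f"{table.sample_ids[bad[0]]!r}"
        )
    rel = table.areas / is_areas[:, None]
    df = pd.DataFrame(rel, index=table.sample_ids, columns=table.component_ids)
    df.index.name = SAMPLE_ID_COLUMN
    if drop_internal_standard:
        df = df.drop(columns=table.internal_standard_id)
    return df


def retention_index(t_x: float, ladder: AlkaneLadder) -> float:
    """Temperature-programmed (van den Dool–Kratz) retention index.

    ``RI = 100 * (n + (t_x - t_n) / (t_{n+1} - t_n))`` where the alkanes
    with carbon numbers n and n+1 bracket the peak.  No extrapolation:
    peaks eluting outside the ladder span raise an error.
    """
    t = float(t_x)
    times = ladder.retention_times
    carbons = ladder.carbon_numbers
    if not times[0] <= t <= times[-1]:
        raise ValueError(
            f"retention time {t} min outside the alkane ladder span "
            f"[{times[0]}, {times[-1]}] min"
        )
    # rightmost alkane with time <= t (bracketing segment below)
    i = int(np.searchsorted(times, t, side="right")) - 1
    i = min(i, len(times) - 2)
    frac = (t - times[i]) / (times[i + 1] - times[i])
    return 100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i]))


def write_alkane_ladder(ladder: AlkaneLadder, path) -> None:
    pd.DataFrame(
        {
            "carbon_number": ladder.carbon_numbers,
            "retention_time_min": ladder.retention_times,
        }
    ).to_csv(path, index=False)


def read_alkane_ladder(path) -> AlkaneLadder:
    df = pd.read_csv(path)
    for col in ("carbon_number", "retention_time_min"):
        if col not in df.columns:
            raise ValueError(f"alkane ladder {path} lacks column {col!r}")
    return AlkaneLadder(
        carbon_numbers=df["carbon_number"].to_numpy(),
        retention_times=df["retention_time_min"].to_numpy(),
    )
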
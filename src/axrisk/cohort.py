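"""Cohort data model and CSV input/output.

A cohort is one record per patient: binary axillary lymph-node (LN) status,
clinical categoricals (BI-RADS category, stiff-rim sign, optional T stage and
tumor location), and 17 quantitative shear-wave-elastography (SWE) values —
E_mean/E_max/E_min/E_sd for the tumor and for 1/2/3 mm peritumoral shells,
plus the lesion-to-fat stiffness ratio E_ratio.

Internally the table is a pandas DataFrame with one flat canonical column per
value (fast vectorized statistics); region-structured ``SWERegionStats`` views
are available per record.  The CSV boundary uses the same canonical header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .grades import GradeContingency

log = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "STATS",
    "SWE_COLUMNS",
    "CANONICAL_COLUMNS",
    "BIRADS_LEVELS",
    "SWERegionStats",
    "PatientRecord",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "expand_contingency",
]

REGIONS = ("tumor", "shell1", "shell2", "shell3")
STATS = ("emean", "emax", "emin", "esd")
SWE_COLUMNS = tuple(f"{r}_{s}" for r in REGIONS for s in STATS)
QUANT_COLUMNS = SWE_COLUMNS + ("e_ratio",)

BIRADS_LEVELS = ("3", "4A", "4B", "4C", "5")
LN_LEVELS = ("negative", "positive")
STIFF_RIM_LEVELS = ("present", "absent")
T_STAGE_LEVELS = ("T1", "T2_T3")
LOCATION_LEVELS = ("upper_outer", "upper_inner", "lower_outer", "lower_inner")

CANONICAL_COLUMNS = (
    "patient_id",
    "ln_status",
    "age",
    "tumor_size_mm",
    "t_stage",
    "location",
    "birads",
    "stiff_rim",
    "e_ratio",
) + SWE_COLUMNS

REQUIRED_COLUMNS = ("patient_id", "ln_status", "birads", "stiff_rim", "e_ratio") + SWE_COLUMNS
OPTIONAL_COLUMNS = ("age", "tumor_size_mm", "t_stage", "location")


class CohortFormatError(ValueError):
    """File-level problem: missing column, unreadable header."""


@dataclass(frozen=True)
class SWERegionStats:
    """Elastic-modulus summary (kPa) over one region of interest."""

    region: str
    e_mean: float
    e_max: float
    e_min: float
    e_sd: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        vals = (self.e_mean, self.e_max, self.e_min, self.e_sd)
        if any(v < 0 for v in vals):
            raise ValueError(f"negative elastic modulus in region {self.region}")
        if not (self.e_min <= self.e_mean <= self.e_max):
            raise ValueError(
                f"region {self.region}: requires e_min <= e_mean <= e_max, "
                f"got ({self.e_min}, {self.e_mean}, {self.e_max})"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: LN outcome, categorical features, and SWE measurements."""

    patient_id: str
    ln_status: str
    birads: str
    stiff_rim: str
    e_ratio: float
    swe: dict  # region -> SWERegionStats, all four regions required
    age: float | None = None
    tumor_size_mm: float | None = None
    t_stage: str | None = None
    location: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if self.ln_status not in LN_LEVELS:
            raise ValueError(f"invalid ln_status {self.ln_status!r}")
        if self.birads not in BIRADS_LEVELS:
            raise ValueError(f"invalid birads {self.birads!r}")
        if self.stiff_rim not in STIFF_RIM_LEVELS:
            raise ValueError(f"invalid stiff_rim {self.stiff_rim!r}")
        if self.e_ratio < 0:
            raise ValueError("e_ratio must be nonnegative")
        missing = set(REGIONS) - set(self.swe)
        if missing:
            raise ValueError(f"missing SWE regions: {sorted(missing)}")

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "ln_status": self.ln_status,
            "age": self.age,
            "tumor_size_mm": self.tumor_size_mm,
            "t_stage": self.t_stage,
            "location": self.location,
            "birads": self.birads,
            "stiff_rim": self.stiff_rim,
            "e_ratio": self.e_ratio,
        }
        for region in REGIONS:
            st = self.swe[region]
            row[f"{region}_emean"] = st.e_mean
            row[f"{region}_emax"] = st.e_max
            row[f"{region}_emin"] = st.e_min
            row[f"{region}_esd"] = st.e_sd
        return row


class CohortTable:
    """Validated per-patient cohort, DataFrame-backed.

    Construction validates every row; see :func:`read_cohort` for the
    diagnostic-collecting entry point that drops invalid rows instead of
    raising.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "", *, _validated: bool = False):
        frame = frame.reindex(columns=list(CANONICAL_COLUMNS))
        if not _validated:
            keep, diags = _validate_frame(frame)
            if diags:
                raise ValueError(
                    "invalid cohort rows: " + "; ".join(f"row {i}: {r}" for i, r in diags)
                )
            frame = keep
        self._frame = frame.reset_index(drop=True)
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    # -- views ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying flat-column DataFrame."""
        return self._frame.copy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self._frame.iterrows():
            swe = {
                region: SWERegionStats(
                    region,
                    float(row[f"{region}_emean"]),
                    float(row[f"{region}_emax"]),
                    float(row[f"{region}_emin"]),
                    float(row[f"{region}_esd"]),
                )
                for region in REGIONS
            }
            out.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    ln_status=row["ln_status"],
                    birads=str(row["birads"]),
                    stiff_rim=row["stiff_rim"],
                    e_ratio=float(row["e_ratio"]),
                    swe=swe,
                    age=None if pd.isna(row["age"]) else float(row["age"]),
                    tumor_size_mm=None
                    if pd.isna(row["tumor_size_mm"])
                    else float(row["tumor_size_mm"]),
                    t_stage=None if pd.isna(row["t_stage"]) else row["t_stage"],
                    location=None if pd.isna(row["location"]) else row["location"],
                )
            )
        return out

    @property
    def outcome(self) -> np.ndarray:
        """Binary LN status, 1 = positive."""
        return (self._frame["ln_status"].to_numpy() == "positive").astype(int)

    @property
    def n_positive(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    @classmethod
    def from_records(cls, records, provenance: str = "") -> "CohortTable":
        rows = [r.to_row() for r in records]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(frame, provenance)


def _validate_frame(frame: pd.DataFrame):
    """Split a canonical-column frame into (valid rows, diagnostics)."""
    diags: list[tuple[int, str]] = []
    bad = np.zeros(len(frame), dtype=bool)

    def flag(mask, reason: str) -> None:
        for i in np.flatnonzero(np.asarray(mask) & ~bad):
            diags.append((int(i), reason))
        bad[np.asarray(mask)] = True

    pid = frame["patient_id"].astype("string")
    flag(pid.isna().to_numpy() | (pid.str.len() == 0).fillna(True).to_numpy(), "empty patient_id")
    flag(pid.duplicated(keep=False).fillna(False).to_numpy() & ~pid.isna().to_numpy(),
         "duplicate patient_id")
    flag(~frame["ln_status"].isin(LN_LEVELS).to_numpy(), "invalid ln_status")
    flag(~frame["birads"].astype("string").isin(BIRADS_LEVELS).to_numpy(), "invalid birads")
    flag(~frame["stiff_rim"].isin(STIFF_RIM_LEVELS).to_numpy(), "invalid stiff_rim")

    for col in QUANT_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        flag(vals.isna().to_numpy(), f"missing or non-numeric {col}")
        flag((vals < 0).fillna(False).to_numpy(), f"negative {col}")
        frame = frame.assign(**{col: vals})
    for region in REGIONS:
        emin = frame[f"{region}_emin"]
        emean = frame[f"{region}_emean"]
        emax = frame[f"{region}_emax"]
        viol = ~((emin <= emean) & (emean <= emax))
        flag(viol.fillna(True).to_numpy() & ~bad, f"{region}: e_min <= e_mean <= e_max violated")

    tstage_bad = frame["t_stage"].notna() & ~frame["t_stage"].isin(T_STAGE_LEVELS)
    flag(tstage_bad.to_numpy(), "invalid t_stage")
    loc_bad = frame["location"].notna() & ~frame["location"].isin(LOCATION_LEVELS)
    flag(loc_bad.to_numpy(), "invalid location")

    keep = frame.loc[~bad].copy()
    keep["birads"] = keep["birads"].astype("string").astype(object)
    diags.sort(key=lambda t: t[0])
    return keep, diags


def read_cohort(path, provenance: str | None = None) -> CohortTable:
    """Read a cohort CSV, dropping invalid rows with logged diagnostics.

    Raises :class:`CohortFormatError` if a required column is absent.  Rows
    that fail validation (non-numeric SWE, duplicate ids, ordering
    violations, ...) are excluded; each exclusion is logged and recorded on
    the returned table's ``diagnostics`` list as ``(row_number, reason)``
    with 1-based data row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"patient_id": str, "birads": str, "ln_status": str,
               "stiff_rim": str, "t_stage": str, "location": str},
        float_precision="round_trip",
    )
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise CohortFormatError(f"missing required columns: {sorted(missing)}")
    frame = frame.reindex(columns=list(CANONICAL_COLUMNS))
    keep, diags = _validate_frame(frame)
    for i, reason in diags:
        log.warning("%s: data row %d excluded: %s", path.name, i + 1, reason)
    table = CohortTable(keep, provenance or str(path), _validated=True)
    table.diagnostics = [(i + 1, reason) for i, reason in diags]
    return table


def write_cohort(cohort: CohortTable, path) -> Path:
    """Write a cohort as canonical UTF-8 comma-separated CSV.

    Values round-trip at full precision: ``read_cohort(write_cohort(c)) == c``.
    """
    path = Path(path)
    # %.17g renders every double uniquely, so values round-trip bit-exactly
    cohort.frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def expand_contingency(counts: GradeContingency) -> tuple[np.ndarray, np.ndarray]:
    """Expand grade-by-LN-status counts into per-subject (grade, outcome) pairs.

    Re-tabulating the result reproduces the input counts exactly, which lets
    rank statistics be computed on printed contingency tables as if the
    per-patient data were available.
    """
    return counts.expand()
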
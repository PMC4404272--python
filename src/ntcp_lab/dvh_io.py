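"""Cohort data containers and tabular I/O for rectal dose-volume histograms.

A cumulative DVH gives, for each dose level, the fraction of the organ
volume receiving at least that dose; the differential form gives the
relative volume per dose bin and is what the gEUD power mean consumes.
DVHs and clinical covariates travel as plain delimited text (CSV/TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VOL_TOL = 1e-6

__all__ = [
    "CumulativeDVH",
    "DifferentialDVH",
    "PatientRecord",
    "Cohort",
    "DVHFormatError",
    "DVHValidationError",
    "read_dvh_table",
    "read_clinical_table",
    "read_cohort",
    "write_dvh_table",
    "write_clinical_table",
    "cumulative_to_differential",
    "accumulate_differential",
]


class DVHFormatError(ValueError):
    """Malformed input file (missing columns, empty file)."""


class DVHValidationError(ValueError):
    """Input violates a DVH or covariate invariant."""


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: ``volume_fractions[i]`` of the organ receives at
    least ``dose_bins[i]`` Gy.

    Dose bins are strictly increasing, fractions non-increasing in [0, 1]
    and the curve starts at 1 (whole organ receives at least the minimum
    dose). Small numeric noise (within 1e-6) is clamped on construction.
    """

    dose_bins: np.ndarray
    volume_fractions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_bins, dtype=float)
        v = np.asarray(self.volume_fractions, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size:
            raise DVHValidationError("dose_bins and volume_fractions must be 1-D of equal length")
        if d.size < 2:
            raise DVHValidationError("a cumulative DVH needs at least 2 bins")
        if d[0] < 0:
            raise DVHValidationError("first dose bin must be >= 0 Gy")
        if np.any(np.diff(d) <= 0):
            raise DVHValidationError("dose bins must be strictly increasing")
        if np.any(v > 1 + _VOL_TOL) or np.any(v < -_VOL_TOL):
            raise DVHValidationError("volume fractions must lie in [0, 1]")
        if np.any(np.diff(v) > _VOL_TOL):
            raise DVHValidationError("cumulative volume fractions must be non-increasing")
        if abs(v[0] - 1.0) > _VOL_TOL:
            raise DVHValidationError(f"first volume fraction must be 1, got {v[0]!r}")
        v = np.clip(v, 0.0, 1.0)
        v = np.minimum.accumulate(v)  # clamp sub-tolerance wiggles
        object.__setattr__(self, "dose_bins", d)
        object.__setattr__(self, "volume_fractions", v)

    @property
    def n_bins(self) -> int:
        return int(self.dose_bins.size)


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: relative volume ``bin_volumes[i]`` receives dose
    ``bin_doses[i]`` Gy; volumes are non-negative and sum to 1."""

    bin_doses: np.ndarray
    bin_volumes: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_doses, dtype=float)
        v = np.asarray(self.bin_volumes, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size == 0:
            raise DVHValidationError("bin_doses and bin_volumes must be 1-D of equal nonzero length")
        if np.any(np.diff(d) <= 0):
            raise DVHValidationError("bin doses must be strictly increasing")
        if np.any(v < -1e-12):
            raise DVHValidationError("bin volumes must be non-negative")
        v = np.clip(v, 0.0, None)
        if abs(v.sum() - 1.0) > 1e-9:
            raise DVHValidationError(f"bin volumes must sum to 1, got {v.sum()!r}")
        object.__setattr__(self, "bin_doses", d)
        object.__setattr__(self, "bin_volumes", v)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: DVH, binary covariates and the binary late-GI outcome.

    ``ah_ac`` — 1 if the patient takes antihypertensive and/or
    anticoagulant drugs; ``acute_gi`` — 1 if grade 1-2 acute GI toxicity
    occurred; ``late_gi`` — the outcome, 1 if grade 1-2 late GI toxicity.
    """

    patient_id: str
    dvh: CumulativeDVH
    ah_ac: int
    acute_gi: int
    late_gi: int
    age_years: float | None = None

    def __post_init__(self) -> None:
        for name in ("ah_ac", "acute_gi", "late_gi"):
            val = getattr(self, name)
            if val not in (0, 1):
                raise DVHValidationError(
                    f"patient {self.patient_id!r}: covariate {name} must be 0 or 1, got {val!r}"
                )
        if self.age_years is not None and not self.age_years > 0:
            raise DVHValidationError(f"patient {self.patient_id!r}: age_years must be positive")


@dataclass(frozen=True)
class Cohort:
    """Non-empty list of patients with distinct ids."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        pts = tuple(self.patients)
        if not pts:
            raise DVHValidationError("a cohort must contain at least one patient")
        ids = [p.patient_id for p in pts]
        if len(set(ids)) != len(ids):
            raise DVHValidationError("patient ids must be distinct within a cohort")
        object.__setattr__(self, "patients", pts)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([p.late_gi for p in self.patients], dtype=int)

    @property
    def dvhs(self) -> list[CumulativeDVH]:
        return [p.dvh for p in self.patients]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise DVHFormatError(f"{path}: empty or undelimited file") from exc
    if df.empty:
        raise DVHFormatError(f"{path}: no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_dvh_table(
    path: str | Path, volume_mode: str = "fraction"
) -> dict[str, CumulativeDVH]:
    """Read a long-format DVH table into per-patient cumulative DVHs.

    The file is delimited text with header ``patient_id,dose_gy,volume``;
    one row per (patient, dose bin). In ``absolute`` mode each patient's
    volumes are normalized by that patient's maximum tabulated volume.
    """
    if volume_mode not in ("fraction", "absolute"):
        raise ValueError(f"volume_mode must be 'fraction' or 'absolute', got {volume_mode!r}")
    df = _read_table(path)
    required = {"patient_id", "dose_gy", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise DVHFormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, CumulativeDVH] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("dose_gy")
        doses = grp["dose_gy"].to_numpy(dtype=float)
        vols = grp["volume"].to_numpy(dtype=float)
        if volume_mode == "absolute":
            vmax = vols.max()
            if vmax <= 0:
                raise DVHValidationError(f"patient {pid!r}: non-positive maximum volume")
            vols = vols / vmax
        try:
            out[str(pid)] = CumulativeDVH(doses, vols)
        except DVHValidationError as exc:
            raise DVHValidationError(f"patient {pid!r}: {exc}") from exc
    return out


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical covariate table, validating binary domains."""
    df = _read_table(path)
    required = {"patient_id", "ah_ac", "acute_gi", "late_gi"}
    missing = required - set(df.columns)
    if missing:
        raise DVHFormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("ah_ac", "acute_gi", "late_gi"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            pid = df.loc[bad, "patient_id"].iloc[0]
            raise DVHValidationError(
                f"{path}: non-binary value {df.loc[bad, col].iloc[0]!r} in column "
                f"{col!r} (patient {pid!r})"
            )
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_cohort(dvh_path: str | Path, clinical_path: str | Path) -> Cohort:
    """Assemble a cohort by inner-joining DVH and clinical tables on patient id.

    Patients present in only one file are dropped with a logged warning.
    """
    dvhs = read_dvh_table(dvh_path)
    clin = read_clinical_table(clinical_path)
    clin_ids = list(clin["patient_id"])
    common = [pid for pid in clin_ids if pid in dvhs]
    dropped = sorted(set(dvhs) ^ set(clin_ids))
    if not common:
        raise DVHValidationError(
            f"no overlapping patient ids between {dvh_path} and {clinical_path}"
        )
    if dropped:
        logger.warning("dropping %d unmatched patients: %s", len(dropped), dropped)
    clin = clin.set_index("patient_id")
    patients = []
    for pid in common:
        row = clin.loc[pid]
        age = float(row["age_years"]) if "age_years" in clin.columns and pd.notna(row.get("age_years")) else None
        patients.append(
            PatientRecord(
                patient_id=pid,
                dvh=dvhs[pid],
                ah_ac=int(row["ah_ac"]),
                acute_gi=int(row["acute_gi"]),
                late_gi=int(row["late_gi"]),
                age_years=age,
            )
        )
    return Cohort(tuple(patients))


def write_dvh_table(dvhs: Mapping[str, CumulativeDVH], path: str | Path) -> None:
    """Write per-patient cumulative DVHs in the long CSV format read back
    by :func:`read_dvh_table` (full float precision)."""
    rows = [
        (pid, d, v)
        for pid, dvh in dvhs.items()
        for d, v in zip(dvh.dose_bins, dvh.volume_fractions)
    ]
    pd.DataFrame(rows, columns=["patient_id", "dose_gy", "volume"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_clinical_table(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "ah_ac": p.ah_ac,
            "acute_gi": p.acute_gi,
            "late_gi": p.late_gi,
            "age_years": p.age_years if p.age_years is not None else "",
        }
        for p in cohort
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def cumulative_to_differential(dvh: CumulativeDVH) -> DifferentialDVH:
    """Convert a cumulative DVH to its differential form.

    Bin i (i < last) holds volume V(d_i) - V(d_{i+1}) at the interval
    midpoint (d_i + d_{i+1})/2; the last bin keeps V(d_last) at d_last.
    Zero-volume bins are retained (they do not affect the gEUD).
    """
    d = dvh.dose_bins
    v = dvh.volume_fractions
    vols = np.empty_like(v)
    vols[:-1] = v[:-1] - v[1:]
    vols[-1] = v[-1]
    doses = np.empty_like(d)
    doses[:-1] = 0.5 * (d[:-1] + d[1:])
    doses[-1] = d[-1]
    # total = V(d_0) = 1 by the cumulative invariant
    return DifferentialDVH(doses, vols)


def accumulate_differential(ddvh: DifferentialDVH, dose_edges: np.ndarray) -> np.ndarray:
    """Re-accumulate a differential DVH onto dose edges: fraction of volume
    in bins whose representative dose is >= each edge (round-trip check for
    :func:`cumulative_to_differential` when edges are the original bins)."""
    edges = np.asarray(dose_edges, dtype=float)
    return np.array([ddvh.bin_volumes[ddvh.bin_doses >= e].sum() for e in edges])
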
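"""Patient-level cohort model and CSV input/output.

The cohort is the study population of critically ill TBI patients in whom a
normal-ish CT (Marshall < 3) does not explain the clinical state: either the
Glasgow Coma Scale was below 13 ("moderate_severe" sub-cohort) or the patient
was intubated before a GCS could be recorded ("unrecorded" sub-cohort).  Each
patient carries a six-protein serum biomarker panel sampled within 24 h of
injury and an MRI-derived grade of traumatic axonal injury (Adams-Gentry
classification: stage 1 hemispheric, stage 2 corpus callosum, stage 3
brainstem; stage 0 is this package's encoding for "no axonal injury", which
the original grading leaves implicit).

The on-disk format is a plain CSV with one row per patient and the columns
listed in :data:`COLUMNS`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBCOHORTS = ("moderate_severe", "unrecorded")

#: Canonical protein order used in every table this package emits.
PROTEINS = ("GFAP", "NFL", "NSE", "S100B", "Tau", "UCHL1")

#: Assay units per protein (astroglial/neuronal markers in ng/ml, the
#: ultrasensitive Simoa analytes in pg/ml).
UNITS: Mapping[str, str] = {
    "GFAP": "ng/ml",
    "NSE": "ng/ml",
    "S100B": "ng/ml",
    "NFL": "pg/ml",
    "Tau": "pg/ml",
    "UCHL1": "pg/ml",
}

PROTEIN_COLUMNS: Mapping[str, str] = {
    "GFAP": "gfap_ng_ml",
    "NFL": "nfl_pg_ml",
    "NSE": "nse_ng_ml",
    "S100B": "s100b_ng_ml",
    "Tau": "tau_pg_ml",
    "UCHL1": "uchl1_pg_ml",
}

COLUMNS = (
    "patient_id",
    "subcohort",
    "sample_time_h",
    "gfap_ng_ml",
    "nfl_pg_ml",
    "nse_ng_ml",
    "s100b_ng_ml",
    "tau_pg_ml",
    "uchl1_pg_ml",
    "adams_gentry",
)


class CohortFormatError(ValueError):
    """The CSV lacks required columns or cannot be parsed."""


class CohortValidationError(ValueError):
    """A row violates a cohort invariant (names the offending row)."""


class EmptyGroupError(ValueError):
    """A summary was requested for a group with no members."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (print convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BiomarkerPanel:
    """Six serum protein concentrations, all strictly positive.

    GFAP, NSE and S100B are in ng/ml; NFL, Tau and UCH-L1 in pg/ml.
    """

    gfap: float
    nfl: float
    nse: float
    s100b: float
    tau: float
    uchl1: float

    def value(self, protein: str) -> float:
        return getattr(self, protein.lower().replace("-", ""))

    def as_dict(self) -> dict[str, float]:
        return {p: self.value(p) for p in PROTEINS}

    def problems(self) -> list[str]:
        return [
            f"{p} concentration {self.value(p)!r} is not strictly positive"
            for p in PROTEINS
            if not (isinstance(self.value(p), (int, float)) and self.value(p) > 0
                    and math.isfinite(self.value(p)))
        ]


@dataclass(frozen=True)
class PatientRecord:
    """One subject: sub-cohort, biomarker panel, sample time, injury grade."""

    patient_id: str
    subcohort: str
    sample_time_h: float
    biomarkers: BiomarkerPanel
    adams_gentry: int

    @property
    def brainstem_injury(self) -> bool:
        """Adams-Gentry stage 3; the positive class for triage thresholds."""
        return self.adams_gentry == 3

    def problems(self) -> list[str]:
        out = []
        if self.subcohort not in SUBCOHORTS:
            out.append(f"subcohort {self.subcohort!r} not in {SUBCOHORTS}")
        if not (0 <= self.sample_time_h <= 24):
            out.append(f"sample_time_h {self.sample_time_h!r} outside [0, 24]")
        if self.adams_gentry not in (0, 1, 2, 3):
            out.append(f"adams_gentry {self.adams_gentry!r} outside 0-3")
        out.extend(self.biomarkers.problems())
        return out


@dataclass(frozen=True)
class GroupSummary:
    """Count/share plus median and quartiles, as printed in cohort tables."""

    n: int
    percent: int
    median: float
    q1: float
    q3: float

    def format_summary(self, digits: int = 2) -> str:
        return (f"{self.median:.{digits}f} "
                f"({self.q1:.{digits}f}–{self.q3:.{digits}f})")

    def format_count(self) -> str:
        return f"{self.n} ({self.percent}%)"


def format_count_percent(n: int, total: int) -> str:
    """``"21 (70%)"``-style count with integer percent of *total*."""
    if total <= 0:
        raise EmptyGroupError("total must be positive")
    return f"{n} ({round_half_up(100.0 * n / total)}%)"


def _record_from_row(row: Mapping[str, object], label: str) -> PatientRecord:
    try:
        panel = BiomarkerPanel(
            gfap=float(row["gfap_ng_ml"]),
            nfl=float(row["nfl_pg_ml"]),
            nse=float(row["nse_ng_ml"]),
            s100b=float(row["s100b_ng_ml"]),
            tau=float(row["tau_pg_ml"]),
            uchl1=float(row["uchl1_pg_ml"]),
        )
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            subcohort=str(row["subcohort"]),
            sample_time_h=float(row["sample_time_h"]),
            biomarkers=panel,
            adams_gentry=int(row["adams_gentry"]),
        )
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(f"row {label}: unparseable value ({exc})") from exc
    problems = rec.problems()
    if problems:
        raise CohortValidationError(f"row {label}: " + "; ".join(problems))
    return rec


def read_cohort(path: str | Path, strict: bool = True) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    With ``strict=True`` (default) any invariant violation raises
    :class:`CohortValidationError` naming the row; with ``strict=False``
    offending rows are dropped with a logged warning.
    """
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str, "subcohort": str},
                            float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortFormatError(f"cannot read cohort CSV {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"cohort CSV {path} missing columns: {missing}")
    records: list[PatientRecord] = []
    for idx, row in frame.iterrows():
        label = f"{idx + 2} (patient_id={row['patient_id']!r})"  # +2: header + 1-based
        try:
            records.append(_record_from_row(row, label))
        except CohortValidationError as exc:
            if strict:
                raise
            logger.warning("dropping invalid %s: %s", label, exc)
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "subcohort": r.subcohort,
            "sample_time_h": r.sample_time_h,
            "adams_gentry": r.adams_gentry,
        }
        for p in PROTEINS:
            row[PROTEIN_COLUMNS[p]] = r.biomarkers.value(p)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as CSV; ``write_cohort`` then :func:`read_cohort` is the
    identity on valid cohorts (floats serialised via ``repr`` round-trip)."""
    # repr round-trips doubles exactly; pandas' default float formatting
    # can lose the last couple of bits
    records_to_frame(records).to_csv(path, index=False,
                                     float_format=lambda v: repr(float(v)))


def _group_key(group_by: str | Callable[[PatientRecord], object]):
    if callable(group_by):
        return group_by
    if group_by in ("brainstem_injury", "subcohort", "adams_gentry"):
        return lambda r: getattr(r, group_by)
    raise ValueError(f"unknown grouping {group_by!r}")


def group_records(
    records: Iterable[PatientRecord],
    group_by: str | Callable[[PatientRecord], object],
) -> dict[object, list[PatientRecord]]:
    key = _group_key(group_by)
    groups: dict[object, list[PatientRecord]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    return dict(sorted(groups.items(), key=lambda kv: str(kv[0])))


def summarize_biomarker(
    records: Sequence[PatientRecord],
    group_by: str | Callable[[PatientRecord], object],
    protein: str,
) -> dict[object, GroupSummary]:
    """Per-group count (integer percent of cohort), median and quartiles.

    Quartiles use linear interpolation between order statistics, the default
    convention of mainstream statistics software; concentrations are
    summarised on their raw (untransformed) scale.
    """
    records = list(records)
    if not records:
        raise EmptyGroupError("no records supplied")
    if protein == "sample_time_h":
        values = lambda r: r.sample_time_h  # noqa: E731
    elif protein in PROTEINS:
        values = lambda r: r.biomarkers.value(protein)  # noqa: E731
    else:
        raise ValueError(f"unknown protein {protein!r}")
    total = len(records)
    out: dict[object, GroupSummary] = {}
    for label, members in group_records(records, group_by).items():
        if not members:
            raise EmptyGroupError(f"group {label!r} is empty")
        x = np.asarray([values(r) for r in members], dtype=float)
        out[label] = GroupSummary(
            n=len(members),
            percent=round_half_up(100.0 * len(members) / total),
            median=float(np.median(x)),
            q1=float(np.percentile(x, 25)),
            q3=float(np.percentile(x, 75)),
        )
    return out
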
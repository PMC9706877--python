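"""Cost–benefit model: "MRI for all" versus "protein plus selected MRI".

Two strategies are costed per patient.  Under "MRI for all" every patient is
transferred to the scanner, costing ``cost_mri_per_patient`` (which includes
the transfer).  Under "protein plus selected MRI" every patient is assayed
(``cost_assay``) and only those at or above the triage threshold are
transferred, so

    cost_triage = cost_assay + fraction_above * cost_mri_per_patient
    savings     = cost_mri_for_all - cost_triage
                = (1 - fraction_above) * cost_mri_per_patient - cost_assay

Savings may be negative.  A protein with no assay cost configured (no
licensed clinical platform in that health system) gets ``available=False``
and no numeric cost output.  Missed-injury costs are deliberately absent:
the safety trade-off is expressed solely through the minimum-sensitivity
constraint of the cutpoint stage.

Default UK and US configurations ship as YAML under ``tbitriage/configs``;
the US scenario prices only GFAP and UCH-L1 (the point-of-care i-stat
platform measures nothing else).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .cohort import PROTEINS, PatientRecord, format_count_percent
from .cutpoints import CutpointResult, select_cutpoint


class CostParameterError(ValueError):
    """Invalid cost-model input."""


@dataclass(frozen=True)
class CostConfig:
    """Unit costs of one health system.

    ``assays`` maps protein name to cost per test, or ``None`` where the
    system has no licensed assay for that protein.  ``currency`` is a
    passive label; no conversion is performed.
    """

    system_name: str
    currency: str
    cost_mri_per_patient: float
    assays: Mapping[str, float | None]

    def __post_init__(self):
        if self.cost_mri_per_patient < 0:
            raise CostParameterError("cost_mri_per_patient must be >= 0")
        for protein, cost in self.assays.items():
            if cost is not None and cost < 0:
                raise CostParameterError(f"assay cost for {protein} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            system_name=str(d["system_name"]),
            currency=str(d["currency"]),
            cost_mri_per_patient=float(d["cost_mri_per_patient"]),
            assays={str(k): (None if v is None else float(v))
                    for k, v in d["assays"].items()},
        )


def builtin_config(name: str) -> CostConfig:
    """Load a shipped health-system config (``"uk"`` or ``"us"``)."""
    ref = resources.files("tbitriage") / "configs" / f"{name.lower()}.yaml"
    with resources.as_file(ref) as path:
        return CostConfig.from_yaml(path)


def default_configs() -> list[CostConfig]:
    return [builtin_config("uk"), builtin_config("us")]


@dataclass(frozen=True)
class CostResult:
    """Per-patient strategy costs for one protein in one health system."""

    system_name: str
    currency: str
    protein: str
    fraction_above: float
    available: bool
    cost_mri_for_all: float | None = None
    cost_triage: float | None = None
    savings: float | None = None


def triage_cost(config: CostConfig, protein: str,
                fraction_above: float) -> CostResult:
    """Per-patient cost of triaged MRI at the given transfer fraction."""
    if not (0 <= fraction_above <= 1):
        raise CostParameterError("fraction_above must be in [0, 1]")
    assay = config.assays.get(protein)
    if assay is None:
        return CostResult(config.system_name, config.currency, protein,
                          fraction_above, available=False)
    cost_triage_value = assay + fraction_above * config.cost_mri_per_patient
    return CostResult(
        system_name=config.system_name,
        currency=config.currency,
        protein=protein,
        fraction_above=fraction_above,
        available=True,
        cost_mri_for_all=config.cost_mri_per_patient,
        cost_triage=cost_triage_value,
        savings=config.cost_mri_per_patient - cost_triage_value,
    )


def triage_report(
    records: Sequence[PatientRecord],
    min_sensitivity: float,
    configs: Sequence[CostConfig] = (),
) -> pd.DataFrame:
    """One row per protein: constrained cutpoint plus per-system costs.

    Columns: threshold, sensitivity, specificity, ``patients_above`` as
    ``"n (percent%)"``, and for each config a ``<system>_mri_for_all`` /
    ``<system>_triage`` / ``<system>_savings`` triplet (NaN where the system
    has no assay for the protein, printed as "–" downstream).  Sensitivity
    and specificity are rounded to 2 decimals for the report.
    """
    records = list(records)
    labels = [r.brainstem_injury for r in records]
    rows = []
    for protein in PROTEINS:
        values = [r.biomarkers.value(protein) for r in records]
        cp: CutpointResult = select_cutpoint(values, labels, min_sensitivity,
                                             protein=protein)
        row = {
            "protein": protein,
            "threshold": cp.threshold,
            "sensitivity": round(cp.confusion.sensitivity, 2),
            "specificity": round(cp.confusion.specificity, 2),
            "patients_above": format_count_percent(
                cp.confusion.n_above_threshold, cp.confusion.n),
            "fraction_above": cp.confusion.fraction_above,
        }
        for config in configs:
            cost = triage_cost(config, protein, cp.confusion.fraction_above)
            tag = config.system_name.lower()
            if cost.available:
                row[f"{tag}_mri_for_all"] = round(cost.cost_mri_for_all, 2)
                row[f"{tag}_triage"] = round(cost.cost_triage, 2)
                row[f"{tag}_savings"] = round(cost.savings, 2)
            else:
                row[f"{tag}_mri_for_all"] = round(config.cost_mri_per_patient, 2)
                row[f"{tag}_triage"] = float("nan")
                row[f"{tag}_savings"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein")
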
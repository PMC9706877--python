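"""End-to-end run: simulate/load -> association tests -> cutpoints -> costs.

One call produces the full analysis bundle in an output directory:
association tables for both outcomes in each analysis scope (each sub-cohort
separately and pooled), a triage report (cutpoints + costs) at each
requested minimum sensitivity on the moderate-severe sub-cohort, and a JSON
manifest with the seed, version, and SHA-256 hashes of every output so a
re-run can be verified byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .cohort import PatientRecord, read_cohort, write_cohort
from .economics import CostConfig, default_configs, triage_report
from .simulate import SimulationConfig, simulate_cohort
from .stats import DegenerateScopeError, association_table

logger = logging.getLogger(__name__)

SCOPES = ("moderate_severe", "unrecorded", "all")
OUTCOMES = ("brainstem_binary", "adams_gentry_ordinal")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """What a run consumed and produced; identical inputs reproduce
    identical output hashes."""

    seed: int
    version: str
    cohort_source: str
    min_sensitivities: list[float]
    cost_systems: list[str]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    skipped: list[str] = field(default_factory=list)
    started_utc: str = ""
    finished_utc: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def run_pipeline(
    cohort_source: str | Path | SimulationConfig,
    out_dir: str | Path,
    seed: int = 0,
    min_sensitivities: Sequence[float] = (0.90, 1.00),
    cost_configs: Sequence[CostConfig] | None = None,
) -> RunManifest:
    """Run the full triage analysis and write all outputs under *out_dir*.

    ``cohort_source`` is either a cohort CSV path or a
    :class:`SimulationConfig` (simulated with ``seed``).  Association tables
    are written for both outcomes in every non-degenerate scope; the triage
    report is computed on the moderate-severe sub-cohort at each minimum
    sensitivity (skipped with a logged notice if that sub-cohort lacks both
    brainstem classes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cost_configs is None:
        cost_configs = default_configs()
    manifest = RunManifest(
        seed=seed,
        version=__version__,
        cohort_source=(type(cohort_source).__name__
                       if isinstance(cohort_source, SimulationConfig)
                       else str(cohort_source)),
        min_sensitivities=[float(s) for s in min_sensitivities],
        cost_systems=[c.system_name for c in cost_configs],
        started_utc=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )

    try:
        if isinstance(cohort_source, SimulationConfig):
            records = simulate_cohort(cohort_source, seed=seed)
            cohort_path = out / "cohort.csv"
            write_cohort(records, cohort_path)
            manifest.outputs[cohort_path.name] = _sha256(cohort_path)
        else:
            records = read_cohort(cohort_source)
    except Exception as exc:
        raise PipelineError(f"cohort stage failed: {exc}") from exc

    for outcome in OUTCOMES:
        short = "brainstem" if outcome == "brainstem_binary" else "stage"
        for scope in SCOPES:
            name = f"association_{short}_{scope}.tsv"
            try:
                table = association_table(records, outcome=outcome,
                                          scope=scope, seed=seed)
            except DegenerateScopeError as exc:
                logger.warning("skipping %s: %s", name, exc)
                manifest.skipped.append(name)
                continue
            except Exception as exc:
                raise PipelineError(
                    f"association stage failed ({outcome}, {scope}): {exc}"
                ) from exc
            table.to_csv(out / name, sep="\t")
            manifest.outputs[name] = _sha256(out / name)

    triage_scope = [r for r in records if r.subcohort == "moderate_severe"]
    for s in manifest.min_sensitivities:
        name = f"triage_sens{int(round(100 * s))}.tsv"
        try:
            report = triage_report(triage_scope, s, cost_configs)
        except Exception as exc:
            logger.warning("skipping %s: %s", name, exc)
            manifest.skipped.append(name)
            continue
        report.to_csv(out / name, sep="\t", na_rep="–")
        manifest.outputs[name] = _sha256(out / name)
        jname = name.replace(".tsv", ".json")
        (out / jname).write_text(
            report.reset_index().to_json(orient="records", indent=2))
        manifest.outputs[jname] = _sha256(out / jname)

    manifest.finished_utc = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
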
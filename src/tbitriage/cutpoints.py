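"""Sensitivity-constrained threshold selection for MRI triage.

The triage rule is "send to MRI iff the serum concentration is >= threshold".
For each protein the selected threshold maximises specificity for brainstem
injury subject to a clinician-set minimum sensitivity (typically 0.90 or
1.00).  Candidate thresholds are the observed concentrations: with the ">="
rule they enumerate every distinct empirical operating point, so exhaustive
search over them is exact.  The all-positive rule (threshold at the minimum
observed value) always attains sensitivity 1, so the constraint is feasible
for any level up to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class CutpointParameterError(ValueError):
    """Invalid input to cutpoint selection."""


class DegenerateLabelsError(ValueError):
    """Labels contain a single class; sensitivity or specificity undefined."""


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts of a thresholded test against the brainstem-injury label."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def n_above_threshold(self) -> int:
        return self.tp + self.fp

    @property
    def fraction_above(self) -> float:
        return self.n_above_threshold / self.n


@dataclass(frozen=True)
class CutpointResult:
    """A selected threshold and its operating characteristics."""

    protein: str
    threshold: float
    min_sensitivity: float
    confusion: ConfusionSummary
    feasible: bool


def _check_inputs(values: Sequence[float], labels: Sequence[bool]):
    v = np.asarray(list(values), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if v.size == 0 or v.size != y.size:
        raise CutpointParameterError("values and labels must align and be non-empty")
    if y.all() or not y.any():
        raise DegenerateLabelsError("labels must contain both classes")
    return v, y


def confusion_at_threshold(
    values: Sequence[float],
    labels: Sequence[bool],
    threshold: float,
) -> ConfusionSummary:
    """Exact confusion counts for the rule "positive iff value >= threshold"."""
    v, y = _check_inputs(values, labels)
    pos = v >= threshold
    return ConfusionSummary(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        tn=int(np.sum(~pos & ~y)),
        fn=int(np.sum(~pos & y)),
    )


def select_cutpoint(
    values: Sequence[float],
    labels: Sequence[bool],
    min_sensitivity: float,
    protein: str = "",
) -> CutpointResult:
    """Maximise specificity subject to sensitivity >= ``min_sensitivity``.

    Exhaustive search over the observed concentrations; among thresholds
    attaining the constrained-optimal specificity the smallest is returned
    (it maximises the sensitivity margin).  ``feasible`` is always true for
    ``min_sensitivity <= 1`` since thresholding at the minimum observed
    value classifies everyone positive.
    """
    if not (0 < min_sensitivity <= 1):
        raise CutpointParameterError("min_sensitivity must be in (0, 1]")
    v, y = _check_inputs(values, labels)
    best: tuple[float, float] | None = None  # (specificity, -threshold)
    best_threshold = None
    best_conf = None
    for threshold in np.unique(v):
        conf = confusion_at_threshold(v, y, threshold)
        if conf.sensitivity < min_sensitivity:
            continue
        key = (conf.specificity, -threshold)
        if best is None or key > best:
            best, best_threshold, best_conf = key, float(threshold), conf
    if best_conf is None:  # unreachable for min_sensitivity <= 1
        fallback = confusion_at_threshold(v, y, float(np.min(v)))
        return CutpointResult(protein, float(np.min(v)), min_sensitivity,
                              fallback, feasible=False)
    return CutpointResult(protein, best_threshold, min_sensitivity,
                          best_conf, feasible=True)
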
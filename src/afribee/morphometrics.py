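"""Linear discriminant scoring of worker morphometrics.

Two fixed linear combinations of forewing, hindwing, femur and tibia
lengths (mm) separate Africanized from European honey bee workers: one
fitted on individual workers, one on colony means of ten workers.  The
coefficient vectors are established constants from the morphometric
literature; this module applies them, it does not refit them.

A score below the configured midpoint threshold classifies the worker (or
colony) as Africanized; a score at or above it classifies it European.
The true midpoints depend on reference group means that are not part of
this package, so thresholds are explicit configuration with a default of
0.0 (the discriminant axes are constructed so the two groups straddle
zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .types import DomainError, MorphMeasurements

#: Individual-worker discriminant: coefficients on (FWL, HWL, FL, TL) in mm.
INDIVIDUAL_COEFFS: tuple[float, float, float, float] = (2.5164, 1.2159, 16.3439, -10.6356)
INDIVIDUAL_CONST: float = -36.4909

#: Colony-mean discriminant, applied to per-colony means of each measurement.
COLONY_COEFFS: tuple[float, float, float, float] = (2.7535, 2.6834, 27.9261, -19.5551)
COLONY_CONST: float = -46.5884


class Formula(str, Enum):
    INDIVIDUAL = "individual"
    COLONY_MEAN = "colony_mean"


class Classification(str, Enum):
    AFRICANIZED = "africanized"
    EUROPEAN = "european"


@dataclass(frozen=True)
class Thresholds:
    """Midpoint thresholds per formula; scores strictly below → Africanized."""

    individual: float = 0.0
    colony_mean: float = 0.0

    def for_formula(self, formula: Formula) -> float:
        return self.individual if formula is Formula.INDIVIDUAL else self.colony_mean


@dataclass(frozen=True)
class DiscriminantResult:
    score: float
    formula: Formula
    classification: Classification
    threshold_used: float


def _linear(values: Sequence[float], coeffs: Sequence[float], const: float) -> float:
    return float(np.dot(coeffs, values) + const)


def individual_score(m: MorphMeasurements) -> float:
    """Discriminant score of a single worker (full floating precision)."""
    return _linear(m.as_tuple(), INDIVIDUAL_COEFFS, INDIVIDUAL_CONST)


def colony_score(members: Iterable[MorphMeasurements]) -> float:
    """Discriminant score of a colony from the means of each measurement.

    The arithmetic mean of each of the four measurements over the sampled
    workers is taken first; the colony-mean coefficient vector is then
    applied to those means.  Field protocol samples ten workers per
    colony; any n >= 1 is accepted (a warning is emitted for n != 10).
    """
    rows = [m.as_tuple() for m in members]
    if not rows:
        raise DomainError("colony_score requires at least one worker")
    if len(rows) != 10:
        import warnings

        warnings.warn(
            f"colony_score called with n={len(rows)} workers; the standard "
            "protocol uses 10 per colony",
            stacklevel=2,
        )
    means = np.mean(rows, axis=0)
    return _linear(means, COLONY_COEFFS, COLONY_CONST)


def classify(
    score: float,
    formula: Formula = Formula.INDIVIDUAL,
    thresholds: Thresholds = Thresholds(),
) -> DiscriminantResult:
    """Classify a discriminant score against the configured midpoint.

    Africanized iff score is strictly below the threshold; a tie is
    classified European (conservative with respect to declaring
    Africanization).
    """
    if not math.isfinite(score):
        raise DomainError(f"score must be finite, got {score!r}")
    threshold = thresholds.for_formula(formula)
    label = (
        Classification.AFRICANIZED if score < threshold else Classification.EUROPEAN
    )
    return DiscriminantResult(
        score=score, formula=formula, classification=label, threshold_used=threshold
    )


def score_and_classify(
    m: MorphMeasurements, thresholds: Thresholds = Thresholds()
) -> DiscriminantResult:
    """Convenience: individual score plus classification in one call."""
    return classify(individual_score(m), Formula.INDIVIDUAL, thresholds)
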
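"""Core record types shared across the pipeline.

A :class:`Specimen` is one worker bee; it accumulates whatever evidence is
available for it — four morphometric lengths, marker sequences keyed by
marker name, and the marker calls produced by the assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class AfribeeError(Exception):
    """Base class for all package errors."""


class FormatError(AfribeeError):
    """A file does not match the expected tabular/FASTA layout."""


class DomainError(AfribeeError):
    """An input violates a mathematical or biological precondition."""


class Marker(str, Enum):
    CYTB_RFLP = "cytb_rflp"
    COI_SNP = "coi_snp"
    SPACER_LINEAGE = "spacer_lineage"


class Call(str, Enum):
    AFRICAN = "african"
    EUROPEAN = "european"
    LINEAGE_A = "lineage_A"
    LINEAGE_C = "lineage_C"
    LINEAGE_M = "lineage_M"
    LINEAGE_O = "lineage_O"
    INDETERMINATE = "indeterminate"


#: Spacer lineages whose maternal origin is African vs European/Middle Eastern.
AFRICAN_LINEAGES = frozenset({Call.LINEAGE_A})
EUROPEAN_LINEAGES = frozenset({Call.LINEAGE_C, Call.LINEAGE_M, Call.LINEAGE_O})


class Source(str, Enum):
    FORAGING = "foraging"
    MANAGED_HIVE = "managed_hive"
    FERAL_HIVE = "feral_hive"
    REFERENCE = "reference"


@dataclass(frozen=True)
class MorphMeasurements:
    """The four worker lengths (mm) feeding the discriminant formulas.

    Forewing, hindwing, hind-leg femur and hind-leg tibia lengths.  All
    values must be strictly positive and finite; values outside a broad
    plausibility band (0.5–20 mm) trigger a warning but are accepted.
    """

    forewing_mm: float
    hindwing_mm: float
    femur_mm: float
    tibia_mm: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not math.isfinite(v) or v <= 0:
                raise DomainError(
                    f"{name} must be a positive finite length in mm, got {v!r}"
                )
            if not (0.5 <= v <= 20.0):
                warnings.warn(
                    f"{name}={v} mm is outside the plausible range 0.5-20 mm",
                    stacklevel=3,
                )

    def as_dict(self) -> dict[str, float]:
        return {
            "forewing_mm": self.forewing_mm,
            "hindwing_mm": self.hindwing_mm,
            "femur_mm": self.femur_mm,
            "tibia_mm": self.tibia_mm,
        }

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.forewing_mm, self.hindwing_mm, self.femur_mm, self.tibia_mm)


@dataclass(frozen=True)
class MarkerCall:
    """Outcome of one assay on one specimen.

    ``evidence`` is a human-readable trace (band lengths, observed base,
    per-lineage distances).  ``confident`` is False whenever the call is
    indeterminate, and every confident call carries non-empty evidence.
    """

    marker: Marker
    call: Call
    evidence: str
    confident: bool

    def __post_init__(self) -> None:
        if self.call is Call.INDETERMINATE and self.confident:
            raise DomainError("an indeterminate call cannot be confident")
        if self.confident and not self.evidence:
            raise DomainError("a confident call requires non-empty evidence")

    @property
    def mitotype(self) -> Optional[Call]:
        """African/European class of this call, or None if indeterminate.

        Spacer lineage A maps to African; C, M, O map to European.
        """
        if self.call in (Call.AFRICAN, Call.EUROPEAN):
            return self.call
        if self.call in AFRICAN_LINEAGES:
            return Call.AFRICAN
        if self.call in EUROPEAN_LINEAGES:
            return Call.EUROPEAN
        return None


@dataclass
class Specimen:
    """One worker bee with its site membership and accumulated evidence."""

    specimen_id: str
    site_id: str = ""
    source: Source = Source.FORAGING
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    morph: Optional[MorphMeasurements] = None
    sequences: dict[str, str] = field(default_factory=dict)
    calls: list[MarkerCall] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise DomainError(
                f"latitude {self.latitude} outside [-90, 90] for {self.specimen_id}"
            )
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise DomainError(
                f"longitude {self.longitude} outside [-180, 180] for {self.specimen_id}"
            )

    def mitotype_call(self) -> Optional[MarkerCall]:
        """First confident call that resolves to an African/European mitotype.

        RFLP and COI-SNP calls take precedence over spacer lineage.
        """
        order = (Marker.CYTB_RFLP, Marker.COI_SNP, Marker.SPACER_LINEAGE)
        for marker in order:
            for c in self.calls:
                if c.marker is marker and c.confident and c.mitotype is not None:
                    return c
        return None


@dataclass(frozen=True)
class SiteSummary:
    """Per-site mitotype tally: how many of the sampled bees were African."""

    site_id: str
    n_bees: int
    n_african_mito: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_african_mito <= self.n_bees:
            raise DomainError(
                f"site {self.site_id}: n_african_mito={self.n_african_mito} "
                f"outside [0, n_bees={self.n_bees}]"
            )

    @property
    def mixed(self) -> bool:
        """True iff the site holds both mitotype classes."""
        return 0 < self.n_african_mito < self.n_bees
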
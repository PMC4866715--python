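"""Domain types for rock-shell biomonitoring surveys.

The unit conventions used throughout the package:

* lengths in mm, masses in g
* tissue organotin concentrations in μg (compound) kg⁻¹ dry weight
* site coordinates in decimal degrees, distances in km

All types validate their invariants on construction and raise
:class:`ValidationError` with a message naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The six organotin analytes, in the canonical reporting order:
#: butyltins (mono-, di-, tri-) then phenyltins (mono-, di-, tri-).
ANALYTES = ("MBT", "DBT", "TBT", "MPT", "DPT", "TPT")

BUTYLTINS = ("MBT", "DBT", "TBT")
PHENYLTINS = ("MPT", "DPT", "TPT")

#: Survey epochs for the long-term comparison. The 2004–06 surveys are
#: treated as a single baseline epoch, as the paired trend tests require
#: one value per site per epoch.
EPOCHS = ("2004-06", "2010", "2015")

VDS_STAGES = tuple(range(7))  # imposex vas-deferens-sequence stages 0–6


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


@dataclass(frozen=True)
class IndividualRecord:
    """One snail: sex, morphometrics and (for females) the imposex stage.

    ``vds_stage`` is the vas deferens sequence stage 0–6 and is carried by
    females only; males must leave it ``None``. ``penis_length_mm`` may be 0
    (imposex females without a measurable penis).
    """

    site_id: str
    year: int
    sex: str  # "female" | "male"
    shell_length_mm: float
    fresh_tissue_g: Optional[float] = None
    dry_shell_g: Optional[float] = None
    penis_length_mm: float = 0.0
    vds_stage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.shell_length_mm > 0:
            raise ValidationError(f"shell_length_mm must be > 0, got {self.shell_length_mm}")
        for name in ("fresh_tissue_g", "dry_shell_g"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0 when present, got {v}")
        if self.penis_length_mm < 0:
            raise ValidationError(f"penis_length_mm must be >= 0, got {self.penis_length_mm}")
        if self.sex == "male":
            if self.vds_stage is not None:
                raise ValidationError("males carry no vds_stage")
        elif self.vds_stage is not None and self.vds_stage not in VDS_STAGES:
            raise ValidationError(f"vds_stage must be in 0..6, got {self.vds_stage}")


@dataclass
class SiteSurvey:
    """All individuals collected at one site in one survey year."""

    site_id: str
    site_name: str
    year: int
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    distance_km: Optional[float] = None
    individuals: list[IndividualRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.distance_km is not None and self.distance_km < 0:
            raise ValidationError(f"distance_km must be >= 0, got {self.distance_km}")
        if not self.individuals:
            raise ValidationError(f"site {self.site_id}: at least one individual required")

    @property
    def females(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.sex == "female"]

    @property
    def males(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.sex == "male"]


@dataclass(frozen=True)
class SiteImposexSummary:
    """Site-level imposex indices — one row of the survey summary table."""

    site_id: str
    year: int
    mean_vdsi: float
    median_vdsi: float
    pct_imposex: float
    pct_sterile_female: float
    rpsi: float
    condition_index: Optional[float]
    n_females: int
    n_males: int

    def __post_init__(self) -> None:
        if not 0 <= self.mean_vdsi <= 6:
            raise ValidationError(f"mean_vdsi must lie in [0, 6], got {self.mean_vdsi}")
        for name in ("pct_imposex", "pct_sterile_female"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")
        if self.rpsi < 0:
            raise ValidationError(f"rpsi must be >= 0, got {self.rpsi}")
        if self.condition_index is not None and not 0 < self.condition_index < 100:
            raise ValidationError(
                f"condition_index must lie in (0, 100), got {self.condition_index}"
            )


@dataclass(frozen=True)
class AnalyteMeasurement:
    """One concentration with its left-censoring state.

    For censored entries ``value`` is meaningless until a substitution
    policy has been applied; the detection limit must be present.
    """

    value: float
    censored: bool = False
    detection_limit: Optional[float] = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.detection_limit is None or not self.detection_limit > 0:
                raise ValidationError("censored entry requires a positive detection_limit")
        elif self.value < 0:
            raise ValidationError(f"uncensored value must be >= 0, got {self.value}")


@dataclass
class AnalytePanel:
    """Six organotin concentrations for one tissue replicate (μg kg⁻¹ dw)."""

    site_id: str
    year: int
    replicate_id: str
    measurements: dict[str, AnalyteMeasurement]

    def __post_init__(self) -> None:
        missing = set(ANALYTES) - set(self.measurements)
        if missing:
            raise ValidationError(f"panel missing analytes: {sorted(missing)}")
        extra = set(self.measurements) - set(ANALYTES)
        if extra:
            raise ValidationError(f"panel has unknown analytes: {sorted(extra)}")

    def value(self, analyte: str) -> float:
        return self.measurements[analyte].value


@dataclass(frozen=True)
class ToxicityEndpoint:
    """A literature chronic/sub-chronic tissue-residue endpoint (PNETC)."""

    species: str
    group: str  # "BT" | "PT"
    endpoint_ug_kg_dw: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("BT", "PT"):
            raise ValidationError(f"group must be 'BT' or 'PT', got {self.group!r}")
        if not self.endpoint_ug_kg_dw > 0:
            raise ValidationError(
                f"endpoint_ug_kg_dw must be > 0, got {self.endpoint_ug_kg_dw}"
            )
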
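"""Imposex indices for neogastropod biomonitoring surveys.

Imposex — the superimposition of male sex organs on females induced by
organotin exposure — is scored per female as a vas deferens sequence (VDS)
stage 0–6. Site-level indices computed here:

* **VDSI**: mean (and median) VDS stage over the females of a site.
* **RPSI**: 100 × (mean female penis length)³ / (mean male penis length)³.
  The cubed ratio approximates a bulk (volume) comparison.
* **% imposex**: share of females at any stage > 0.
* **% sterile females**: share at stages blocking reproduction (VDS ≥ 5 by
  default: the vas deferens tissue occludes the vulva).
* **condition index**: fresh tissue weight × 100 / (fresh tissue weight +
  dry shell mass), a body-condition covariate.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from .records import IndividualRecord, SiteImposexSummary, SiteSurvey, ValidationError


@dataclass(frozen=True)
class ImposexConfig:
    """Scoring conventions for the site-level indices.

    sterile_stage_threshold
        VDS stage at or above which a female is counted sterile (default 5).
    rpsi_exponent
        Power applied to the penis-length ratio (default 3, the classical
        volume-like convention).
    """

    sterile_stage_threshold: int = 5
    rpsi_exponent: int = 3

    def __post_init__(self) -> None:
        if self.sterile_stage_threshold not in range(1, 7):
            raise ValidationError(
                f"sterile_stage_threshold must be in 1..6, got {self.sterile_stage_threshold}"
            )
        if self.rpsi_exponent < 1:
            raise ValidationError(f"rpsi_exponent must be >= 1, got {self.rpsi_exponent}")


DEFAULT_CONFIG = ImposexConfig()


def _female_stages(females: Sequence[IndividualRecord]) -> list[int]:
    stages = [f.vds_stage for f in females if f.sex == "female" and f.vds_stage is not None]
    if not stages:
        raise ValidationError("no females with a VDS stage")
    return stages


def vdsi(females: Sequence[IndividualRecord]) -> tuple[float, float]:
    """Mean and median VDS stage over the staged females."""
    stages = _female_stages(females)
    return statistics.fmean(stages), float(statistics.median(stages))


def rpsi(
    females: Sequence[IndividualRecord],
    males: Sequence[IndividualRecord],
    config: ImposexConfig = DEFAULT_CONFIG,
) -> float:
    """Relative penis size index (%).

    Females without a measurable penis contribute length 0 to the female
    mean, which keeps the index defined at low-imposex sites.
    """
    male_lengths = [m.penis_length_mm for m in males if m.sex == "male"]
    if not male_lengths:
        raise ValidationError("RPSI requires at least one male")
    mean_male = statistics.fmean(male_lengths)
    if mean_male <= 0:
        raise ValidationError("RPSI undefined: mean male penis length is 0")
    female_lengths = [f.penis_length_mm for f in females if f.sex == "female"]
    if not female_lengths:
        raise ValidationError("RPSI requires at least one female")
    mean_female = statistics.fmean(female_lengths)
    return 100.0 * (mean_female / mean_male) ** config.rpsi_exponent


def pct_imposex(females: Sequence[IndividualRecord]) -> float:
    """Percentage of females displaying any imposex (VDS stage > 0)."""
    stages = _female_stages(females)
    return 100.0 * sum(s > 0 for s in stages) / len(stages)


def pct_sterile(
    females: Sequence[IndividualRecord],
    config: ImposexConfig = DEFAULT_CONFIG,
) -> float:
    """Percentage of females at or above the sterile stage threshold."""
    stages = _female_stages(females)
    thr = config.sterile_stage_threshold
    return 100.0 * sum(s >= thr for s in stages) / len(stages)


def condition_index(fresh_tissue_g: float, dry_shell_g: float) -> float:
    """Body condition: fresh tissue weight × 100 / (fresh tissue + dry shell)."""
    if not fresh_tissue_g > 0 or not dry_shell_g > 0:
        raise ValidationError("condition index requires positive masses")
    return 100.0 * fresh_tissue_g / (fresh_tissue_g + dry_shell_g)


def summarize_site(
    survey: SiteSurvey, config: ImposexConfig = DEFAULT_CONFIG
) -> SiteImposexSummary:
    """Compute the full row of site-level indices from individual records.

    The condition index is averaged over every individual carrying both
    masses (``None`` if no individual does).
    """
    females, males = survey.females, survey.males
    mean_v, median_v = vdsi(females)
    cis = [
        condition_index(i.fresh_tissue_g, i.dry_shell_g)
        for i in survey.individuals
        if i.fresh_tissue_g is not None and i.dry_shell_g is not None
    ]
    return SiteImposexSummary(
        site_id=survey.site_id,
        year=survey.year,
        mean_vdsi=mean_v,
        median_vdsi=median_v,
        pct_imposex=pct_imposex(females),
        pct_sterile_female=pct_sterile(females, config),
        rpsi=rpsi(females, males, config),
        condition_index=statistics.fmean(cis) if cis else None,
        n_females=len(females),
        n_males=len(males),
    )
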
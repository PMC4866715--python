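"""Organotin panel arithmetic: censoring substitution, totals, composition,
degradation indices, and dry-weight → wet-weight tin-equivalent conversion.

Concentrations are μg of the organotin *compound* (cation basis) per kg dry
tissue. Tin equivalents multiply by the tin mass fraction of the cation;
the dry→wet basis change multiplies by the dry-matter fraction
(1 − moisture). Degradation indices (mono + di)/tri flag aged (> 1) versus
recent (< 1) inputs of the parent tri-substituted compound.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Literal, NamedTuple, Optional

import pandas as pd

from .records import (
    ANALYTES,
    BUTYLTINS,
    PHENYLTINS,
    AnalyteMeasurement,
    AnalytePanel,
    ValidationError,
)

#: Atomic mass of tin (g mol⁻¹).
SN_MASS = 118.71

#: Molecular masses of the organotin cations, g mol⁻¹
#: (e.g. TBT = (C4H9)3Sn+ = 118.71 + 3 × 57.115).
CATION_MASS = {
    "MBT": 175.87,
    "DBT": 232.97,
    "TBT": 290.06,
    "MPT": 195.86,
    "DPT": 272.97,
    "TPT": 350.03,
}

#: Default tissue moisture fraction used for the dw → ww basis change.
DEFAULT_MOISTURE = 0.80

CensoringPolicy = Literal["half_dl", "zero", "dl"]


def tin_fraction(analyte: str) -> float:
    """Mass fraction of tin in the organotin cation."""
    try:
        return SN_MASS / CATION_MASS[analyte]
    except KeyError:
        raise ValidationError(f"unknown analyte {analyte!r}") from None


@dataclass(frozen=True)
class DegradationIndices:
    """(mono + di)/tri degradation ratios; None when the parent compound
    concentration is zero (ratio undefined, not an error)."""

    bdi: Optional[float]
    pdi: Optional[float]


class PanelTotals(NamedTuple):
    total_ots: float
    total_bts: float
    total_pts: float


def substitute_censored(panel: AnalytePanel, policy: CensoringPolicy = "half_dl") -> AnalytePanel:
    """Replace below-detection-limit entries per the substitution policy.

    ``half_dl`` (DL/2, the common ecotox convention), ``zero`` or ``dl``.
    Censoring flags are retained so downstream analyses can still identify
    substituted values.
    """
    factors = {"half_dl": 0.5, "zero": 0.0, "dl": 1.0}
    if policy not in factors:
        raise ValidationError(f"unknown censoring policy {policy!r}")
    new = {}
    for a, m in panel.measurements.items():
        if m.censored:
            if m.detection_limit is None:
                raise ValidationError(f"{a}: censored entry without a detection limit")
            new[a] = AnalyteMeasurement(
                value=factors[policy] * m.detection_limit,
                censored=True,
                detection_limit=m.detection_limit,
            )
        else:
            new[a] = m
    return AnalytePanel(
        site_id=panel.site_id, year=panel.year,
        replicate_id=panel.replicate_id, measurements=new,
    )


def total_ots(panel: AnalytePanel) -> PanelTotals:
    """Totals over the six analytes, the three butyltins and the three
    phenyltins (μg kg⁻¹ dw). Censoring must already be substituted."""
    for a in ANALYTES:
        if panel.value(a) < 0:
            raise ValidationError(f"{a}: negative concentration")
    bts = sum(panel.value(a) for a in BUTYLTINS)
    pts = sum(panel.value(a) for a in PHENYLTINS)
    return PanelTotals(total_ots=bts + pts, total_bts=bts, total_pts=pts)


def composition_pct(panel: AnalytePanel, analyte: str) -> float:
    """Share (%) of one analyte in the panel's total organotins."""
    if analyte not in ANALYTES:
        raise ValidationError(f"unknown analyte {analyte!r}")
    total = total_ots(panel).total_ots
    if total <= 0:
        raise ValidationError("composition undefined: total organotins is 0")
    return 100.0 * panel.value(analyte) / total


def degradation_indices(panel: AnalytePanel) -> DegradationIndices:
    """BDI = (MBT + DBT)/TBT and PDI = (MPT + DPT)/TPT."""
    tbt, tpt = panel.value("TBT"), panel.value("TPT")
    bdi = None if tbt == 0 else (panel.value("MBT") + panel.value("DBT")) / tbt
    pdi = None if tpt == 0 else (panel.value("MPT") + panel.value("DPT")) / tpt
    return DegradationIndices(bdi=bdi, pdi=pdi)


def dw_to_ww_sn(
    value_ug_kg_dw: float,
    analyte: str,
    moisture_fraction: float = DEFAULT_MOISTURE,
) -> float:
    """Convert μg compound kg⁻¹ dry weight to μg Sn kg⁻¹ wet weight."""
    if value_ug_kg_dw < 0:
        raise ValidationError("concentration must be >= 0")
    if not 0 <= moisture_fraction < 1:
        raise ValidationError(f"moisture_fraction must lie in [0, 1), got {moisture_fraction}")
    return value_ug_kg_dw * tin_fraction(analyte) * (1.0 - moisture_fraction)


def site_chemistry_table(
    panels: Iterable[AnalytePanel],
    policy: CensoringPolicy = "half_dl",
    moisture_fraction: float = DEFAULT_MOISTURE,
) -> pd.DataFrame:
    """Per-site-year chemistry summary: replicate means of each analyte and
    of the totals, degradation indices and Sn wet-weight equivalents.

    Tissue replicates (pools of individuals) are averaged per site-year;
    all downstream site-level analyses consume these means.
    """
    panels = [substitute_censored(p, policy) for p in panels]
    if not panels:
        raise ValidationError("no panels supplied")
    groups: dict[tuple[str, int], list[AnalytePanel]] = {}
    for p in panels:
        groups.setdefault((p.site_id, p.year), []).append(p)
    rows = []
    for (site_id, year), reps in sorted(groups.items()):
        row: dict = {"site_id": site_id, "year": year, "n_replicates": len(reps)}
        for a in ANALYTES:
            row[a] = statistics.fmean(p.value(a) for p in reps)
        mean_panel = AnalytePanel(
            site_id=site_id, year=year, replicate_id="mean",
            measurements={a: AnalyteMeasurement(value=row[a]) for a in ANALYTES},
        )
        totals = total_ots(mean_panel)
        row["total_ots"] = totals.total_ots
        row["total_bts"] = totals.total_bts
        row["total_pts"] = totals.total_pts
        deg = degradation_indices(mean_panel)
        row["bdi"], row["pdi"] = deg.bdi, deg.pdi
        row["tpt_pct"] = (
            composition_pct(mean_panel, "TPT") if totals.total_ots > 0 else None
        )
        row["tbt_sn_ww"] = dw_to_ww_sn(row["TBT"], "TBT", moisture_fraction)
        row["tpt_sn_ww"] = dw_to_ww_sn(row["TPT"], "TPT", moisture_fraction)
        row["total_ots_sn_ww"] = sum(
            dw_to_ww_sn(row[a], a, moisture_fraction) for a in ANALYTES
        )
        rows.append(row)
    return pd.DataFrame(rows)
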
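"""CSV readers/writers for surveys, tissue panels, toxicity endpoints and
summaries, plus the packaged site-level index table for the three survey
epochs.

All files are comma-separated UTF-8 with a mandatory header row, "." as the
decimal mark, and the empty string for missing values. Readers validate
every row and report failures with 1-based data-row numbers.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    ANALYTES,
    AnalyteMeasurement,
    AnalytePanel,
    IndividualRecord,
    SiteImposexSummary,
    SiteSurvey,
    ToxicityEndpoint,
    ValidationError,
)

SURVEY_COLUMNS = (
    "site_id", "site_name", "year", "lat", "lon", "distance_km", "animal_id",
    "sex", "shell_length_mm", "fresh_tissue_g", "dry_shell_g",
    "penis_length_mm", "vds_stage",
)
TISSUE_COLUMNS = (
    "site_id", "year", "replicate_id", "analyte", "value_ug_kg_dw",
    "censored", "detection_limit",
)
TOXICITY_COLUMNS = ("species", "group", "endpoint_ug_kg_dw", "source")
SUMMARY_COLUMNS = (
    "site_id", "year", "mean_vdsi", "median_vdsi", "pct_imposex",
    "pct_sterile_female", "rpsi", "condition_index", "n_females", "n_males",
)

_FIXTURE = "table1_site_indices.csv"


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class RowError(ValueError):
    """One or more data rows failed validation."""


def _check_header(found: Sequence[str] | None, expected: Sequence[str], path) -> None:
    if found is None:
        raise SchemaError(f"{path}: empty file, expected header {list(expected)}")
    missing = [c for c in expected if c not in found]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _opt_float(cell: str, column: str, row: int) -> float | None:
    if cell is None or cell.strip() == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowError(f"row {row}: non-numeric value {cell!r} in column '{column}'")


def _req_float(cell: str, column: str, row: int) -> float:
    v = _opt_float(cell, column, row)
    if v is None:
        raise RowError(f"row {row}: missing required value in column '{column}'")
    return v


def read_survey(path) -> list[SiteSurvey]:
    """Read individual-level survey rows, grouped into one
    :class:`SiteSurvey` per (site, year).

    Rows violating a domain invariant abort the read with a message giving
    the 1-based data-row number and the offending field.
    """
    groups: dict[tuple[str, int], dict] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SURVEY_COLUMNS, path)
        n = 0
        for i, row in enumerate(reader, start=1):
            n += 1
            try:
                year = int(_req_float(row["year"], "year", i))
                stage_cell = row.get("vds_stage", "")
                stage = None
                if stage_cell is not None and stage_cell.strip() != "":
                    stage_f = _req_float(stage_cell, "vds_stage", i)
                    if stage_f != int(stage_f) or not 0 <= stage_f <= 6:
                        raise RowError(
                            f"row {i}: invalid 'vds_stage' {stage_cell!r} (must be an integer 0..6)"
                        )
                    stage = int(stage_f)
                rec = IndividualRecord(
                    site_id=row["site_id"].strip(),
                    year=year,
                    sex=row["sex"].strip(),
                    shell_length_mm=_req_float(row["shell_length_mm"], "shell_length_mm", i),
                    fresh_tissue_g=_opt_float(row["fresh_tissue_g"], "fresh_tissue_g", i),
                    dry_shell_g=_opt_float(row["dry_shell_g"], "dry_shell_g", i),
                    penis_length_mm=_req_float(row["penis_length_mm"], "penis_length_mm", i),
                    vds_stage=stage,
                )
            except (RowError, ValidationError) as exc:
                errors.append(f"row {i}: {exc}" if not str(exc).startswith("row") else str(exc))
                continue
            key = (rec.site_id, rec.year)
            g = groups.setdefault(
                key,
                {
                    "site_name": row.get("site_name", "").strip(),
                    "lat": _opt_float(row.get("lat", ""), "lat", i),
                    "lon": _opt_float(row.get("lon", ""), "lon", i),
                    "distance_km": _opt_float(row.get("distance_km", ""), "distance_km", i),
                    "individuals": [],
                },
            )
            g["individuals"].append(rec)
    if errors:
        raise RowError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    if n == 0:
        raise RowError(f"{path}: no data rows")
    return [
        SiteSurvey(
            site_id=site_id,
            site_name=g["site_name"],
            year=year,
            latitude=g["lat"],
            longitude=g["lon"],
            distance_km=g["distance_km"],
            individuals=g["individuals"],
        )
        for (site_id, year), g in sorted(groups.items())
    ]


def write_survey(surveys: Iterable[SiteSurvey], path) -> None:
    surveys = list(surveys)
    if not surveys:
        raise ValueError("no surveys to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SURVEY_COLUMNS)
        for s in surveys:
            for k, ind in enumerate(s.individuals, start=1):
                w.writerow([
                    s.site_id, s.site_name, s.year,
                    _fmt(s.latitude), _fmt(s.longitude), _fmt(s.distance_km),
                    k, ind.sex, _fmt(ind.shell_length_mm),
                    _fmt(ind.fresh_tissue_g), _fmt(ind.dry_shell_g),
                    _fmt(ind.penis_length_mm),
                    "" if ind.vds_stage is None else ind.vds_stage,
                ])


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v == int(v):
        return repr(v)
    return repr(v) if isinstance(v, float) else str(v)


def read_tissue(path) -> list[AnalytePanel]:
    """Read long-format tissue concentrations into six-analyte panels."""
    cells: dict[tuple[str, int, str], dict[str, AnalyteMeasurement]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, TISSUE_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            censored = row["censored"].strip().lower() in ("1", "true", "yes")
            dl = _opt_float(row["detection_limit"], "detection_limit", i)
            value = _opt_float(row["value_ug_kg_dw"], "value_ug_kg_dw", i)
            if not censored and value is None:
                raise RowError(
                    f"row {i}: missing required value in column 'value_ug_kg_dw'")
            try:
                m = AnalyteMeasurement(
                    value=0.0 if value is None else value,
                    censored=censored,
                    detection_limit=dl,
                )
            except ValidationError as exc:
                raise RowError(f"row {i}: {exc}")
            key = (row["site_id"].strip(), int(_req_float(row["year"], "year", i)),
                   row["replicate_id"].strip())
            analyte = row["analyte"].strip()
            if analyte not in ANALYTES:
                raise RowError(f"row {i}: unknown analyte {analyte!r}")
            cells.setdefault(key, {})[analyte] = m
    panels = []
    for (site_id, year, rep), meas in sorted(cells.items()):
        panels.append(AnalytePanel(site_id=site_id, year=year, replicate_id=rep,
                                   measurements=meas))
    return panels


def write_tissue(panels: Iterable[AnalytePanel], path) -> None:
    panels = list(panels)
    if not panels:
        raise ValueError("no panels to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TISSUE_COLUMNS)
        for p in panels:
            for a in ANALYTES:
                m = p.measurements[a]
                w.writerow([
                    p.site_id, p.year, p.replicate_id, a,
                    _fmt(m.value), "true" if m.censored else "false",
                    _fmt(m.detection_limit),
                ])


def read_toxicity(path) -> list[ToxicityEndpoint]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, TOXICITY_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                out.append(ToxicityEndpoint(
                    species=row["species"].strip(),
                    group=row["group"].strip(),
                    endpoint_ug_kg_dw=_req_float(
                        row["endpoint_ug_kg_dw"], "endpoint_ug_kg_dw", i),
                    source=row.get("source", "").strip(),
                ))
            except ValidationError as exc:
                raise RowError(f"row {i}: {exc}")
    return out


def write_toxicity(endpoints: Iterable[ToxicityEndpoint], path) -> None:
    endpoints = list(endpoints)
    if not endpoints:
        raise ValueError("no endpoints to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TOXICITY_COLUMNS)
        for e in endpoints:
            w.writerow([e.species, e.group, _fmt(e.endpoint_ug_kg_dw), e.source])


def write_summaries(summaries: Iterable[SiteImposexSummary], path) -> None:
    """Write site summaries; full-precision repr so the file round-trips."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SUMMARY_COLUMNS)
        for s in summaries:
            w.writerow([
                s.site_id, s.year, _fmt(s.mean_vdsi), _fmt(s.median_vdsi),
                _fmt(s.pct_imposex), _fmt(s.pct_sterile_female), _fmt(s.rpsi),
                _fmt(s.condition_index), s.n_females, s.n_males,
            ])


def read_summaries(path) -> list[SiteImposexSummary]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SUMMARY_COLUMNS, path)
        for i, row in enumerate(reader, start=1):
            try:
                out.append(SiteImposexSummary(
                    site_id=row["site_id"].strip(),
                    year=int(_req_float(row["year"], "year", i)),
                    mean_vdsi=_req_float(row["mean_vdsi"], "mean_vdsi", i),
                    median_vdsi=_req_float(row["median_vdsi"], "median_vdsi", i),
                    pct_imposex=_req_float(row["pct_imposex"], "pct_imposex", i),
                    pct_sterile_female=_req_float(
                        row["pct_sterile_female"], "pct_sterile_female", i),
                    rpsi=_req_float(row["rpsi"], "rpsi", i),
                    condition_index=_opt_float(
                        row["condition_index"], "condition_index", i),
                    n_females=int(_req_float(row["n_females"], "n_females", i)),
                    n_males=int(_req_float(row["n_males"], "n_males", i)),
                ))
            except ValidationError as exc:
                raise RowError(f"row {i}: {exc}")
    return out


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged site-level index table for the three survey epochs.

    Returns a tidy frame with one row per (site_id, epoch):
    ``site_id, site_name, epoch, mean_vdsi, median_vdsi, pct_imposex,
    pct_sterile, rpsi, condition_index, distance_km``.
    Epochs are ``"2004-06"``, ``"2010"`` and ``"2015"``. Cells the surveys
    did not evaluate (and the one 2010 site where the shore had been
    developed) are NaN.
    """
    with resources.files("otbiomon.data").joinpath(_FIXTURE).open("r") as fh:
        wide = pd.read_csv(fh)
    frames = []
    for suffix, epoch in (("2004_06", "2004-06"), ("2010", "2010"), ("2015", "2015")):
        cols = {
            "mean_vdsi": f"mean_vdsi_{suffix}",
            "median_vdsi": f"median_vdsi_{suffix}",
            "pct_imposex": f"pct_imposex_{suffix}",
            "pct_sterile": f"pct_sterile_{suffix}",
            "rpsi": f"rpsi_{suffix}",
        }
        sub = wide[["site_id", "site_name", "distance_km"]].copy()
        sub["epoch"] = epoch
        for out_col, in_col in cols.items():
            sub[out_col] = wide[in_col]
        ci_col = f"condition_index_{suffix}"
        sub["condition_index"] = wide[ci_col] if ci_col in wide else float("nan")
        frames.append(sub)
    tidy = pd.concat(frames, ignore_index=True)
    order = ["site_id", "site_name", "epoch", "mean_vdsi", "median_vdsi",
             "pct_imposex", "pct_sterile", "rpsi", "condition_index",
             "distance_km"]
    return tidy[order].sort_values(["epoch", "site_id"]).reset_index(drop=True)
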
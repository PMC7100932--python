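"""Cohort I/O, decoding, inclusion criteria and subcohort selection.

Reads per-patient tables shaped like the study's de-identified dataset (CSV or
XLSX with named sheets), decodes coded fields (resection grade 3/2/1 =
GTR/STR/biopsy; MGMT NA/0/1/2 = not available/undetermined/unmethylated/
methylated), converts volumes (mm^3) to spherically equivalent radii (mm)
where radii are absent, and applies the study's inclusion and
pseudoprogression-subcohort rules with an audit trail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .pi_model import volume_to_radius

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "CohortAudit",
    "CohortSchemaError",
    "RowParseError",
    "ConfigError",
    "DEFAULT_COLUMN_MAP",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "apply_inclusion_criteria",
    "select_pseudoprogression_subcohort",
    "write_audit",
    "INCLUSION_CRITERIA",
]


class CohortSchemaError(ValueError):
    """Required columns missing from the input table."""


class RowParseError(ValueError):
    """A row contained an unparseable value."""


class ConfigError(ValueError):
    """Unknown criterion or malformed configuration."""


MGMT_CODES = {None: "not_available", 0: "undetermined", 1: "unmethylated", 2: "methylated"}
MGMT_NAMES = {v: k for k, v in MGMT_CODES.items()}
RESECTION_CODES = {3: "GTR", 2: "STR", 1: "biopsy", None: "unknown"}
RESECTION_NAMES = {v: k for k, v in RESECTION_CODES.items()}


@dataclass
class PatientRecord:
    """One subject: demographics, imaging radii, treatment counts, outcomes.

    Radii are spherically equivalent radii in mm; times are day offsets from
    the pre-adjuvant image (intermediate observations and the post-adjuvant
    image), never raw calendar dates.
    """

    id: str
    sex: str = "unknown"  # male | female | unknown
    age_years: float | None = None
    cycles_tmz: int | None = None
    pre_t1gd_radius_mm: float | None = None
    pre_t2flair_radius_mm: float | None = None
    post_t1gd_radius_mm: float | None = None
    intermediate_t1gd: list[tuple[float, float]] = field(default_factory=list)
    post_t1gd_offset_days: float | None = None
    d_over_rho_mm2: float | None = None
    os_days: float | None = None
    death_observed: bool = False
    progression_days: float | None = None
    mgmt: str = "not_available"
    resection: str = "unknown"
    xrt_end_to_post_image_days: float | None = None
    other_therapy_flag: bool = False
    diagnosis: str = "primary_gbm"
    concurrent_xrt_tmz: bool = True

    def __post_init__(self) -> None:
        if self.sex not in {"male", "female", "unknown"}:
            raise ValueError(f"record {self.id}: bad sex {self.sex!r}")
        if self.mgmt not in MGMT_NAMES:
            raise ValueError(f"record {self.id}: bad MGMT status {self.mgmt!r}")
        if self.resection not in RESECTION_NAMES:
            raise ValueError(f"record {self.id}: bad resection {self.resection!r}")
        if self.os_days is not None and self.os_days <= 0:
            raise ValueError(f"record {self.id}: os_days must be positive")
        for name in ("pre_t1gd_radius_mm", "pre_t2flair_radius_mm", "post_t1gd_radius_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"record {self.id}: {name} negative")
        self.intermediate_t1gd = sorted(self.intermediate_t1gd)


@dataclass
class CohortAudit:
    stage_labels: list[str]
    stage_counts: list[int]
    excluded_ids_per_stage: list[list[str]]

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.stage_counts, self.stage_counts[1:])):
            raise ValueError("audit counts must be non-increasing")


#: Logical field -> default column name in input tables.  Users may override
#: any entry (e.g. via a YAML column map) to track journal-file drift.
DEFAULT_COLUMN_MAP = {
    "id": "id",
    "sex": "sex",
    "age_years": "age",
    "cycles_tmz": "cycles_tmz",
    "pre_t1gd_radius_mm": "pre_t1gd_radius_mm",
    "pre_t2flair_radius_mm": "pre_t2flair_radius_mm",
    "post_t1gd_radius_mm": "post_t1gd_radius_mm",
    "pre_t1gd_volume_mm3": "pre_t1gd_volume_mm3",
    "pre_t2flair_volume_mm3": "pre_t2flair_volume_mm3",
    "post_t1gd_volume_mm3": "post_t1gd_volume_mm3",
    "intermediate_t1gd": "intermediate_t1gd",
    "post_t1gd_offset_days": "post_t1gd_offset_days",
    "d_over_rho_mm2": "d_over_rho_mm2",
    "os_days": "os_days",
    "death_observed": "death_observed",
    "progression_days": "progression_days",
    "mgmt": "mgmt_status",
    "resection": "resection_grade",
    "xrt_end_to_post_image_days": "xrt_gap_days",
    "other_therapy_flag": "other_therapy",
}

_REQUIRED = ["id", "sex", "age_years", "cycles_tmz", "os_days", "death_observed"]
# radius fields that may instead arrive as volumes
_RADIUS_OR_VOLUME = [
    ("pre_t1gd_radius_mm", "pre_t1gd_volume_mm3"),
    ("pre_t2flair_radius_mm", "pre_t2flair_volume_mm3"),
    ("post_t1gd_radius_mm", "post_t1gd_volume_mm3"),
]

_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
    "": "unknown", "unknown": "unknown", "na": "unknown",
}


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v.strip().lower() in {"", "na", "nan", "none"}:
        return True
    return False


def _to_float(v, rid: str, col: str) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        raise RowParseError(f"record {rid}: cannot parse {col}={v!r} as a number") from None


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "t", "yes", "y"}
    return bool(v)


def _decode_mgmt(v, rid: str) -> str:
    if _is_missing(v):
        return "not_available"
    if isinstance(v, str) and v.strip().lower() in MGMT_NAMES:
        return v.strip().lower()
    code = int(_to_float(v, rid, "mgmt"))
    if code not in (0, 1, 2):
        raise RowParseError(f"record {rid}: bad MGMT code {v!r}")
    return MGMT_CODES[code]


def _decode_resection(v, rid: str) -> str:
    if _is_missing(v):
        return "unknown"
    if isinstance(v, str) and v.strip() in RESECTION_NAMES:
        return v.strip()
    code = int(_to_float(v, rid, "resection"))
    if code not in (1, 2, 3):
        raise RowParseError(f"record {rid}: bad resection code {v!r}")
    return RESECTION_CODES[code]


def _parse_intermediates(v, rid: str) -> list[tuple[float, float]]:
    """Parse 'day:radius;day:radius' strings into an ordered observation list."""
    if _is_missing(v):
        return []
    if isinstance(v, list):
        return [(float(t), float(r)) for t, r in v]
    out = []
    for chunk in str(v).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            t, r = chunk.split(":")
            out.append((float(t), float(r)))
        except ValueError:
            raise RowParseError(
                f"record {rid}: cannot parse intermediate observation {chunk!r} "
                "(expected 'days:radius_mm')"
            ) from None
    return sorted(out)


def _radius_from_row(row, rid, rmap, radius_field, volume_field):
    rcol, vcol = rmap.get(radius_field), rmap.get(volume_field)
    radius = row.get(rcol) if rcol in row.index else None
    volume = row.get(vcol) if vcol in row.index else None
    has_r, has_v = not _is_missing(radius), not _is_missing(volume)
    if has_r:
        r = _to_float(radius, rid, rcol)
        if has_v:
            rv = volume_to_radius(_to_float(volume, rid, vcol))
            if abs(r - rv) >= 0.1:
                logger.warning(
                    "record %s: %s=%.3f mm disagrees with volume-derived %.3f mm; keeping radius",
                    rid, radius_field, r, rv,
                )
        return r
    if has_v:
        return volume_to_radius(_to_float(volume, rid, vcol))
    return None


def read_cohort(
    path,
    sheet: str = "cohort",
    column_map: dict[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a cohort table (CSV, or XLSX sheet) into validated PatientRecords.

    Coded fields are decoded per the dataset key; radii may be given directly
    in mm or derived from volumes in mm^3 (radii win when both are present,
    with a consistency warning beyond 0.1 mm).
    """
    rmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        rmap.update(column_map)
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return []
    if df.empty:
        return []
    missing = [rmap[f] for f in _REQUIRED if rmap[f] not in df.columns]
    for radius_field, volume_field in _RADIUS_OR_VOLUME:
        if rmap[radius_field] not in df.columns and rmap[volume_field] not in df.columns:
            missing.append(f"{rmap[radius_field]} (or {rmap[volume_field]})")
    if missing:
        raise CohortSchemaError(f"missing required columns: {', '.join(sorted(missing))}")

    records = []
    for _, row in df.iterrows():
        rid = str(row[rmap["id"]])
        sex_raw = str(row[rmap["sex"]]).strip().lower() if not _is_missing(row[rmap["sex"]]) else ""
        sex = _SEX_ALIASES.get(sex_raw)
        if sex is None:
            raise RowParseError(f"record {rid}: bad sex {row[rmap['sex']]!r}")

        def opt_float(fieldname):
            col = rmap.get(fieldname)
            if col not in row.index or _is_missing(row[col]):
                return None
            return _to_float(row[col], rid, col)

        rec = PatientRecord(
            id=rid,
            sex=sex,
            age_years=opt_float("age_years"),
            cycles_tmz=(None if _is_missing(row[rmap["cycles_tmz"]])
                        else int(_to_float(row[rmap["cycles_tmz"]], rid, "cycles_tmz"))),
            pre_t1gd_radius_mm=_radius_from_row(row, rid, rmap, *_RADIUS_OR_VOLUME[0]),
            pre_t2flair_radius_mm=_radius_from_row(row, rid, rmap, *_RADIUS_OR_VOLUME[1]),
            post_t1gd_radius_mm=_radius_from_row(row, rid, rmap, *_RADIUS_OR_VOLUME[2]),
            intermediate_t1gd=_parse_intermediates(
                row.get(rmap["intermediate_t1gd"]), rid),
            post_t1gd_offset_days=opt_float("post_t1gd_offset_days"),
            d_over_rho_mm2=opt_float("d_over_rho_mm2"),
            os_days=opt_float("os_days"),
            death_observed=_to_bool(row[rmap["death_observed"]]),
            progression_days=opt_float("progression_days"),
            mgmt=_decode_mgmt(row.get(rmap["mgmt"]), rid),
            resection=_decode_resection(row.get(rmap["resection"]), rid),
            xrt_end_to_post_image_days=opt_float("xrt_end_to_post_image_days"),
            other_therapy_flag=_to_bool(row.get(rmap["other_therapy_flag"], False)),
        )
        records.append(rec)
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Serialize records to a flat table using the default column names."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "sex": r.sex,
            "age": r.age_years,
            "cycles_tmz": r.cycles_tmz,
            "pre_t1gd_radius_mm": r.pre_t1gd_radius_mm,
            "pre_t2flair_radius_mm": r.pre_t2flair_radius_mm,
            "post_t1gd_radius_mm": r.post_t1gd_radius_mm,
            "intermediate_t1gd": ";".join(f"{t:g}:{rad:g}" for t, rad in r.intermediate_t1gd),
            "post_t1gd_offset_days": r.post_t1gd_offset_days,
            "d_over_rho_mm2": r.d_over_rho_mm2,
            "os_days": r.os_days,
            "death_observed": int(r.death_observed),
            "progression_days": r.progression_days,
            "mgmt_status": MGMT_NAMES[r.mgmt],
            "resection_grade": RESECTION_NAMES[r.resection],
            "xrt_gap_days": r.xrt_end_to_post_image_days,
            "other_therapy": int(r.other_therapy_flag),
        })
    return pd.DataFrame(rows)


def write_cohort(records: list[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion criteria (A-E) and subcohorts
# ---------------------------------------------------------------------------

def _crit_primary_gbm(r):
    return r.diagnosis == "primary_gbm"

def _crit_treatment(r):
    return (r.resection != "unknown" and r.concurrent_xrt_tmz
            and r.cycles_tmz is not None and r.cycles_tmz >= 1)

def _crit_demographics(r):
    return r.age_years is not None and r.sex != "unknown" and r.os_days is not None

def _crit_no_other_therapy(r):
    return not r.other_therapy_flag

def _crit_imaging(r):
    return (r.pre_t1gd_radius_mm is not None
            and r.pre_t2flair_radius_mm is not None
            and r.post_t1gd_radius_mm is not None)


#: name -> (label, predicate); order mirrors the study's A-E staging.
INCLUSION_CRITERIA = {
    "primary_gbm": ("A: primary GBM diagnosis", _crit_primary_gbm),
    "treatment": ("B: resection + concurrent XRT/TMZ + >=1 adjuvant cycle", _crit_treatment),
    "demographics": ("C: age, sex, survival and treatment dates available", _crit_demographics),
    "no_other_therapy": ("D: no other therapies before first adjuvant cycle", _crit_no_other_therapy),
    "imaging": ("E: pre- and post-adjuvant imaging available", _crit_imaging),
}


def apply_inclusion_criteria(
    records: list[PatientRecord],
    config: dict[str, bool] | list[str] | None = None,
) -> tuple[list[PatientRecord], CohortAudit]:
    """Filter a cohort through the enabled inclusion criteria, with an audit trail.

    ``config`` may be a list of criterion names to enable, or a name->bool
    mapping; by default all five criteria are enabled.  Unknown names raise
    ConfigError.
    """
    if config is None:
        enabled = list(INCLUSION_CRITERIA)
    elif isinstance(config, dict):
        unknown = set(config) - set(INCLUSION_CRITERIA)
        if unknown:
            raise ConfigError(f"unknown inclusion criteria: {sorted(unknown)}")
        enabled = [k for k in INCLUSION_CRITERIA if config.get(k, False)]
    else:
        unknown = set(config) - set(INCLUSION_CRITERIA)
        if unknown:
            raise ConfigError(f"unknown inclusion criteria: {sorted(unknown)}")
        enabled = [k for k in INCLUSION_CRITERIA if k in config]

    labels = ["all records"]
    counts = [len(records)]
    excluded: list[list[str]] = [[]]
    kept = list(records)
    for name in enabled:
        label, pred = INCLUSION_CRITERIA[name]
        dropped = [r.id for r in kept if not pred(r)]
        kept = [r for r in kept if pred(r)]
        labels.append(label)
        counts.append(len(kept))
        excluded.append(dropped)
        logger.info("inclusion %s: %d retained (%d excluded)", label, len(kept), len(dropped))
    return kept, CohortAudit(labels, counts, excluded)


def select_pseudoprogression_subcohort(
    records: list[PatientRecord], min_days: float = 84.0
) -> list[PatientRecord]:
    """Subjects with strictly more than ``min_days`` between XRT end and post-adjuvant image.

    Default 84 days = 12 weeks; the boundary itself is excluded (strict
    inequality).  Records lacking the gap field are skipped with a warning.
    """
    if min_days < 0:
        raise ValueError("min_days must be non-negative")
    out = []
    for r in records:
        if r.xrt_end_to_post_image_days is None:
            warnings.warn(f"record {r.id}: no XRT-to-post-image gap; skipped", stacklevel=2)
            continue
        if r.xrt_end_to_post_image_days > min_days:
            out.append(r)
    return out


def write_audit(audit: CohortAudit, path) -> None:
    pd.DataFrame({
        "stage": audit.stage_labels,
        "n": audit.stage_counts,
        "excluded_ids": [";".join(ids) for ids in audit.excluded_ids_per_stage],
    }).to_csv(path, index=False)
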
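"""Volumetric response metrics, responder classification and invasiveness tertiles.

All percent changes are stored as fractions (-1 = -100%) and formatted as
percentages only at reporting boundaries.  Response is computed on spherically
equivalent radii; because the volume <-> radius map is monotone, the sign of
the change (and hence the responder split) is identical whether radii or
volumes are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .pi_model import PIParameters, estimate_d_over_rho

__all__ = [
    "ResponseMetrics",
    "InvasivenessGrouping",
    "pct_change_t1gd",
    "classify_responder",
    "find_nadir",
    "proportion_adjuvant_to_nadir",
    "assign_invasiveness_tertiles",
    "compute_response_metrics",
    "cohort_metrics",
    "TERTILE_LABELS",
]

TERTILE_LABELS = ("nodular", "moderate", "diffuse")


@dataclass(frozen=True)
class ResponseMetrics:
    pct_change_t1gd: float
    pct_change_t1gd_nadir: float | None
    nadir_radius_mm: float | None
    proportion_adjuvant_to_nadir: float | None
    responder: bool


@dataclass(frozen=True)
class InvasivenessGrouping:
    """Rank-based tertile split of per-patient D/rho values."""

    labels: list[str]            # per input value, in input order
    bounds: list[tuple[float, float]]  # (min, max) of each group, ascending
    group_sizes: tuple[int, int, int]


def pct_change_t1gd(pre_radius_mm: float, post_radius_mm: float) -> float:
    """Fractional change (post - pre)/pre of the T1Gd radius; bounded below by -1."""
    if pre_radius_mm <= 0:
        raise ValueError(
            f"pre-adjuvant radius must be positive (got {pre_radius_mm}); "
            "percent change is undefined and the subject must be excluded"
        )
    if post_radius_mm < 0:
        raise ValueError("post-adjuvant radius must be non-negative")
    return (post_radius_mm - pre_radius_mm) / pre_radius_mm


def classify_responder(pct_change: float) -> str:
    """'responder' iff the T1Gd abnormality strictly decreased.

    An exactly-zero change is classified non_responder with a warning: a
    decrease is read strictly, and ties are not expected in measured volumes.
    """
    if pct_change < -1:
        raise ValueError(f"fractional change below -1 is impossible, got {pct_change}")
    if pct_change < 0:
        return "responder"
    if pct_change == 0:
        warnings.warn("pct change exactly 0: classified non_responder", stacklevel=2)
    return "non_responder"


def find_nadir(
    pre: tuple[float, float],
    series: list[tuple[float, float]],
    post: tuple[float, float],
) -> tuple[float, float]:
    """Smallest T1Gd radius after the pre-adjuvant image and at/before the post image.

    Candidates are the intermediate observations plus the post-adjuvant
    observation; ties break to the earliest time.  With no intermediates the
    nadir is the post observation itself.
    """
    t0, _ = pre
    t_end, _ = post
    candidates = [obs for obs in series if t0 < obs[0] < t_end] + [post]
    if not candidates:
        raise ValueError("no nadir candidates")
    return min(candidates, key=lambda obs: (obs[1], obs[0]))


def proportion_adjuvant_to_nadir(t0: float, t_nadir: float, t_end: float) -> float:
    """Fraction of the adjuvant period elapsed at the nadir image (1 = at post image)."""
    if t_end <= t0:
        raise ValueError("post-adjuvant time must exceed pre-adjuvant time")
    if not (t0 <= t_nadir <= t_end):
        raise ValueError("nadir time must lie within the adjuvant period")
    return (t_nadir - t0) / (t_end - t0)


def assign_invasiveness_tertiles(d_over_rho) -> InvasivenessGrouping:
    """Split patients into evenly sized nodular / moderate / diffuse groups by D/rho.

    Rank-based (stable sort): group sizes are as equal as n allows, with any
    remainder going to the lower groups first; ties across a cut stay with the
    lower group.  Bounds report each group's observed (min, max) in mm^2.
    """
    values = np.asarray(list(d_over_rho), dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"need at least 3 values to form tertiles, got {n}")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("D/rho values must be finite and non-negative")
    q, r = divmod(n, 3)
    sizes = tuple(q + (1 if i < r else 0) for i in range(3))
    order = np.argsort(values, kind="stable")
    labels = [""] * n
    bounds = []
    start = 0
    for label, size in zip(TERTILE_LABELS, sizes):
        idx = order[start:start + size]
        for i in idx:
            labels[int(i)] = label
        bounds.append((float(values[idx].min()), float(values[idx].max())))
        start += size
    return InvasivenessGrouping(labels, bounds, sizes)


def compute_response_metrics(record: PatientRecord) -> ResponseMetrics:
    """Per-patient response metrics from radii and (optional) intermediate images.

    Time offsets are in days from the pre-adjuvant image.  When the
    post-adjuvant day offset is unknown and intermediates exist, nadir metrics
    that need a time axis degrade to None rather than being imputed.
    """
    if record.pre_t1gd_radius_mm is None or record.post_t1gd_radius_mm is None:
        raise ValueError(f"record {record.id}: pre/post T1Gd radii required")
    pct = pct_change_t1gd(record.pre_t1gd_radius_mm, record.post_t1gd_radius_mm)
    responder = classify_responder(pct) == "responder"

    t_end = record.post_t1gd_offset_days
    if t_end is None and not record.intermediate_t1gd:
        # no intermediates: nadir is the post image; the time axis is immaterial
        return ResponseMetrics(pct, pct, record.post_t1gd_radius_mm, 1.0, responder)
    if t_end is None:
        warnings.warn(
            f"record {record.id}: intermediate images but unknown post-image day; "
            "nadir timing not computed", stacklevel=2,
        )
        return ResponseMetrics(pct, None, None, None, responder)
    pre = (0.0, record.pre_t1gd_radius_mm)
    post = (float(t_end), record.post_t1gd_radius_mm)
    t_nadir, r_nadir = find_nadir(pre, record.intermediate_t1gd, post)
    pct_nadir = pct_change_t1gd(record.pre_t1gd_radius_mm, r_nadir)
    prop = proportion_adjuvant_to_nadir(0.0, t_nadir, float(t_end))
    return ResponseMetrics(pct, pct_nadir, r_nadir, prop, responder)


def cohort_metrics(
    records: list[PatientRecord],
    params: PIParameters | None = None,
    *,
    tertile_on: str = "d_over_rho",
) -> pd.DataFrame:
    """Per-patient metrics table: response, responder flag, D/rho and tertile label.

    D/rho is taken from the record when present, else recomputed from the
    pre-adjuvant radii via the closed form.  Subjects lacking what a given
    metric needs get NaN there rather than being imputed.
    """
    params = params or PIParameters()
    rows = []
    for r in records:
        m = compute_response_metrics(r)
        dr = r.d_over_rho_mm2
        if dr is None and (r.pre_t1gd_radius_mm is not None
                           and r.pre_t2flair_radius_mm is not None):
            dr = estimate_d_over_rho(
                r.pre_t1gd_radius_mm, r.pre_t2flair_radius_mm, params).d_over_rho_mm2
        rows.append({
            "id": r.id,
            "sex": r.sex,
            "age": r.age_years,
            "cycles_tmz": r.cycles_tmz,
            "pre_t1gd_radius_mm": r.pre_t1gd_radius_mm,
            "pre_t2flair_radius_mm": r.pre_t2flair_radius_mm,
            "post_t1gd_radius_mm": r.post_t1gd_radius_mm,
            "d_over_rho_mm2": dr,
            "pct_change_t1gd": m.pct_change_t1gd,
            "pct_change_t1gd_nadir": m.pct_change_t1gd_nadir,
            "nadir_radius_mm": m.nadir_radius_mm,
            "proportion_adjuvant_to_nadir": m.proportion_adjuvant_to_nadir,
            "responder": m.responder,
            "os_days": r.os_days,
            "death_observed": r.death_observed,
            "progression_days": r.progression_days,
            "mgmt_status": r.mgmt,
        })
    df = pd.DataFrame(rows)
    df["tertile"] = pd.NA
    have = df["d_over_rho_mm2"].notna()
    if have.sum() >= 3:
        grouping = assign_invasiveness_tertiles(df.loc[have, "d_over_rho_mm2"].to_numpy())
        df.loc[have, "tertile"] = grouping.labels
        df.attrs["tertile_bounds"] = grouping.bounds
        df.attrs["tertile_sizes"] = grouping.group_sizes
    return df
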
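"""Event derivation, time-in-target statistics and counting-process data.

Events
------
* *Severe flare*: a pBILAG-2004 grade of A or B in any organ domain at a
  visit.  By default every such visit is an event dated at the visit
  (per-visit accounting); a ``new_episode`` mode counts only A/B visits
  whose previous visit had no A/B grade.
* *New damage*: an increase in the SLICC/ACR damage index (SDI) since
  the previous visit of at least ``threshold`` units (default 1 — the
  SDI is integer-valued and any increase is new irreversible damage;
  a threshold of 2 is available for the stricter reading).

Gap-time layout
---------------
The Prentice–Williams–Peterson gap-time model is a Cox model stratified
by event order in which the clock restarts after each event.  The
counting-process rows produced here carry, per patient and event-order
stratum k, intervals (start, stop] on the gap-time scale (days since the
(k-1)-th event, or since follow-up start for k=1), an event flag on the
final row of the stratum, and time-varying covariates held constant
within rows (rows are split at every covariate-change date).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import DAYS_PER_MONTH, VisitRecord, visits_by_patient
from .targets import AttainmentResult

__all__ = [
    "EventSeries",
    "GapTimeRow",
    "TimeInTarget",
    "detect_severe_flare",
    "detect_new_damage",
    "derive_event_series",
    "time_in_target",
    "dichotomize_above_median",
    "build_gap_time_dataset",
    "venn_counts",
    "non_attainment_reasons",
    "gap_time_dataset_for_cohort",
]


@dataclass
class EventSeries:
    patient_id: str
    event_type: str  # "severe_flare" | "new_damage"
    event_dates: list[dt.date]
    follow_up_start: dt.date
    follow_up_end: dt.date

    def __post_init__(self) -> None:
        dates = self.event_dates
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"event dates must be strictly increasing for {self.patient_id}"
            )
        for d in dates:
            if not (self.follow_up_start < d <= self.follow_up_end):
                raise ValueError(
                    f"event outside follow-up window for patient "
                    f"{self.patient_id}: {d}"
                )


@dataclass
class GapTimeRow:
    patient_id: str
    stratum: int  # event order k >= 1
    start: float  # days, gap-time scale, interval (start, stop]
    stop: float
    event: bool
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class TimeInTarget:
    patient_id: str
    target: str
    time_to_first_attainment_months: float | None
    cumulative_months_in_target: float
    percent_time_in_target: float
    above_median: bool = False


def detect_severe_flare(visit: VisitRecord) -> bool | None:
    """A/B grade in any pBILAG domain; None when grades are missing."""
    if not visit.pbilag_grades:
        return None
    return any(g in ("A", "B") for g in visit.pbilag_grades.values())


def detect_new_damage(sdi_now: int, sdi_prev: int, threshold: int = 1) -> bool:
    """SDI increase of at least ``threshold`` units since the last visit."""
    if sdi_now < sdi_prev:
        warnings.warn(
            f"decreasing SDI ({sdi_prev} -> {sdi_now}); treated as no event",
            stacklevel=2,
        )
        return False
    return sdi_now - sdi_prev >= threshold


def derive_event_series(
    visits: list[VisitRecord],
    event_type: str,
    flare_mode: str = "per_visit",
    damage_threshold: int = 1,
) -> dict[str, EventSeries]:
    """Per-patient event series over the follow-up window.

    Follow-up runs from a patient's first to last visit.  Events are
    dated at visits; a qualifying first visit is not an event (it falls
    at gap time zero, before any at-risk interval).
    """
    if event_type not in ("severe_flare", "new_damage"):
        raise ValueError(f"unknown event type {event_type!r}")
    out = {}
    for pid, pvisits in visits_by_patient(visits).items():
        dates = []
        prev = pvisits[0]
        for v in pvisits[1:]:
            if event_type == "severe_flare":
                hit = bool(detect_severe_flare(v))
                if flare_mode == "new_episode":
                    hit = hit and not bool(detect_severe_flare(prev))
            else:
                hit = detect_new_damage(v.sdi, prev.sdi, damage_threshold)
            if hit:
                dates.append(v.visit_date)
            prev = v
        out[pid] = EventSeries(
            patient_id=pid,
            event_type=event_type,
            event_dates=dates,
            follow_up_start=pvisits[0].visit_date,
            follow_up_end=pvisits[-1].visit_date,
        )
    return out


def time_in_target(
    visits: list[VisitRecord],
    attainment: list[AttainmentResult],
) -> TimeInTarget:
    """Time-to-target and time-in-target for one patient and one target.

    State-carry-forward attribution: the patient is in target from an
    attaining visit until the next visit (or end of follow-up, i.e. the
    last visit).  A single-visit patient has zero follow-up and percent
    defined as 0.
    """
    visits = sorted(visits, key=lambda v: v.visit_date)
    verdicts = {r.visit_date: r.attained for r in attainment}
    target = attainment[0].target if attainment else ""
    pid = visits[0].patient_id
    total_days = (visits[-1].visit_date - visits[0].visit_date).days
    in_days = 0
    first_date = None
    for a, b in zip(visits, visits[1:]):
        if verdicts.get(a.visit_date, False):
            in_days += (b.visit_date - a.visit_date).days
    for v in visits:
        if verdicts.get(v.visit_date, False):
            first_date = v.visit_date
            break
    ttf = (
        None
        if first_date is None
        else (first_date - visits[0].visit_date).days / DAYS_PER_MONTH
    )
    percent = 0.0 if total_days == 0 else 100.0 * in_days / total_days
    return TimeInTarget(
        patient_id=pid,
        target=target,
        time_to_first_attainment_months=ttf,
        cumulative_months_in_target=in_days / DAYS_PER_MONTH,
        percent_time_in_target=percent,
    )


def dichotomize_above_median(records: list[TimeInTarget]) -> list[TimeInTarget]:
    """Flag patients whose percent time in target is strictly above the
    median of ever-attaining patients.

    Non-attainers and patients at or below the median are grouped
    together (flag False).  Returns new records with ``above_median``
    set (input order preserved).
    """
    attainers = [
        r.percent_time_in_target
        for r in records
        if r.time_to_first_attainment_months is not None
    ]
    if not attainers:
        med = np.inf
    else:
        med = float(np.median(attainers))
    out = []
    for r in records:
        flag = (
            r.time_to_first_attainment_months is not None
            and r.percent_time_in_target > med
        )
        out.append(
            TimeInTarget(
                patient_id=r.patient_id,
                target=r.target,
                time_to_first_attainment_months=r.time_to_first_attainment_months,
                cumulative_months_in_target=r.cumulative_months_in_target,
                percent_time_in_target=r.percent_time_in_target,
                above_median=flag,
            )
        )
    return out


def build_gap_time_dataset(
    events: EventSeries,
    covariate_path: list[tuple[dt.date, dict[str, float]]] | None = None,
) -> list[GapTimeRow]:
    """Counting-process rows for one patient's recurrent events.

    ``covariate_path`` is a step function: (date, values) pairs, sorted,
    each taking effect at its date (carry-forward until the next).  Rows
    are split at every covariate-change date; the k-th event closes
    stratum k and restarts the gap clock; the final stratum is censored
    at follow-up end.  Zero-length segments (changes coinciding with an
    event or gap start) are dropped.
    """
    path = sorted(covariate_path or [], key=lambda t: t[0])
    boundaries = [events.follow_up_start, *events.event_dates]
    if events.follow_up_end > boundaries[-1]:
        segments = list(zip(boundaries, boundaries[1:] + [events.follow_up_end]))
        terminal_event = [True] * len(events.event_dates) + [False]
    else:  # follow-up ends exactly at the last event
        segments = list(zip(boundaries[:-1], boundaries[1:]))
        terminal_event = [True] * len(events.event_dates)

    def values_at(date: dt.date) -> dict[str, float]:
        current: dict[str, float] = {}
        for d, vals in path:
            if d <= date:
                current.update(vals)
            else:
                break
        return current

    rows: list[GapTimeRow] = []
    for k, ((g0, g1), ev) in enumerate(zip(segments, terminal_event), start=1):
        cuts = sorted({d for d, _ in path if g0 < d < g1} | {g0, g1})
        for a, b in zip(cuts, cuts[1:]):
            rows.append(
                GapTimeRow(
                    patient_id=events.patient_id,
                    stratum=k,
                    start=float((a - g0).days),
                    stop=float((b - g0).days),
                    event=ev and b == g1,
                    covariates=values_at(a),
                )
            )
    return rows


def venn_counts(
    attainment: list[AttainmentResult], targets: list[str]
) -> dict[frozenset[str], int]:
    """Per-visit counts of every attainment intersection region.

    Keys are frozensets of target names attained at the visit (the empty
    frozenset counts visits attaining none).  All listed targets must
    have verdicts for exactly the same visits.
    """
    per_visit: dict[tuple, set[str]] = {}
    seen: dict[str, set[tuple]] = {t: set() for t in targets}
    for r in attainment:
        if r.target not in seen:
            continue
        key = (r.patient_id, r.visit_date)
        seen[r.target].add(key)
        per_visit.setdefault(key, set())
        if r.attained:
            per_visit[key].add(r.target)
    visit_sets = list(seen.values())
    if any(s != visit_sets[0] for s in visit_sets[1:]):
        raise ValueError("mismatched visit sets across targets")
    counts: dict[frozenset[str], int] = {}
    for attained in per_visit.values():
        key = frozenset(attained)
        counts[key] = counts.get(key, 0) + 1
    return counts


def non_attainment_reasons(
    attainment: list[AttainmentResult],
    visits: list[VisitRecord],
    definition,
) -> dict[str, int]:
    """Visits failing each criterion despite passing the activity gate.

    Qualifying visits have SLEDAI-2K <= 4 for low-disease-activity
    targets or cSLEDAI = 0 for remission targets; a visit failing
    several criteria counts under each.
    """
    from .cohort import csledai, sledai2k_total
    from .targets import CRITERIA

    by_key = {(v.patient_id, v.visit_date): v for v in visits}
    counts = {c: 0 for c in CRITERIA if c != "activity"}
    for r in attainment:
        if r.target != definition.name or r.attained:
            continue
        v = by_key[(r.patient_id, r.visit_date)]
        if definition.activity_rule == "csledai_zero":
            if csledai(v) != 0:
                continue
        elif sledai2k_total(v) > 4:
            continue
        for c in r.failed_criteria:
            if c in counts:
                counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# Cohort-level assembly used by the inference stage
# ---------------------------------------------------------------------------

def gap_time_dataset_for_cohort(
    patients,
    visits: list[VisitRecord],
    attainment: list[AttainmentResult],
    target: str,
    event_type: str = "severe_flare",
    flare_mode: str = "per_visit",
    damage_threshold: int = 1,
    extra_patient_covariates: dict[str, dict[str, float]] | None = None,
    include_standard_covariates: bool = True,
) -> list[GapTimeRow]:
    """Assemble PWP rows for the whole cohort with the standard covariates.

    Standard covariates: per-visit target-attainment state
    (carry-forward), disease duration > 1 year (time-varying, crossing
    at diagnosis + 365 days), ethnicity indicators (African/Caribbean
    reference) and the current SDI.  ``extra_patient_covariates`` maps
    covariate name -> {patient_id: value} for additional time-fixed
    terms.
    """
    verdicts = {
        (r.patient_id, r.visit_date): float(r.attained)
        for r in attainment
        if r.target == target
    }
    events = derive_event_series(
        visits, event_type, flare_mode=flare_mode, damage_threshold=damage_threshold
    )
    pat = {p.patient_id: p for p in patients}
    rows: list[GapTimeRow] = []
    for pid, pvisits in visits_by_patient(visits).items():
        p = pat[pid]
        fixed: dict[str, float] = {}
        if include_standard_covariates:
            fixed["eth_white_british"] = float(p.ethnicity == "white_british")
            fixed["eth_asian"] = float(p.ethnicity == "asian")
            fixed["eth_other"] = float(p.ethnicity == "other")
        for name, table in (extra_patient_covariates or {}).items():
            fixed[name] = table[pid]
        path: list[tuple[dt.date, dict[str, float]]] = []
        for i, v in enumerate(pvisits):
            vals = {"in_target": verdicts.get((pid, v.visit_date), 0.0)}
            if include_standard_covariates:
                vals["sdi"] = float(v.sdi)
                vals["duration_gt_1y"] = float(
                    (v.visit_date - p.diagnosis_date).days > 365
                )
            if i == 0:
                vals.update(fixed)
            path.append((v.visit_date, vals))
        if include_standard_covariates:
            crossing = p.diagnosis_date + dt.timedelta(days=366)
            if pvisits[0].visit_date < crossing <= pvisits[-1].visit_date:
                path.append((crossing, {"duration_gt_1y": 1.0}))
        rows.extend(build_gap_time_dataset(events[pid], path))
    return rows
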
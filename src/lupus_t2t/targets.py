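"""Treat-to-target state definitions and the per-visit classification engine.

Five targets are shipped:

* ``cLLDAS`` — childhood lupus low disease activity state: SLEDAI-2K <= 4
  with no major active organ involvement, no new activity, PGA <= 1,
  prednisolone <= min(0.15 mg/kg/day x weight, 7.5 mg/day), no IV
  methylprednisolone, tolerated maintenance immunosuppression (changes
  for non-activity reasons such as growth or side effects permitted).
* ``LLDAS`` — the adult state: identical but with a flat 7.5 mg/day
  prednisolone cap.
* ``cCR`` — childhood clinical remission on steroids: cSLEDAI = 0,
  PGA <= 0.5, prednisolone <= min(0.10 mg/kg/day x weight, 5 mg/day).
* ``DORIS2021`` — adult remission: cSLEDAI = 0, PGA <= 0.5,
  prednisolone <= 5 mg/day.
* ``cCR0`` — childhood clinical remission off steroids: as cCR but
  prednisolone must be exactly zero (and no IV pulses).

The paediatric steroid rules are two-limb: a weight-based rate limb and
an absolute cap, combined as ``min(rate x weight, cap)``.  The two limbs
cross at ``cap / rate`` kg — 50 kg for both shipped rules — below which
the weight-based limb is the stricter constraint.  This is why an
imputed weight can only change a verdict in patients under 50 kg, and
why paediatric attainment is nested inside adult attainment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .cohort import VisitRecord, csledai, sledai2k_total

__all__ = [
    "DOSE_TOL",
    "MAJOR_ORGAN_DOMAINS",
    "CRITERIA",
    "SteroidRule",
    "TargetDefinition",
    "AttainmentResult",
    "UndefinedRuleError",
    "steroid_threshold",
    "crossover_weight",
    "has_new_activity",
    "classify_visit",
    "classify_cohort",
    "default_definitions",
    "definitions_to_yaml",
    "definitions_from_yaml",
]

# absolute tolerance for dose comparisons (decimal dose entry)
DOSE_TOL = 1e-9

# SLEDAI organ domains counted as "major active organ involvement"
MAJOR_ORGAN_DOMAINS = frozenset(
    {"cardiopulmonary", "cns", "fever", "renal", "vasculitis"}
)

# fixed evaluation/reporting order of the criteria
CRITERIA = (
    "activity",
    "new_activity",
    "pga",
    "steroid_dose",
    "iv_methylpred",
    "med_stability",
    "insufficient_data",
)


class UndefinedRuleError(ValueError):
    """The requested quantity is undefined for this steroid rule."""


class _InsufficientData(Exception):
    pass


@dataclass(frozen=True)
class SteroidRule:
    """A prednisolone-dose criterion.

    Either ``require_zero`` (remission off steroids), or at least one of a
    weight-based rate limb (mg/kg/day) and an absolute cap (mg/day); when
    both limbs are present the threshold is ``min(rate x weight, cap)``.
    """

    rate_mg_per_kg_day: float | None = None
    cap_mg_day: float | None = None
    require_zero: bool = False
    forbid_iv_methylpred: bool = True

    def __post_init__(self) -> None:
        if self.require_zero:
            if self.rate_mg_per_kg_day is not None or self.cap_mg_day is not None:
                raise ValueError("require_zero excludes rate/cap limbs")
        elif self.rate_mg_per_kg_day is None and self.cap_mg_day is None:
            raise ValueError(
                "steroid rule needs a rate, a cap, or require_zero"
            )


@dataclass(frozen=True)
class TargetDefinition:
    name: str
    activity_rule: str  # "sledai_le4_no_major_organ" | "csledai_zero"
    pga_max: float
    steroid_rule: SteroidRule
    require_no_new_activity: bool = False
    med_stability_mode: str = "strict"  # "strict" | "paediatric_reason_aware"
    major_organ_domains: frozenset[str] = MAJOR_ORGAN_DOMAINS

    def __post_init__(self) -> None:
        if self.activity_rule not in ("sledai_le4_no_major_organ", "csledai_zero"):
            raise ValueError(f"unknown activity rule {self.activity_rule!r}")
        if self.med_stability_mode not in ("strict", "paediatric_reason_aware"):
            raise ValueError(f"unknown stability mode {self.med_stability_mode!r}")


@dataclass
class AttainmentResult:
    patient_id: str
    visit_date: object
    target: str
    attained: bool
    failed_criteria: list[str] = field(default_factory=list)


def default_definitions() -> dict[str, TargetDefinition]:
    """The five shipped target definitions (paediatric and adult)."""
    return {
        "cLLDAS": TargetDefinition(
            name="cLLDAS",
            activity_rule="sledai_le4_no_major_organ",
            pga_max=1.0,
            steroid_rule=SteroidRule(rate_mg_per_kg_day=0.15, cap_mg_day=7.5),
            require_no_new_activity=True,
            med_stability_mode="paediatric_reason_aware",
        ),
        "LLDAS": TargetDefinition(
            name="LLDAS",
            activity_rule="sledai_le4_no_major_organ",
            pga_max=1.0,
            steroid_rule=SteroidRule(cap_mg_day=7.5),
            require_no_new_activity=True,
            med_stability_mode="paediatric_reason_aware",
        ),
        "cCR": TargetDefinition(
            name="cCR",
            activity_rule="csledai_zero",
            pga_max=0.5,
            steroid_rule=SteroidRule(rate_mg_per_kg_day=0.10, cap_mg_day=5.0),
            med_stability_mode="paediatric_reason_aware",
        ),
        "DORIS2021": TargetDefinition(
            name="DORIS2021",
            activity_rule="csledai_zero",
            pga_max=0.5,
            steroid_rule=SteroidRule(cap_mg_day=5.0),
            med_stability_mode="paediatric_reason_aware",
        ),
        "cCR0": TargetDefinition(
            name="cCR0",
            activity_rule="csledai_zero",
            pga_max=0.5,
            steroid_rule=SteroidRule(require_zero=True),
            med_stability_mode="paediatric_reason_aware",
        ),
    }


def steroid_threshold(weight_kg: float | None, rule: SteroidRule) -> float | None:
    """Maximum permitted prednisolone dose (mg/day) under ``rule``.

    Returns 0.0 for a zero-requirement rule; ``None`` (insufficient data)
    when the rule has a weight-based limb but the weight is unknown.
    """
    if rule.require_zero:
        return 0.0
    if rule.rate_mg_per_kg_day is None:
        return rule.cap_mg_day
    if weight_kg is None:
        return None
    limb = rule.rate_mg_per_kg_day * weight_kg
    if rule.cap_mg_day is None:
        return limb
    return min(limb, rule.cap_mg_day)


def crossover_weight(rule: SteroidRule) -> float:
    """Weight (kg) below which the mg/kg limb is stricter than the cap.

    Defined as ``cap / rate``; 50 kg for both shipped paediatric rules
    (7.5/0.15 and 5.0/0.10).
    """
    if rule.require_zero or rule.rate_mg_per_kg_day is None or rule.cap_mg_day is None:
        raise UndefinedRuleError("crossover requires both a rate and a cap")
    if rule.rate_mg_per_kg_day <= 0:
        raise UndefinedRuleError("crossover requires a positive rate")
    return rule.cap_mg_day / rule.rate_mg_per_kg_day


def has_new_activity(visit: VisitRecord, prior: VisitRecord | None) -> bool:
    """True iff some SLEDAI item scores at this visit but not at the prior one.

    With no prior visit the "no new features" criterion is vacuously
    satisfied (returns False).
    """
    if prior is None:
        return False
    if prior.visit_date > visit.visit_date:
        raise ValueError(
            f"prior visit ({prior.visit_date}) is later than visit "
            f"({visit.visit_date}) for patient {visit.patient_id}"
        )
    for name, score in visit.sledai_items.items():
        if score > 0 and prior.sledai_items.get(name, 0) <= 0:
            return True
    return False


def _check_activity(visit: VisitRecord, definition: TargetDefinition) -> bool:
    from .cohort import SLEDAI_ITEMS

    if definition.activity_rule == "csledai_zero":
        return csledai(visit) == 0
    if sledai2k_total(visit) > 4:
        return False
    for name, score in visit.sledai_items.items():
        if score <= 0:
            continue
        item = SLEDAI_ITEMS.get(name)
        domain = item.domain if item is not None else "other"
        if domain in definition.major_organ_domains:
            return False
    return True


def classify_visit(
    visit: VisitRecord,
    prior: VisitRecord | None,
    definition: TargetDefinition,
) -> AttainmentResult:
    """Evaluate one visit against one target definition.

    Every failed criterion is collected, not only the first; a missing
    required input (PGA, or weight under a rate-bearing steroid rule)
    contributes ``insufficient_data`` and the visit is not attained.
    """
    failed: list[str] = []
    insufficient = False

    if not _check_activity(visit, definition):
        failed.append("activity")

    if definition.require_no_new_activity and has_new_activity(visit, prior):
        failed.append("new_activity")

    if visit.pga is None:
        insufficient = True
    elif visit.pga > definition.pga_max + DOSE_TOL:
        failed.append("pga")

    rule = definition.steroid_rule
    threshold = steroid_threshold(visit.weight_kg, rule)
    if threshold is None:
        insufficient = True
    elif rule.require_zero:
        if visit.prednisolone_mg_day > DOSE_TOL:
            failed.append("steroid_dose")
    elif visit.prednisolone_mg_day > threshold + DOSE_TOL:
        failed.append("steroid_dose")

    if rule.forbid_iv_methylpred and visit.iv_methylpred:
        failed.append("iv_methylpred")

    if definition.med_stability_mode == "strict":
        stable = visit.imsn_change == "none"
    else:
        stable = visit.imsn_change in ("none", "non_activity_reason")
    if not stable:
        failed.append("med_stability")

    if insufficient:
        failed.append("insufficient_data")

    failed.sort(key=CRITERIA.index)
    return AttainmentResult(
        patient_id=visit.patient_id,
        visit_date=visit.visit_date,
        target=definition.name,
        attained=not failed,
        failed_criteria=failed,
    )


def classify_cohort(
    patients,
    visits,
    definitions: dict[str, TargetDefinition] | None = None,
) -> list[AttainmentResult]:
    """Classify every visit against every definition.

    The prior visit for the "no new features" rule is the immediately
    preceding visit of the same patient in date order.
    """
    from .cohort import visits_by_patient

    if definitions is None:
        definitions = default_definitions()
    results: list[AttainmentResult] = []
    for pid, pvisits in visits_by_patient(visits).items():
        prior: VisitRecord | None = None
        for visit in pvisits:
            for definition in definitions.values():
                results.append(classify_visit(visit, prior, definition))
            prior = visit
    return results


# ---------------------------------------------------------------------------
# Declarative import/export so users can add variant targets
# ---------------------------------------------------------------------------

def definitions_to_yaml(definitions: dict[str, TargetDefinition]) -> str:
    payload = {}
    for name, d in definitions.items():
        entry = dataclasses.asdict(d)
        entry["major_organ_domains"] = sorted(d.major_organ_domains)
        payload[name] = entry
    return yaml.safe_dump(payload, sort_keys=True)


def definitions_from_yaml(text: str) -> dict[str, TargetDefinition]:
    payload = yaml.safe_load(text)
    out = {}
    for name, entry in payload.items():
        rule = SteroidRule(**entry.pop("steroid_rule"))
        entry.pop("name", None)
        domains = frozenset(entry.pop("major_organ_domains", MAJOR_ORGAN_DOMAINS))
        out[name] = TargetDefinition(
            name=name, steroid_rule=rule, major_organ_domains=domains, **entry
        )
    return out


def describe_definition(d: TargetDefinition) -> dict[str, str]:
    """Human-readable criteria table for one definition."""
    rule = d.steroid_rule
    if rule.require_zero:
        steroid = "No prednisolone"
    elif rule.rate_mg_per_kg_day is not None:
        steroid = (
            f"Prednisolone dose of {rule.rate_mg_per_kg_day} mg/kg/day or a "
            f"maximum of {rule.cap_mg_day} mg/day"
        )
    else:
        steroid = f"Prednisolone dose of <={rule.cap_mg_day} mg/day"
    if rule.forbid_iv_methylpred:
        steroid += " and no intravenous methylprednisolone"
    activity = (
        "Clinical SLEDAI score equal to 0"
        if d.activity_rule == "csledai_zero"
        else "SLEDAI-2K score <=4 with no major active organ involvement "
        "(" + ", ".join(sorted(d.major_organ_domains)) + ")"
    )
    out = {
        "activity": activity,
        "pga": f"Physician global assessment score of <={d.pga_max}",
        "steroid": steroid,
        "med_stability": (
            "Tolerated standard maintenance immunosuppressive drugs or biologic "
            "agents"
            + (
                "; changes not due to disease activity (side effects, adherence, "
                "growth, building up to target dose) permitted"
                if d.med_stability_mode == "paediatric_reason_aware"
                else ""
            )
        ),
    }
    if d.require_no_new_activity:
        out["new_activity"] = (
            "No new features of lupus activity compared with previous assessment"
        )
    return out
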
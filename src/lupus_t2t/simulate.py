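"""Synthetic longitudinal childhood-SLE cohort generator.

The generator emulates the statistical structure the downstream analysis
consumes, calibrated to the UK national childhood-lupus cohort the
pipeline was designed around: ~430 patients, a median of ~10 visits over
~2 years of follow-up, median diagnosis age ~12.8 years, 83.5% female,
~26% missing weight measurements, severe flares at ~43% of follow-up
visits, and flare/damage hazards that depend multiplicatively on whether
the patient is currently in a treat-to-target state.

Event mechanism
---------------
Severe flares occur in continuous time with intensity::

    baseline_flare_rate * flare_hr_in_target ** state   (events / person-year)

where ``state`` is 1 when the patient was in the latent target state at
the most recent visit (state carry-forward, matching the
counting-process construction downstream) and 0 otherwise.  A flare
brings the patient to clinic: the next visit happens at the flare date
(with A/B pBILAG grades recorded) if the flare precedes the next
routine appointment; otherwise the routine visit happens flare-free.
Every severe-flare event is therefore observed at its own date by the
per-visit A/B derivation, the configured ``flare_hr_in_target`` is
exactly the continuous-time hazard ratio the gap-time model estimates,
and the ratio of per person-time flare frequencies converges to it.

New damage (an SDI increment) follows the same construction with
``baseline_damage_rate`` and ``damage_hr_in_target``: damage events
occur in continuous time and present at an assessment visit on the day
of onset, where the SDI increment is recorded.  Dating events at their
own visits keeps the gap-time partial likelihood correctly specified;
were increments instead discovered one routine interval late, the
recorded events would carry stale covariate labels into risk sets whose
in-target composition has drifted upward meanwhile, exaggerating the
protective effect.

The latent "in target" flag is obtained by applying the real target rule
engine (cLLDAS by default, configurable to cCR-0) to the generated visit
using the true, pre-missingness weight, so parameter recovery closes the
loop through the same classification code the pipeline uses.

All randomness flows from one seed; per-patient substreams are derived
deterministically from the patient index, so the same config and seed
reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .cohort import (
    ETHNICITIES,
    PBILAG_DOMAINS,
    SLEDAI_ITEMS,
    PatientRecord,
    VisitRecord,
)
from .imputation import GrowthReferenceTable, load_growth_reference
from .targets import TargetDefinition, classify_visit, default_definitions

__all__ = ["CohortConfig", "ConfigError", "generate_cohort", "true_state_labels"]


class ConfigError(ValueError):
    pass


# Per-item activity propensities: probability scale factors for each
# clinical SLEDAI item when the latent activity level saturates.
DEFAULT_ITEM_PROBS: dict[str, float] = {
    "arthritis": 0.35,
    "rash": 0.30,
    "alopecia": 0.12,
    "mucosal_ulcers": 0.12,
    "proteinuria": 0.18,
    "hematuria": 0.12,
    "pyuria": 0.08,
    "urinary_casts": 0.04,
    "fever": 0.08,
    "pleurisy": 0.05,
    "pericarditis": 0.03,
    "vasculitis": 0.05,
    "myositis": 0.05,
    "seizure": 0.015,
    "psychosis": 0.01,
    "lupus_headache": 0.02,
    "leukopenia": 0.15,
    "thrombocytopenia": 0.08,
}

# SLEDAI organ domain -> pBILAG-2004 domain used when projecting item
# activity onto grades
_DOMAIN_TO_PBILAG = {
    "cns": "neurological",
    "vasculitis": "general",
    "musculoskeletal": "musculoskeletal",
    "renal": "renal",
    "mucocutaneous": "mucocutaneous",
    "cardiopulmonary": "cardiorespiratory",
    "fever": "general",
    "haematology": "haematological",
}


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_patients: int = 430
    seed: int = 0
    # follow-up and visit schedule
    follow_up_median_years: float = 2.0
    follow_up_sigma: float = 0.85
    follow_up_min_years: float = 0.15
    follow_up_max_years: float = 8.0
    visit_interval_median_days: float = 100.0
    visit_interval_sigma: float = 0.45
    # demographics
    age_at_diagnosis_mean: float = 12.8
    age_at_diagnosis_sd: float = 3.0
    sex_ratio_female: float = 0.835
    ethnicity_probs: dict[str, float] = dc_field(
        default_factory=lambda: {
            "white_british": 0.51,
            "asian": 0.30,
            "african_caribbean": 0.17,
            "other": 0.02,
        }
    )
    # weight model
    weight_level_mu: float = 0.08
    weight_level_sigma: float = 0.18
    weight_noise_sd: float = 0.02
    weight_missing_prob: float = 0.26
    # latent activity process
    activity_start_mean: float = 8.0
    activity_decay: float = 0.60
    activity_noise_sd: float = 0.35
    flare_activity_bump: float = 3.5
    item_persistence: float = 0.35
    serology_persistence: float = 0.55
    serology_floor: float = 0.03
    item_probs: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_ITEM_PROBS)
    )
    pga_noise_sd: float = 0.15
    pga_override: float | None = None
    anti_dsdna_prevalence: float = 0.70
    # steroid taper policy
    initial_mg_per_kg: float = 0.5
    taper_factor: float = 0.60
    taper_noise_sd: float = 0.15
    flare_mg_per_kg: float = 0.20
    iv_mp_flare_prob: float = 0.35
    steroid_stop_threshold_mg: float = 2.0
    steroid_stop_prob_when_quiescent: float = 0.40
    # event hazards
    baseline_flare_rate: float = 2.8  # events per person-year, out of target
    baseline_damage_rate: float = 0.25
    flare_hr_in_target: float = 0.18
    damage_hr_in_target: float = 0.22
    first_visit_flare_prob: float = 0.76
    # latent protective state definition
    latent_state_target: str = "cLLDAS"

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        probs = self.ethnicity_probs
        if set(probs) - set(ETHNICITIES):
            raise ConfigError(f"unknown ethnicity in {sorted(probs)}")
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ConfigError("ethnicity probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("ethnicity_probs must sum to 1")
        for name in (
            "sex_ratio_female",
            "weight_missing_prob",
            "iv_mp_flare_prob",
            "first_visit_flare_prob",
            "anti_dsdna_prevalence",
            "steroid_stop_prob_when_quiescent",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "baseline_flare_rate",
            "baseline_damage_rate",
            "flare_hr_in_target",
            "damage_hr_in_target",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.latent_state_target not in default_definitions():
            raise ConfigError(
                f"unknown latent state target {self.latent_state_target!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


_BASE_DATE = dt.date(2010, 1, 1)
_SDI_BASELINE_PROBS = (0.80, 0.114, 0.047, 0.039)  # SDI 0, 1, 2, 3


def _draw_items(rng, cfg: CohortConfig, activity: float, dsdna_prone: bool,
                complement_prone: bool,
                prev_items: dict[str, int] | None = None) -> dict[str, int]:
    sat = min(1.0, activity / 8.0)
    prev = prev_items or {}
    items: dict[str, int] = {}
    for name, q in cfg.item_probs.items():
        active = rng.random() < q * sat
        if not active and name in prev:
            # smouldering features persist rather than toggling
            active = rng.random() < cfg.item_persistence
        if active:
            items[name] = SLEDAI_ITEMS[name].weight
    for name, prone, base in (
        ("anti_dsdna", dsdna_prone, 0.50),
        ("low_complement", complement_prone, 0.45),
    ):
        if not prone:
            continue
        active = rng.random() < base * sat + cfg.serology_floor
        if not active and name in prev:
            active = rng.random() < cfg.serology_persistence
        if active:
            items[name] = SLEDAI_ITEMS[name].weight
    return items


def _pbilag_from_items(
    rng, items: dict[str, int], flare: bool
) -> dict[str, str]:
    """Project item activity onto domain grades; A/B iff a flare visit."""
    active_domains = set()
    for name, score in items.items():
        if score > 0:
            dom = SLEDAI_ITEMS[name].domain
            mapped = _DOMAIN_TO_PBILAG.get(dom)
            if mapped:
                active_domains.add(mapped)
    grades = {}
    for dom in PBILAG_DOMAINS:
        if dom in active_domains:
            grades[dom] = "C"
        else:
            grades[dom] = "D" if rng.random() < 0.3 else "E"
    if flare:
        if active_domains:
            dom = sorted(active_domains)[rng.integers(len(active_domains))]
        else:
            dom = PBILAG_DOMAINS[rng.integers(len(PBILAG_DOMAINS))]
        grades[dom] = "A" if rng.random() < 0.3 else "B"
    return grades


def generate_cohort(
    config: CohortConfig,
    growth_ref: GrowthReferenceTable | None = None,
) -> tuple[list[PatientRecord], list[VisitRecord]]:
    """Generate a longitudinal cohort.

    Returns (patients, visits); visits are date-ordered per patient, SDI
    is non-decreasing, weights increase in expectation up to age 18, and
    roughly ``weight_missing_prob`` of visit weights are blanked.  Each
    visit carries a private ``_latent_in_target`` flag (the generator's
    truth, see :func:`true_state_labels`) plus ``_flare_event`` and
    ``_damage_event`` flags.
    """
    if growth_ref is None:
        growth_ref = load_growth_reference()
    latent_def: TargetDefinition = default_definitions()[config.latent_state_target]

    patients: list[PatientRecord] = []
    visits: list[VisitRecord] = []
    eth_names = list(config.ethnicity_probs)
    eth_p = np.array([config.ethnicity_probs[e] for e in eth_names])

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < config.sex_ratio_female else "male"
        ethnicity = eth_names[rng.choice(len(eth_names), p=eth_p)]
        age_dx = float(
            np.clip(
                rng.normal(config.age_at_diagnosis_mean, config.age_at_diagnosis_sd),
                0.5,
                18.0,
            )
        )
        dx_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 3650)))
        dsdna_pos = rng.random() < config.anti_dsdna_prevalence
        complement_prone = rng.random() < 0.60
        lymphopenia = rng.random() < 0.35
        sdi0 = int(rng.choice(4, p=_SDI_BASELINE_PROBS))

        follow_up_years = float(
            np.clip(
                np.exp(
                    np.log(config.follow_up_median_years)
                    + config.follow_up_sigma * rng.standard_normal()
                ),
                config.follow_up_min_years,
                config.follow_up_max_years,
            )
        )
        fu_days = int(round(follow_up_years * 365.25))

        level = float(
            np.exp(config.weight_level_mu + config.weight_level_sigma * rng.standard_normal())
        )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                ethnicity=ethnicity,
                diagnosis_date=dx_date,
                age_at_diagnosis=age_dx,
                ana_positive=rng.random() < 0.97,
                anti_dsdna_positive=dsdna_pos,
                low_c3=complement_prone and rng.random() < 0.7,
                low_c4=complement_prone and rng.random() < 0.6,
                lymphopenia=lymphopenia,
                baseline_sdi=sdi0,
            )
        )

        activity = float(rng.gamma(4.0, config.activity_start_mean / 4.0))
        pred = 0.0
        sdi = sdi0
        prior_visit: VisitRecord | None = None
        day = 0
        visit_idx = 0
        flare = rng.random() < config.first_visit_flare_prob
        damage = False
        while day <= fu_days:
            date = dx_date + dt.timedelta(days=day)
            age = age_dx + day / 365.25
            ref_age = min(age, 18.0)
            true_weight = (
                growth_ref.median_weight(sex, ref_age)
                * level
                * float(np.exp(config.weight_noise_sd * rng.standard_normal()))
            )
            true_weight = round(true_weight, 1)

            if damage:
                sdi += 1

            if visit_idx > 0:
                activity *= config.activity_decay * float(
                    np.exp(config.activity_noise_sd * rng.standard_normal())
                )
            if flare:
                activity += config.flare_activity_bump

            items = _draw_items(
                rng, config, activity, dsdna_pos, complement_prone,
                prior_visit.sledai_items if prior_visit else None,
            )
            grades = _pbilag_from_items(rng, items, flare)

            if visit_idx == 0:
                pred = min(config.initial_mg_per_kg * true_weight, 60.0)
            else:
                pred *= config.taper_factor * float(
                    np.exp(config.taper_noise_sd * rng.standard_normal())
                )
                if flare:
                    pred = max(pred, config.flare_mg_per_kg * true_weight)
            if activity < 2.0 and pred < 5.0:
                if rng.random() < config.steroid_stop_prob_when_quiescent:
                    pred = 0.0
            if pred < config.steroid_stop_threshold_mg:
                pred = 0.0
            pred = round(pred, 1)
            iv_mp = bool(flare and rng.random() < config.iv_mp_flare_prob)

            clinical = sum(
                s for n, s in items.items() if not SLEDAI_ITEMS[n].serologic
            )
            if config.pga_override is not None:
                pga = config.pga_override
            else:
                pga = float(
                    np.clip(
                        0.10 * clinical
                        + 0.8 * flare
                        + 0.06 * activity
                        + config.pga_noise_sd * rng.standard_normal(),
                        0.0,
                        3.0,
                    )
                )
            pga = round(pga, 2)

            if flare:
                imsn = "activity_driven" if rng.random() < 0.25 else "none"
            else:
                imsn = "non_activity_reason" if rng.random() < 0.07 else "none"

            visit = VisitRecord(
                patient_id=pid,
                visit_date=date,
                age_at_visit=round(age, 3),
                weight_kg=true_weight,
                weight_provenance="measured",
                sledai_items=items,
                pga=pga,
                pbilag_grades=grades,
                sdi=sdi,
                prednisolone_mg_day=pred,
                iv_methylpred=iv_mp,
                imsn_change=imsn,
                anti_dsdna_positive=items.get("anti_dsdna", 0) > 0,
                low_c3=items.get("low_complement", 0) > 0,
                low_c4=items.get("low_complement", 0) > 0 and rng.random() < 0.7,
            )
            state = classify_visit(visit, prior_visit, latent_def).attained
            visit._latent_in_target = state  # type: ignore[attr-defined]
            visit._flare_event = bool(flare)  # type: ignore[attr-defined]
            visit._damage_event = bool(damage)  # type: ignore[attr-defined]

            if rng.random() < config.weight_missing_prob:
                visit.weight_kg = None
                visit.weight_provenance = "missing"

            visits.append(visit)
            prior_visit = visit
            visit_idx += 1
            # next visit: routine appointment, unless a flare or an acute
            # damage event (continuous-time intensities under the current
            # carry-forward state) comes first
            routine = max(
                7,
                int(
                    round(
                        config.visit_interval_median_days
                        * float(
                            np.exp(config.visit_interval_sigma * rng.standard_normal())
                        )
                    )
                ),
            )
            lam_f = (
                config.baseline_flare_rate
                * (config.flare_hr_in_target if state else 1.0)
                / 365.25
            )
            lam_d = (
                config.baseline_damage_rate
                * (config.damage_hr_in_target if state else 1.0)
                / 365.25
            )
            flare_wait = max(1, int(np.ceil(rng.exponential(1.0 / lam_f))))
            damage_wait = max(1, int(np.ceil(rng.exponential(1.0 / lam_d))))
            if flare_wait <= min(damage_wait, routine - 1):
                flare, damage = True, False
                day += flare_wait
            elif damage_wait < min(flare_wait, routine):
                flare, damage = False, True
                day += damage_wait
            else:
                flare, damage = False, False
                day += routine

    return patients, visits


def true_state_labels(visits: list[VisitRecord]) -> np.ndarray:
    """The generator's latent in-target flags, aligned with ``visits``.

    Only available for cohorts produced by :func:`generate_cohort` in the
    same process (the flags are in-memory annotations, not persisted by
    the CSV writers).
    """
    labels = []
    for v in visits:
        flag = getattr(v, "_latent_in_target", None)
        if flag is None:
            raise ValueError(
                "visit lacks generator state labels (not a synthetic cohort)"
            )
        labels.append(bool(flag))
    return np.array(labels, dtype=bool)
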
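"""Pipeline orchestration and machine-readable summary tables.

``run_pipeline`` executes imputation -> classification -> feature
derivation -> inference on either a cohort read from CSV or a freshly
generated synthetic cohort, and writes the analysis outputs as CSV/JSON
tables: a cohort summary (attainment counts, time-to-target and
time-in-target medians/IQRs), the adult-only vs both-attained
misclassification comparison, Venn region counts, non-attainment reason
counts, the recurrent-event model tables and the HR-vs-cumulative-time
profile, plus a manifest recording the seed, config hash and package
version.

All quantiles are type-7 (linear interpolation), numpy's default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DAYS_PER_MONTH,
    PatientRecord,
    VisitRecord,
    read_cohort,
    visits_by_patient,
    write_cohort,
)
from .features import (
    detect_severe_flare,
    dichotomize_above_median,
    gap_time_dataset_for_cohort,
    non_attainment_reasons,
    time_in_target,
    venn_counts,
)
from .imputation import impute_weights, load_growth_reference
from .inference import (
    SingularInformationError,
    bonferroni_adjust,
    fit_pwp_gap_time,
    hr_vs_cumulative_time,
    wilcoxon_rank_sum,
)
from .simulate import CohortConfig, generate_cohort
from .targets import classify_cohort, default_definitions

__all__ = [
    "PipelineConfig",
    "summarize_cohort",
    "misclassification_table",
    "run_pipeline",
]

_Q = (25, 50, 75)


def _miqr(values) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None], float)
    if arr.size == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(arr, _Q)
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``cohort_paths`` (patients CSV, visits CSV) or
    ``generator`` must be supplied.
    """

    output_dir: str
    cohort_paths: tuple[str, str] | None = None
    generator: CohortConfig | None = None
    damage_threshold: int = 1
    flare_mode: str = "per_visit"
    ties: str = "efron"
    bootstrap_B: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_paths is None) == (self.generator is None):
            raise ValueError(
                "supply exactly one of cohort_paths or generator config"
            )


def summarize_cohort(
    patients: list[PatientRecord],
    visits: list[VisitRecord],
    attainment=None,
) -> dict:
    """Descriptive cohort summary (medians/IQRs, counts/percentages)."""
    if not patients or not visits:
        raise ValueError("empty cohort")
    grouped = visits_by_patient(visits)
    n = len(patients)
    n_visits = len(visits)
    per_patient_visits = [len(v) for v in grouped.values()]
    fu_years = [
        (v[-1].visit_date - v[0].visit_date).days / 365.25 for v in grouped.values()
    ]
    flare_flags = [bool(detect_severe_flare(v)) for v in visits]
    summary = {
        "n_patients": n,
        "n_visits": n_visits,
        "sex_female_n": sum(p.sex == "female" for p in patients),
        "ethnicity_counts": {
            e: sum(p.ethnicity == e for p in patients)
            for e in sorted({p.ethnicity for p in patients})
        },
        "age_at_diagnosis_years": _miqr([p.age_at_diagnosis for p in patients]),
        "baseline_weight_kg": _miqr(
            [grouped[p.patient_id][0].weight_kg for p in patients if p.patient_id in grouped]
        ),
        "visits_per_patient": _miqr(per_patient_visits),
        "follow_up_years": _miqr(fu_years),
        "severe_flare_visit_prevalence": float(np.mean(flare_flags)),
        "damage_visit_prevalence": float(np.mean([v.sdi > 0 for v in visits])),
        "anti_dsdna_positive_n": sum(p.anti_dsdna_positive for p in patients),
    }
    if attainment is not None:
        targets = sorted({r.target for r in attainment})
        per_target = {}
        for t in targets:
            recs = [r for r in attainment if r.target == t]
            ever: dict[str, bool] = {}
            for r in recs:
                ever[r.patient_id] = ever.get(r.patient_id, False) or r.attained
            tit = [
                time_in_target(grouped[pid], [r for r in recs if r.patient_id == pid])
                for pid in grouped
            ]
            ttf = [
                t_.time_to_first_attainment_months
                for t_ in tit
                if t_.time_to_first_attainment_months is not None
            ]
            per_target[t] = {
                "visits_attained_n": sum(r.attained for r in recs),
                "visits_attained_pct": 100.0 * np.mean([r.attained for r in recs]),
                "patients_attained_n": sum(ever.values()),
                "patients_attained_pct": 100.0 * np.mean(list(ever.values())),
                "time_to_target_months": _miqr(ttf),
                "percent_time_in_target": _miqr(
                    [
                        t_.percent_time_in_target
                        for t_ in tit
                        if t_.time_to_first_attainment_months is not None
                    ]
                ),
                "months_in_target": _miqr(
                    [
                        t_.cumulative_months_in_target
                        for t_ in tit
                        if t_.time_to_first_attainment_months is not None
                    ]
                ),
            }
        summary["targets"] = per_target
    return summary


_MISCLASS_PAIRS = (("LLDAS", "cLLDAS"), ("DORIS2021", "cCR"))


def misclassification_table(
    patients: list[PatientRecord],
    visits: list[VisitRecord],
    attainment,
) -> pd.DataFrame:
    """Adult-only vs both-attained visit comparison (weight-based dosing).

    For each (adult, paediatric) target pair, visits attaining the adult
    target only are compared with visits attaining both, on age at
    diagnosis, weight, weight-based prednisolone dose and PGA
    (rank-sum tests, Bonferroni-adjusted over all comparisons).
    """
    verdict: dict[tuple, dict[str, bool]] = {}
    for r in attainment:
        verdict.setdefault((r.patient_id, r.visit_date), {})[r.target] = r.attained
    age_dx = {p.patient_id: p.age_at_diagnosis for p in patients}
    rows = []
    raw_ps = []
    for adult, paed in _MISCLASS_PAIRS:
        adult_only, both = [], []
        for v in visits:
            d = verdict.get((v.patient_id, v.visit_date), {})
            if d.get(adult) and not d.get(paed):
                adult_only.append(v)
            elif d.get(adult) and d.get(paed):
                both.append(v)
        entry = {
            "pair": f"{adult}_vs_{paed}",
            "adult_only_n": len(adult_only),
            "both_n": len(both),
        }
        for label, getter in (
            ("age_at_diagnosis", lambda v: age_dx[v.patient_id]),
            ("weight_kg", lambda v: v.weight_kg),
            (
                "dose_mg_per_kg",
                lambda v: (
                    v.prednisolone_mg_day / v.weight_kg if v.weight_kg else None
                ),
            ),
            ("pga", lambda v: v.pga),
        ):
            a = [getter(v) for v in adult_only]
            b = [getter(v) for v in both]
            a = [x for x in a if x is not None]
            b = [x for x in b if x is not None]
            entry[f"{label}_adult_only"] = _miqr(a)
            entry[f"{label}_both"] = _miqr(b)
            if a and b:
                _, p = wilcoxon_rank_sum(a, b)
            else:
                p = float("nan")
            entry[f"{label}_p"] = p
            raw_ps.append((entry["pair"], label, p))
        rows.append(entry)
    df = pd.DataFrame(rows)
    finite = [p for _, _, p in raw_ps if np.isfinite(p)]
    if finite:
        adj = dict(
            zip(
                [(pair, lab) for pair, lab, p in raw_ps if np.isfinite(p)],
                bonferroni_adjust(finite, m=len(finite)),
            )
        )
        for i, entry in df.iterrows():
            for _, lab, _ in raw_ps:
                key = (entry["pair"], lab)
                if key in adj:
                    df.loc[i, f"{lab}_p_bonferroni"] = adj[key]
    return df


def _fit_table(fit) -> pd.DataFrame:
    return pd.DataFrame(fit.summary()["terms"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns a dict of the in-memory results; files are written under
    ``config.output_dir``.  Deterministic: the same config and seed give
    a byte-identical bundle.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    growth_ref = load_growth_reference()

    if config.generator is not None:
        gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
        patients, visits = generate_cohort(gen_cfg, growth_ref)
        config_payload = gen_cfg.to_dict()
    else:
        patients, visits = read_cohort(*config.cohort_paths)
        config_payload = {"cohort_paths": list(config.cohort_paths)}

    sex_by_pid = {p.patient_id: p.sex for p in patients}
    visits = impute_weights(visits, growth_ref, sex_by_pid)
    write_cohort(patients, visits, out / "patients.csv", out / "visits_imputed.csv")

    definitions = default_definitions()
    attainment = classify_cohort(patients, visits, definitions)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "visit_date": r.visit_date.isoformat(),
                "target": r.target,
                "attained": int(r.attained),
                "failed_criteria": ";".join(r.failed_criteria),
            }
            for r in attainment
        ]
    ).to_csv(out / "attainment.csv", index=False)

    summary = summarize_cohort(patients, visits, attainment)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    mis = misclassification_table(patients, visits, attainment)
    mis.to_json(out / "misclassification.json", orient="records", indent=2)

    venn = {}
    for pair in (("cLLDAS", "LLDAS"), ("cCR", "DORIS2021")):
        counts = venn_counts(attainment, list(pair))
        venn["_and_".join(pair)] = {
            "+".join(sorted(k)) if k else "neither": v for k, v in counts.items()
        }
    (out / "venn_counts.json").write_text(json.dumps(venn, indent=2, sort_keys=True))

    reasons = {
        name: non_attainment_reasons(attainment, visits, d)
        for name, d in definitions.items()
    }
    (out / "non_attainment_reasons.json").write_text(
        json.dumps(reasons, indent=2, sort_keys=True)
    )

    models = {}
    for target in definitions:
        try:
            rows = gap_time_dataset_for_cohort(
                patients,
                visits,
                attainment,
                target,
                event_type="severe_flare",
                flare_mode=config.flare_mode,
            )
            fit = fit_pwp_gap_time(
                rows,
                [
                    "in_target",
                    "duration_gt_1y",
                    "eth_white_british",
                    "eth_asian",
                    "eth_other",
                    "sdi",
                ],
                ties=config.ties,
            )
            models[f"severe_flare_multivariable_{target}"] = fit.summary()
        except (ValueError, SingularInformationError) as exc:
            models[f"severe_flare_multivariable_{target}"] = {"error": str(exc)}
        try:
            rows = gap_time_dataset_for_cohort(
                patients,
                visits,
                attainment,
                target,
                event_type="new_damage",
                damage_threshold=config.damage_threshold,
                include_standard_covariates=False,
            )
            fit = fit_pwp_gap_time(rows, ["in_target"], ties=config.ties)
            models[f"new_damage_univariable_{target}"] = fit.summary()
        except (ValueError, SingularInformationError) as exc:
            models[f"new_damage_univariable_{target}"] = {"error": str(exc)}
    (out / "models.json").write_text(json.dumps(models, indent=2, sort_keys=True))

    hr_profile = {}
    cllDAS_fits = hr_vs_cumulative_time(patients, visits, attainment, "cLLDAS")
    for x, fit in cllDAS_fits.items():
        hr_profile[str(x)] = {
            "hr": float(fit.effects[0]),
            "ci_low": float(fit.ci_low[0]),
            "ci_high": float(fit.ci_high[0]),
        }
    (out / "hr_vs_cumulative_time.json").write_text(
        json.dumps(hr_profile, indent=2, sort_keys=True)
    )

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config_payload, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "summary": summary,
        "misclassification": mis,
        "venn": venn,
        "reasons": reasons,
        "models": models,
        "hr_vs_cumulative_time": hr_profile,
        "manifest": manifest,
    }
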
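"""Weight imputation cascade and baseline covariate backfill.

Missing weights are needed because the paediatric steroid criteria are
weight-based (mg/kg/day).  Three rules are applied in strict order to
each missing weight:

1. *window*: the nearest documented (measured) weight within +-6 months
   (183 days); equal-distance ties resolve to the earlier record.
2. *growth centile*: for patients aged <= 18 years, the sex-specific
   50th-centile weight interpolated from a growth reference table.
3. *LOCF*: for patients over 18, the last observed (measured) weight
   carried forward.

A weight stays missing only when no rule applies (over 18 with no prior
measurement).  Exactly one provenance label is recorded per filled
value, and a measured weight is never overwritten.

An imputed weight can change a target verdict only below the steroid
crossover weight (50 kg for the shipped rules), where the mg/kg limb is
the binding constraint.

The bundled reference table (``data/growth_reference_synthetic.csv``) is
a synthetic stand-in with plausible monotone 50th-centile medians over
[0, 18] years; any WHO-consistent table satisfying the same contract
(strictly increasing ages and weights, [0, 18] coverage) can be
substituted.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import VisitRecord, visits_by_patient

__all__ = [
    "WINDOW_DAYS",
    "BACKFILL_DAYS",
    "GrowthReferenceTable",
    "load_growth_reference",
    "impute_weights",
    "backfill_baseline",
]

WINDOW_DAYS = 183  # "6 months" before or after the visit
BACKFILL_DAYS = 42  # "6 weeks" around the baseline visit


class GrowthReferenceTable:
    """Sex-specific 50th-centile weight-for-age, piecewise-linear in age."""

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._tables = {}
        for sex, (ages, weights) in tables.items():
            ages = np.asarray(ages, dtype=float)
            weights = np.asarray(weights, dtype=float)
            if not (np.all(np.diff(ages) > 0) and np.all(np.diff(weights) > 0)):
                raise ValueError(
                    f"growth reference for {sex!r} must be strictly increasing"
                )
            if ages[0] > 0 or ages[-1] < 18:
                raise ValueError(
                    f"growth reference for {sex!r} must cover [0, 18] years"
                )
            self._tables[sex] = (ages, weights)

    @classmethod
    def from_csv(cls, path) -> "GrowthReferenceTable":
        df = pd.read_csv(path)
        tables = {}
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age_years")
            tables[sex] = (
                grp["age_years"].to_numpy(),
                grp["median_weight_kg"].to_numpy(),
            )
        return cls(tables)

    def median_weight(self, sex: str, age_years: float) -> float:
        if sex not in self._tables:
            raise KeyError(f"no growth reference for sex {sex!r}")
        ages, weights = self._tables[sex]
        return float(np.interp(age_years, ages, weights))


def load_growth_reference() -> GrowthReferenceTable:
    """Load the bundled synthetic growth reference table."""
    ref = resources.files("lupus_t2t.data") / "growth_reference_synthetic.csv"
    with resources.as_file(ref) as path:
        return GrowthReferenceTable.from_csv(path)


def _nearest_window_weight(
    visit: VisitRecord, measured: list[VisitRecord]
) -> float | None:
    best: tuple[int, int, float] | None = None
    for m in measured:
        delta = (m.visit_date - visit.visit_date).days
        dist = abs(delta)
        if dist > WINDOW_DAYS:
            continue
        # ties at equal day distance resolve to the earlier record
        key = (dist, 0 if delta < 0 else 1)
        if best is None or key < best[:2]:
            best = (*key, m.weight_kg)
    return None if best is None else best[2]


def impute_weights(
    visits: list[VisitRecord],
    ref: GrowthReferenceTable,
    sex_by_patient: dict[str, str],
) -> list[VisitRecord]:
    """Apply the three-rule cascade to every missing weight.

    Returns new :class:`VisitRecord` objects (inputs are not mutated);
    measured weights pass through untouched with provenance ``measured``.
    """
    out: list[VisitRecord] = []
    for pid, pvisits in visits_by_patient(visits).items():
        sex = sex_by_patient[pid]
        measured = [v for v in pvisits if v.weight_kg is not None]
        for v in pvisits:
            if v.weight_kg is not None:
                out.append(dataclasses.replace(v, weight_provenance="measured"))
                continue
            w = _nearest_window_weight(v, measured)
            if w is not None:
                out.append(
                    dataclasses.replace(
                        v, weight_kg=w, weight_provenance="window_imputed"
                    )
                )
                continue
            if v.age_at_visit <= 18:
                w = ref.median_weight(sex, v.age_at_visit)
                out.append(
                    dataclasses.replace(
                        v, weight_kg=w, weight_provenance="who_centile"
                    )
                )
                continue
            prior = [m for m in measured if m.visit_date < v.visit_date]
            if prior:
                out.append(
                    dataclasses.replace(
                        v,
                        weight_kg=prior[-1].weight_kg,
                        weight_provenance="locf",
                    )
                )
                continue
            out.append(dataclasses.replace(v, weight_provenance="missing"))
    out.sort(key=lambda v: (v.patient_id, v.visit_date))
    return out


BACKFILL_FIELDS = ("anti_dsdna_positive", "low_c3", "low_c4", "pga", "weight_kg")


def backfill_baseline(
    visit0: VisitRecord,
    neighbours: list[VisitRecord],
    fields: tuple[str, ...] = BACKFILL_FIELDS,
) -> VisitRecord:
    """Fill missing baseline covariates from visits within +-6 weeks.

    Each missing field (value ``None``) is taken from the nearest
    neighbour visit (by day distance, earlier preferred on ties) within
    42 days that has the field present; otherwise it stays missing.
    """
    updates = {}
    ordered = sorted(
        neighbours,
        key=lambda v: (
            abs((v.visit_date - visit0.visit_date).days),
            0 if v.visit_date < visit0.visit_date else 1,
        ),
    )
    for name in fields:
        if getattr(visit0, name) is not None:
            continue
        for nb in ordered:
            if abs((nb.visit_date - visit0.visit_date).days) > BACKFILL_DAYS:
                continue
            value = getattr(nb, name)
            if value is not None:
                updates[name] = value
                break
    return dataclasses.replace(visit0, **updates) if updates else visit0
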
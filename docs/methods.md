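# Methods

## Target rule engine

Each target definition is a declarative bundle: an activity rule
(`sledai_le4_no_major_organ` or `csledai_zero`), a PGA cap, a steroid
rule, an optional "no new features" requirement, and a medication
stability mode. Criteria are evaluated in a fixed order (activity, new
activity, PGA, steroid dose, IV methylprednisolone, medication
stability) and *all* failed criteria are reported, so non-attainment
reason counts can attribute a visit to several criteria at once.

Decisions made where the definitions leave room:

* **Two-limb steroid rules** are read as `threshold = min(rate × weight,
  cap)`. Only this reading yields strict nesting of the paediatric
  inside the adult targets and the 50 kg crossover (`cap / rate`), below
  which the mg/kg limb binds. Dose comparisons use `≤` with a 1e-9 mg
  absolute tolerance for decimal dose entry.
* **First visits** satisfy "no new features" vacuously. The alternative
  (automatic failure) would bar any first-visit attainment, which
  nothing in the definitions implies.
* **Medication stability** is an enum over the recorded reason for an
  immunosuppressant change (`none`, `activity_driven`,
  `non_activity_reason`). All five shipped definitions use the
  reason-aware mode (changes for side effects, adherence, growth or
  dose build-up are tolerated; activity-driven changes are not). Shipping
  the adult definitions with a stricter mode would create visits that
  attain a paediatric target while failing its adult counterpart, which
  contradicts both the structural nesting argument and the observed
  nesting of attainment in practice; a strict mode remains available for
  variant definitions.
* **cCR-0** ("no prednisolone") also forbids IV methylprednisolone — an
  IV pulse is steroid exposure incompatible with remission off steroids.
* **Missing weight** under a rate-bearing rule yields an
  `insufficient_data` verdict rather than a silent fall-back to the cap;
  the cap-only fallback is exactly the adult rule and would mask the
  misclassification the paediatric limb exists to catch.
* **Major organ involvement** means any positively scored SLEDAI item
  tagged with one of {cardiopulmonary, cns, fever, renal, vasculitis};
  the tag map is configurable on the definition.

## Weight imputation

Missing weights are filled by a strict three-rule cascade: (1) the
nearest documented weight within ±183 days ("6 months"), ties at equal
day distance resolving to the earlier record (measured history preferred
over future); (2) for ages ≤ 18, the sex-specific 50th-centile
weight-for-age interpolated piecewise-linearly from a bundled reference
table; (3) for ages > 18, last observed weight carried forward. Exactly
one provenance label per filled value; measured weights are never
overwritten. Baseline covariates missing at the first visit are
back-filled from the nearest visit within ±42 days ("6 weeks").

The bundled reference table (`data/growth_reference_synthetic.csv`) is a
synthetic stand-in with plausible monotone medians covering 0–18 years
for both sexes. Tests assert only the contract (strict monotonicity,
range coverage), so any WHO-consistent 50th-centile table can be dropped
in. Only the median is used — no LMS/z-score modelling.

## Event derivation and counting-process construction

A severe flare is a pBILAG-2004 grade A or B in any organ domain at a
visit; by default every qualifying visit is an event dated at that visit
(per-visit accounting), with a `new_episode` mode counting only A/B
visits following a non-A/B visit. New damage is an SDI increase of at
least `damage_increment_threshold` since the previous visit; the default
threshold is 1 because the SDI is integer-valued and any increase is new
irreversible damage, with 2 available for a stricter reading. A
decreasing SDI triggers a data-integrity warning and is treated as no
event. Follow-up runs from a patient's first to last visit; a
qualifying first visit is not an event (it falls at gap time zero).

PWP gap-time rows are built per patient: the k-th event closes stratum
k and resets the clock; rows split at every covariate change date
(visits, plus the disease-duration crossing at diagnosis + 366 days);
the final stratum is censored at the last visit. Time-varying
covariates use state carry-forward, consistent with the time-in-target
attribution (a patient is "in target" from an attaining visit until the
next visit). Time in target divides cumulative in-target months by
total follow-up; patients never attaining, or at or below the median
percentage among attainers, are grouped together in the dichotomized
outcome. Durations are computed in days and reported as months via
days / 30.4375.

## Estimators

The stratified Cox partial likelihood is maximized by Newton–Raphson
from β = 0 with step-halving on any decrease, converging when the
gradient max-norm drops below 1e-8 (25 iterations maximum; fits report
`converged`). Efron's tie correction is the default; Breslow is retained
as a cross-check and the two coincide exactly on tie-free data. Risk
sums per event time are accumulated with difference arrays over
`searchsorted` index ranges, so each Newton iteration is O(rows + event
times) per stratum. Model-based (inverse-information) standard errors
are the default for confidence intervals; a cluster-robust sandwich
variance by patient is computed alongside using Breslow-type score
residuals (a standard approximation when ties are handled by Efron's
method). A covariate constant within all risk sets raises a
singular-information error naming the covariate.

Logistic regression uses IRLS to the same gradient tolerance with Wald
intervals, raising a separation error when estimates diverge with
perfect classification. Wilcoxon signed-rank and rank-sum tests use
exact enumeration (with midranks) up to 12 observations and a normal
approximation with continuity and tie corrections beyond; all p-values
are two-sided. Bonferroni adjustment is `min(1, p·m)`. The paired
comparison of hazard ratios between two target definitions bootstraps
patients with replacement (B = 200 by default, seeded), refits both
univariable models per replicate, and applies the dependent-samples
t-test to the paired log-HRs; the bootstrap construction is this
package's own choice of pairing. The HR-vs-cumulative-time profile
refits the flare model with the patient-level indicator "spent ≥ X% of
follow-up in target" for X = 10…80%; X = 0 reduces to the ever-attained
indicator.

## Synthetic cohort generator

The generator emulates the longitudinal structure the analysis consumes,
with defaults chosen once to match the conditions of a national
paediatric lupus registry: 430 patients, 83.5% female, diagnosis age
~N(12.8, 3.0) clipped to (0.5, 18], ethnicity (51/30/17/2%), lognormal
follow-up with median 2 years, lognormal routine visit intervals with
median 100 days, ~26% of weights blanked, first-visit severe-flare
prevalence 76%, and per-visit severe-flare prevalence near 43–48%.
Disease activity follows a latent level that starts high, decays
geometrically (factor 0.60/visit) and jumps at flares; SLEDAI items are
drawn with per-item propensities scaled by the level, with persistence
(0.35 clinical, 0.55 serologic) so established features smoulder rather
than toggle; PGA is a noisy function of clinical activity and flares.
Prednisolone starts at 0.5 mg/kg, tapers geometrically (factor
0.60/visit with noise), jumps to ≥ 0.2 mg/kg at flares, and is
discontinued stochastically at low doses in quiescent disease —
producing the younger/lighter misclassification phenomenon naturally,
since lighter patients need absolutely lower doses to satisfy the mg/kg
limbs.

**Events.** Severe flares occur in continuous time at intensity
`baseline_flare_rate × flare_hr_in_target^state` (state = the latent
target state at the most recent visit, matching the carry-forward
covariate downstream) and *trigger a clinic visit at the flare date*,
where A/B pBILAG grades are recorded. New damage follows the same
construction with its own rate and hazard ratio, presenting at an
assessment visit on the day of onset where the SDI increments. Dating
every event at its own visit keeps the gap-time partial likelihood
correctly specified, so the configured hazard ratios are exactly the
estimands of the downstream models and the per person-time event
frequency ratio converges to them. Two alternatives were evaluated and
rejected: per-visit Bernoulli events dated at scheduled visits make the
partial likelihood estimate something between the per-visit probability
ratio and the per-visit odds ratio (severely overstating a strong
protective effect when the per-visit event probability is ~0.5), and
detecting damage one routine interval late lets events carry stale
out-of-target labels into risk sets whose in-target composition has
drifted upward, again exaggerating protection by ~15–20%.

The latent in-target flag is produced by the real rule engine applied to
the generated visit with its true (pre-blanking) weight; recovery
experiments therefore include the small covariate misclassification that
weight imputation introduces downstream (window imputation fires for the
overwhelming majority of blanked weights, so the attenuation is well
under the tolerances used). All randomness flows from one seed with
per-patient substreams, making cohorts byte-reproducible.

**What the generator does not emulate:** item-level clinical coherence
(no pharmacokinetics, no organ-specific trajectories), frailty or other
unobserved heterogeneity in event risk beyond the target state,
informative loss to follow-up, and measurement error in the indices
themselves. Passing recovery tests therefore demonstrates correctness of
the pipeline and estimators under the stated generative assumptions, not
robustness of the clinical findings to violations of them.

## Validation experiments and problem sizes

The recovery experiments (also run by `scripts/acceptance.py`) use 25
seeded replicates of 500-patient cohorts for the hazard ratios and 25
replicates of n = 2000 for the logistic odds ratio — sizes at which the
Monte Carlo standard error of the mean recovered effect is ~1–5% of the
effect, comfortably inside the ±15% assertion bands, while keeping the
full suite to a few minutes on one CPU. Estimator unit tests use tiny
instances checked against a 1-D grid/golden-section maximization of the
same partial likelihood, a standard counting-process Cox fitter
(lifelines) on single-event reductions, statsmodels for the logistic
fit, closed-form 2×2 odds ratios, and full enumeration for the exact
rank tests.

## Known limitations

* The cCR-0 recovery shows a small residual upward bias (~3–7% toward
  the null over seed sets), consistent with the rarer, shorter in-target
  stints under the zero-steroid definition interacting with integer-day
  event ties; it is well inside the ±15% validation band.
* Robust (sandwich) standard errors under Efron ties reuse Breslow-type
  score residuals.
* The pipeline analyses targets one at a time; joint/mutually exclusive
  state modelling is out of scope, as are frailty recurrent-event
  variants and calendar-time (total-time) models beyond an internal
  cross-check.
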
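# lupus-t2t

Treat-to-target (T2T) analysis tooling for childhood-onset systemic lupus
erythematosus (cSLE) cohorts: a rule engine for paediatric and adult
disease-state targets, weight imputation for weight-based steroid criteria,
recurrent-event survival modelling of severe flares and new damage, and a
synthetic longitudinal cohort generator that makes the whole pipeline
testable without access to patient data.

## The problem

T2T management steers therapy toward a defined disease state. For cSLE,
paediatric-specific targets add a *weight-based* prednisolone limb to the
adult definitions, because a flat milligram cap lets a 25 kg child on a
high mg/kg dose be classified as "low disease activity":

| Target | Activity rule | PGA | Prednisolone | Stability |
|---|---|---|---|---|
| cLLDAS | SLEDAI-2K ≤ 4, no major organ | ≤ 1.0 | ≤ min(0.15 mg/kg/d × wt, 7.5 mg/d), no IV-MP | tolerated maintenance IS |
| LLDAS | SLEDAI-2K ≤ 4, no major organ | ≤ 1.0 | ≤ 7.5 mg/d, no IV-MP | tolerated maintenance IS |
| cCR | cSLEDAI = 0 | ≤ 0.5 | ≤ min(0.10 mg/kg/d × wt, 5 mg/d), no IV-MP | tolerated maintenance IS |
| DORIS 2021 | cSLEDAI = 0 | ≤ 0.5 | ≤ 5 mg/d, no IV-MP | tolerated maintenance IS |
| cCR-0 | cSLEDAI = 0 | ≤ 0.5 | none | tolerated maintenance IS |

The two-limb rules cross the adult caps at `cap / rate = 50 kg`: below
50 kg the mg/kg limb binds, which is exactly where imputed weights can
change a verdict and where adult-only ("misclassified") attainment lives.
The low-disease-activity targets additionally require no new SLEDAI
features versus the previous assessment.

Whether attaining a target protects against severe flares (pBILAG-2004
grade A or B in any organ domain) and new damage (an SDI increase since
the last visit) is assessed with Prentice–Williams–Peterson (PWP)
gap-time models: Cox models stratified by event order k with the clock
reset after each event, so the hazard for the k-th event at gap time t is

    λ_k(t | x(t)) = λ0k(t) · exp(β′x(t))

with time-varying covariates (current target state, disease duration
> 1 year, ethnicity, SDI) carried forward between visits. Predictors of
spending above-median cumulative time in target are assessed with
univariable logistic regression. The Cox partial likelihood
(Efron or Breslow ties, Newton–Raphson with step-halving) and the IRLS
logistic fitter are implemented in this package and cross-checked against
independent oracles in the test suite.

## Worked example

```python
from lupus_t2t.reporting import PipelineConfig, run_pipeline
from lupus_t2t.simulate import CohortConfig

res = run_pipeline(PipelineConfig(
    output_dir="out", generator=CohortConfig(n_patients=430), seed=1))

s = res["summary"]
print(s["n_visits"])                              # 6461
print(s["severe_flare_visit_prevalence"])         # 0.475
print(s["targets"]["cLLDAS"]["visits_attained_pct"])   # 19.9
print(s["targets"]["cCR0"]["visits_attained_pct"])     # 11.9
for t in res["models"]["severe_flare_multivariable_cLLDAS"]["terms"]:
    print(t["term"], round(t["effect"], 2))
# in_target 0.22   duration_gt_1y 1.02   eth_white_british 1.07
# eth_asian 1.0    eth_other 1.25        sdi 1.01
```

The generated cohort reproduces the longitudinal structure of a national
paediatric lupus registry (430 patients, ~10 visits over ~2 years,
severe flares at ~43–48% of visits, 26% missing weights). The fitted
multivariable hazard ratio of 0.22 (95% CI 0.18–0.27) for `in_target`
says that visits spent in cLLDAS carry roughly a five-fold lower severe
flare hazard — this single replicate was generated with a true in-target
hazard ratio of 0.18, which the CI covers. The misclassification table
in the same bundle shows 26 adult-only (LLDAS without cLLDAS) visits at
a median weight of 32.6 kg versus 52.4 kg for visits attaining both —
the weight-based misclassification phenomenon the paediatric limbs
exist to prevent. The HR-vs-cumulative-time profile falls monotonically
from 0.77 (≥10% of follow-up in target) to 0.24 (≥80%).

A CLI mirrors the stages (`t2t simulate | impute | classify | features |
fit-pwp | fit-logistic | report`), each CSV-in/CSV-out.

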
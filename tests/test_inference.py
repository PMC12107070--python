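"""Estimators against independent oracles: grid maximization, lifelines,
statsmodels, scipy and closed forms."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import mannwhitneyu, spearmanr, ttest_rel, wilcoxon

from lupus_t2t.features import GapTimeRow
from lupus_t2t.inference import (
    SeparationError,
    SingularInformationError,
    bonferroni_adjust,
    compare_hr_dependent,
    fit_logistic,
    fit_pwp_gap_time,
    hr_vs_cumulative_time,
    paired_t,
    pwp_partial_loglik,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


def _row(pid, stratum, start, stop, event, **cov):
    return GapTimeRow(pid, stratum, float(start), float(stop), event, cov)


def _random_small_instance(rng):
    """<=5 subjects, <=2 events each, one binary covariate."""
    rows = []
    for i in range(rng.integers(3, 6)):
        x = float(rng.random() < 0.5)
        t = 0.0
        for k in range(1, rng.integers(1, 3) + 1):
            gap = float(rng.integers(2, 30))
            event = bool(rng.random() < 0.7)
            rows.append(_row(f"p{i}", k, 0, gap, event, x=x))
            if not event:
                break
    if not any(r.event for r in rows):
        rows[0] = _row(rows[0].patient_id, 1, 0, rows[0].stop, True, **rows[0].covariates)
    return rows


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_newton_matches_grid_maximization(ties):
    """On tiny instances the Newton estimate equals a 1-D golden-section
    maximization of the same partial likelihood to 1e-6."""
    rng = np.random.default_rng(12)
    checked = 0
    for _ in range(40):
        rows = _random_small_instance(rng)
        xs = {r.covariates["x"] for r in rows}
        ev = {r.covariates["x"] for r in rows if r.event}
        if len(xs) < 2 or len(ev) < 2:
            continue  # avoid boundary / monotone-likelihood instances
        fit = fit_pwp_gap_time(rows, ["x"], ties=ties)
        if not fit.converged or abs(fit.coef[0]) > 4:
            continue
        res = minimize_scalar(
            lambda b: -pwp_partial_loglik(rows, ["x"], [b], ties=ties),
            bounds=(-8, 8),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)
        checked += 1
    assert checked >= 10


def test_reduces_to_single_event_cox():
    """With at most one event per subject the PWP fit equals a standard
    counting-process Cox fit (lifelines) to 1e-8."""
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    rng = np.random.default_rng(5)
    rows = []
    for i in range(120):
        x = float(rng.random() < 0.4)
        z = float(rng.normal())
        t = float(rng.integers(5, 400))
        event = bool(rng.random() < 0.6 * math.exp(-0.5 * x))
        rows.append(_row(f"p{i}", 1, 0, t, event, x=x, z=z))
    fit = fit_pwp_gap_time(rows, ["x", "z"])
    df = pd.DataFrame(
        {
            "id": [r.patient_id for r in rows],
            "start": [r.start for r in rows],
            "stop": [r.stop for r in rows],
            "event": [int(r.event) for r in rows],
            "x": [r.covariates["x"] for r in rows],
            "z": [r.covariates["z"] for r in rows],
        }
    )
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(df, id_col="id", start_col="start", stop_col="stop", event_col="event")
    assert np.allclose(fit.coef, ctv.params_.values, atol=1e-8)
    assert np.allclose(fit.se, ctv.standard_errors_.values, atol=1e-6)


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(9)
    rows = []
    used = set()
    for i in range(60):
        t = float(rng.integers(1, 10_000))
        while t in used:
            t += 1
        used.add(t)
        rows.append(_row(f"p{i}", 1, 0, t, bool(rng.random() < 0.5), x=float(i % 2)))
    fe = fit_pwp_gap_time(rows, ["x"], ties="efron")
    fb = fit_pwp_gap_time(rows, ["x"], ties="breslow")
    assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-10)
    assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)


def test_loglik_never_below_null(small_cohort):
    from lupus_t2t.features import gap_time_dataset_for_cohort
    from lupus_t2t.targets import classify_cohort, default_definitions

    patients, visits = small_cohort
    att = classify_cohort(patients, visits, default_definitions())
    rows = gap_time_dataset_for_cohort(patients, visits, att, "cLLDAS")
    fit = fit_pwp_gap_time(rows, ["in_target", "sdi"])
    ll0 = pwp_partial_loglik(rows, ["in_target", "sdi"], [0.0, 0.0])
    assert fit.loglik >= ll0
    assert fit.converged
    assert fit.robust_se is not None and np.all(fit.robust_se > 0)


def test_constant_covariate_raises():
    rows = [_row("a", 1, 0, 5, True, x=1.0), _row("b", 1, 0, 7, True, x=1.0)]
    with pytest.raises(SingularInformationError, match="x"):
        fit_pwp_gap_time(rows, ["x"])
    with pytest.raises(ValueError, match="no events"):
        fit_pwp_gap_time([_row("a", 1, 0, 5, False, x=1.0)], ["x"])


def test_pwp_null_covariate_coverage():
    """A covariate independent of the hazard: the 95% CI for its HR covers
    1 in at least 90% of seeded replicates."""
    cover = 0
    B = 50
    for s in range(B):
        rng = np.random.default_rng(1000 + s)
        rows = []
        for i in range(150):
            x = float(rng.random() < 0.5)
            t0 = 0.0
            for k in range(1, 4):
                gap = float(rng.exponential(100) + 1)
                event = bool(rng.random() < 0.5)
                rows.append(_row(f"p{i}", k, 0, round(gap, 1) + 0.5, event, x=x))
                if not event:
                    break
        fit = fit_pwp_gap_time(rows, ["x"])
        if fit.ci_low[0] <= 1.0 <= fit.ci_high[0]:
            cover += 1
    assert cover / B >= 0.90


def test_logistic_matches_cross_product_odds_ratio():
    a, b, c, d = 10, 20, 30, 40  # exposed-case, exposed-control, ...
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    fit = fit_logistic(x[:, None], y, names=["exposure"])
    assert fit.effects[1] == pytest.approx((a * d) / (b * c), abs=1e-6)


def test_logistic_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    X = rng.normal(size=(300, 2))
    eta = 0.4 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y, names=["a", "b"])
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.allclose(fit.coef, sm_fit.params, atol=1e-6)
    assert np.allclose(fit.se, sm_fit.bse, atol=1e-5)


def test_logistic_null_coverage():
    cover = 0
    B = 50
    for s in range(B):
        rng = np.random.default_rng(3000 + s)
        x = (rng.random(500) < 0.5).astype(float)
        y = (rng.random(500) < 0.4).astype(float)
        fit = fit_logistic(x[:, None], y, names=["x"])
        if fit.ci_low[1] <= 1.0 <= fit.ci_high[1]:
            cover += 1
    assert cover / B >= 0.90


def test_logistic_separation_detected():
    x = np.array([0, 0, 0, 1, 1, 1.0])
    y = np.array([0, 0, 0, 1, 1, 1.0])
    with pytest.raises(SeparationError):
        fit_logistic(x[:, None], y)


def test_wilcoxon_signed_rank_exact_enumeration():
    """Exact p equals brute-force enumeration over all sign assignments."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        w, p = wilcoxon_signed_rank(x, y)
        d = x - y
        d = d[d != 0]
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        le = ge = tot = 0
        for signs in itertools.product((0, 1), repeat=len(d)):
            ws = float(np.dot(signs, ranks))
            tot += 1
            le += ws <= w_obs
            ge += ws >= w_obs
        p_brute = min(1.0, 2 * min(le / tot, ge / tot))
        assert w == pytest.approx(w_obs)
        assert p == pytest.approx(p_brute, abs=1e-12)
        # scipy exact agrees on untied data
        assert p == pytest.approx(wilcoxon(x, y, method="exact").pvalue, abs=1e-9)


def test_wilcoxon_signed_rank_degenerate():
    assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)


def test_wilcoxon_rank_sum_exact_enumeration():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([10.0, 11.0, 12.0, 13.0])
    w, p = wilcoxon_rank_sum(x, y)
    assert w == 1 + 2 + 3 + 4
    assert p == pytest.approx(2 * 1 / math.comb(8, 4), abs=1e-12)
    sp = mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
    assert p == pytest.approx(sp, abs=1e-9)


def test_wilcoxon_large_sample_close_to_scipy():
    rng = np.random.default_rng(8)
    x = rng.normal(0.3, 1, 40)
    y = rng.normal(0.0, 1, 35)
    _, p = wilcoxon_rank_sum(x, y)
    sp = mannwhitneyu(x, y, method="asymptotic", alternative="two-sided").pvalue
    assert p == pytest.approx(sp, rel=0.05)
    xs = rng.normal(0.3, 1, 30)
    ys = rng.normal(0.0, 1, 30)
    _, p2 = wilcoxon_signed_rank(xs, ys)
    sp2 = wilcoxon(xs, ys, correction=True, method="approx").pvalue
    assert p2 == pytest.approx(sp2, rel=0.05)


def test_bonferroni():
    assert bonferroni_adjust([0.01], m=5)[0] == pytest.approx(0.05)
    assert bonferroni_adjust([0.3], m=1)[0] == pytest.approx(0.3)
    assert bonferroni_adjust([0.5], m=5)[0] == 1.0
    with pytest.raises(ValueError):
        bonferroni_adjust([0.1], m=0)
    with pytest.raises(ValueError):
        bonferroni_adjust([1.5], m=2)


def test_paired_t_closed_form():
    rng = np.random.default_rng(6)
    x = rng.normal(0.5, 1, 20)
    y = rng.normal(0.0, 1, 20)
    t, p = paired_t(x, y)
    ref = ttest_rel(x, y)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)
    assert paired_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_compare_hr_dependent_identical_targets(small_cohort):
    from lupus_t2t.targets import classify_cohort, default_definitions

    patients, visits = small_cohort
    att = classify_cohort(patients, visits, default_definitions())
    t, p = compare_hr_dependent(
        patients, visits, att, "cLLDAS", "cLLDAS", B=4, seed=0
    )
    assert (t, p) == (0.0, 1.0)


def test_compare_hr_dependent_nested_targets_not_significant(small_cohort):
    """Paediatric vs adult LDA definitions protect comparably, so the
    paired bootstrap comparison should not reach significance."""
    from lupus_t2t.targets import classify_cohort, default_definitions

    patients, visits = small_cohort
    att = classify_cohort(patients, visits, default_definitions())
    t, p = compare_hr_dependent(
        patients, visits, att, "cLLDAS", "LLDAS", B=25, seed=11
    )
    assert np.isfinite(t)
    assert p > 0.05


def test_hr_declines_with_cumulative_time_threshold():
    """With a strongly protective in-target state, the flare HR for
    "spent >= X% of follow-up in target" decreases in X."""
    from lupus_t2t.simulate import CohortConfig, generate_cohort
    from lupus_t2t.targets import classify_cohort, default_definitions

    patients, visits = generate_cohort(CohortConfig(n_patients=250, seed=21))
    att = classify_cohort(patients, visits, default_definitions())
    fits = hr_vs_cumulative_time(patients, visits, att, "cLLDAS")
    xs = sorted(fits)
    assert len(xs) >= 5
    hrs = [fits[x].effects[0] for x in xs]
    rho, _ = spearmanr(xs, hrs)
    assert rho <= 0
    assert hrs[0] < 1.0
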
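"""Estimation: stratified gap-time Cox partial likelihood, IRLS logistic
regression, rank tests and multiplicity / paired-comparison utilities.

The recurrent-event model is the Prentice-Williams-Peterson (PWP)
gap-time model: a Cox proportional-hazards model whose risk sets are
formed within event-order strata on the gap-time scale (time since the
previous event).  The partial likelihood is maximized by Newton-Raphson
with step-halving, starting from zero; tied event times are handled by
the Efron correction by default (Breslow available as a cross-check).
Model-based (inverse-information) standard errors are the default for
confidence intervals; a robust sandwich variance clustered by patient
is computed alongside, using Breslow-type score residuals (a standard
approximation under Efron ties).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .features import GapTimeRow

__all__ = [
    "Z975",
    "ModelFit",
    "ConvergenceError",
    "SingularInformationError",
    "SeparationError",
    "fit_pwp_gap_time",
    "fit_logistic",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bonferroni_adjust",
    "paired_t",
    "compare_hr_dependent",
    "hr_vs_cumulative_time",
]

Z975 = 1.959964  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    pass


class SingularInformationError(np.linalg.LinAlgError):
    pass


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE diverges."""


@dataclass
class ModelFit:
    kind: str  # "pwp_cox" | "logistic"
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    robust_se: np.ndarray | None
    loglik: float
    n_iter: int
    converged: bool
    ties: str | None = None
    n_events: int = 0
    n_obs: int = 0

    @property
    def effects(self) -> np.ndarray:
        """Exponentiated coefficients (HR for Cox, OR for logistic)."""
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef - Z975 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef + Z975 * self.se)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        return 2 * norm.sf(np.abs(self.zvalues))

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "converged": self.converged,
            "loglik": self.loglik,
            "terms": [
                {
                    "term": n,
                    "estimate": float(b),
                    "se": float(s),
                    "effect": float(np.exp(b)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p": float(p),
                }
                for n, b, s, lo, hi, p in zip(
                    self.names, self.coef, self.se, self.ci_low, self.ci_high,
                    self.pvalues,
                )
            ],
        }


# ---------------------------------------------------------------------------
# Stratified gap-time Cox partial likelihood
# ---------------------------------------------------------------------------

class _Stratum:
    """Precomputed index structure for one event-order stratum."""

    def __init__(self, start, stop, event, X):
        self.X = X
        self.n = len(start)
        etimes = np.unique(stop[event])
        self.times = etimes
        self.T = len(etimes)
        # rows are at risk at event times in (start, stop]
        self.lo = np.searchsorted(etimes, start, side="right")
        self.hi = np.searchsorted(etimes, stop, side="right")
        self.event = event
        # map each event row to its event-time index
        self.ev_idx = np.searchsorted(etimes, stop[event])
        self.d = np.bincount(self.ev_idx, minlength=self.T).astype(float)
        self.ev_rows = np.flatnonzero(event)

    def risk_sums(self, w):
        """S0(t), S1(t), S2(t) over risk sets at each event time."""
        T, p = self.T, self.X.shape[1]
        wx = w[:, None] * self.X
        wxx = wx[:, :, None] * self.X[:, None, :]
        parts = np.concatenate(
            [w[:, None], wx, wxx.reshape(self.n, p * p)], axis=1
        )
        diff = np.zeros((T + 1, parts.shape[1]))
        np.add.at(diff, self.lo, parts)
        np.add.at(diff, self.hi, -parts)
        cum = np.cumsum(diff[:-1], axis=0)
        S0 = cum[:, 0]
        S1 = cum[:, 1 : 1 + p]
        S2 = cum[:, 1 + p :].reshape(T, p, p)
        return S0, S1, S2

    def death_sums(self, w):
        T, p = self.T, self.X.shape[1]
        Xe = self.X[self.ev_rows]
        we = w[self.ev_rows]
        wx = we[:, None] * Xe
        Sd0 = np.bincount(self.ev_idx, weights=we, minlength=T)
        Sd1 = np.zeros((T, p))
        Sd2 = np.zeros((T, p, p))
        for j in range(p):
            Sd1[:, j] = np.bincount(self.ev_idx, weights=wx[:, j], minlength=T)
            for k in range(p):
                Sd2[:, j, k] = np.bincount(
                    self.ev_idx, weights=wx[:, j] * Xe[:, k], minlength=T
                )
        return Sd0, Sd1, Sd2, Xe, we


def _pwp_loglik_grad_hess(strata, beta, ties, want_derivs=True):
    ll = 0.0
    p = len(beta)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for st in strata:
        if st.T == 0:
            continue
        eta = st.X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        S0, S1, S2 = st.risk_sums(w)
        Xe = st.X[st.ev_rows]
        ll += float(eta[st.ev_rows].sum())
        if want_derivs:
            grad += Xe.sum(axis=0)
        if ties == "breslow":
            ll -= float((st.d * np.log(S0)).sum())
            if want_derivs:
                xbar = S1 / S0[:, None]
                grad -= (st.d[:, None] * xbar).sum(axis=0)
                v = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
                hess -= (st.d[:, None, None] * v).sum(axis=0)
        else:  # efron
            Sd0, Sd1, Sd2, _, _ = st.death_sums(w)
            dmax = int(st.d.max())
            for l in range(dmax):
                m = st.d > l
                frac = l / st.d[m]
                D0 = S0[m] - frac * Sd0[m]
                ll -= float(np.log(D0).sum())
                if want_derivs:
                    D1 = S1[m] - frac[:, None] * Sd1[m]
                    xbar = D1 / D0[:, None]
                    grad -= xbar.sum(axis=0)
                    D2 = S2[m] - frac[:, None, None] * Sd2[m]
                    v = (
                        D2 / D0[:, None, None]
                        - xbar[:, :, None] * xbar[:, None, :]
                    )
                    hess += -v.sum(axis=0)
    return ll, grad, hess


def _score_residuals(strata, beta, patient_ids):
    """Breslow-type per-patient score residuals for the sandwich variance."""
    p = len(beta)
    resid = {}
    for st, pids in zip(strata, patient_ids):
        if st.T == 0:
            continue
        eta = np.clip(st.X @ beta, -500, 500)
        w = np.exp(eta)
        S0, S1, _ = st.risk_sums(w)
        xbar = S1 / S0[:, None]
        a = st.d / S0  # hazard increments
        b = xbar * (st.d / S0)[:, None]
        cumA = np.concatenate([[0.0], np.cumsum(a)])
        cumB = np.vstack([np.zeros(p), np.cumsum(b, axis=0)])
        A = cumA[st.hi] - cumA[st.lo]
        B = cumB[st.hi] - cumB[st.lo]
        U = -w[:, None] * (st.X * A[:, None] - B)
        U[st.ev_rows] += st.X[st.ev_rows] - xbar[st.ev_idx]
        for pid, u in zip(pids, U):
            resid[pid] = resid.get(pid, 0) + u
    return np.array(list(resid.values()))


def fit_pwp_gap_time(
    rows: list[GapTimeRow],
    covariates: list[str],
    ties: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit the stratified gap-time Cox model on counting-process rows.

    Risk sets are formed within each event-order stratum at observed
    event (gap) times; rows with ``start < t <= stop`` are at risk at
    time ``t``.  Newton-Raphson from beta = 0 with step-halving on any
    decrease of the partial log-likelihood.

    Raises
    ------
    ValueError
        If no events are present.
    SingularInformationError
        If some covariate is constant within all risk sets.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    if not any(r.event for r in rows):
        raise ValueError("no events in dataset")
    p = len(covariates)
    X_all = np.array(
        [[r.covariates.get(c, 0.0) for c in covariates] for r in rows], float
    )
    if not np.all(np.isfinite(X_all)):
        raise ValueError("non-finite covariate values")
    strata_ids = sorted({r.stratum for r in rows})
    strata, pids = [], []
    for k in strata_ids:
        idx = [i for i, r in enumerate(rows) if r.stratum == k]
        start = np.array([rows[i].start for i in idx])
        stop = np.array([rows[i].stop for i in idx])
        if np.any(stop <= start):
            raise ValueError("rows must satisfy start < stop")
        event = np.array([rows[i].event for i in idx])
        strata.append(_Stratum(start, stop, event, X_all[idx]))
        pids.append([rows[i].patient_id for i in idx])

    for j, name in enumerate(covariates):
        if np.ptp(X_all[:, j]) == 0:
            raise SingularInformationError(
                f"covariate {name!r} is constant across all risk sets"
            )

    beta = np.zeros(p)
    ll, grad, hess = _pwp_loglik_grad_hess(strata, beta, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            j = int(np.argmin(np.diag(info)))
            raise SingularInformationError(
                f"singular information matrix; covariate {covariates[j]!r} "
                "may be constant within all risk sets"
            ) from exc
        # step-halving: accept only non-decreasing log-likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _pwp_loglik_grad_hess(strata, cand, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError("singular information at optimum") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    U = _score_residuals(strata, beta, pids)
    robust = cov @ (U.T @ U) @ cov
    robust_se = np.sqrt(np.maximum(np.diag(robust), 0))
    return ModelFit(
        kind="pwp_cox",
        names=list(covariates),
        coef=beta,
        se=se,
        robust_se=robust_se,
        loglik=ll,
        n_iter=it,
        converged=converged,
        ties=ties,
        n_events=int(sum(r.event for r in rows)),
        n_obs=len(rows),
    )


def pwp_partial_loglik(
    rows: list[GapTimeRow], covariates: list[str], beta, ties: str = "efron"
) -> float:
    """Partial log-likelihood at ``beta`` (for oracle / grid checks)."""
    p = len(covariates)
    X_all = np.array(
        [[r.covariates.get(c, 0.0) for c in covariates] for r in rows], float
    )
    strata = []
    for k in sorted({r.stratum for r in rows}):
        idx = [i for i, r in enumerate(rows) if r.stratum == k]
        strata.append(
            _Stratum(
                np.array([rows[i].start for i in idx]),
                np.array([rows[i].stop for i in idx]),
                np.array([rows[i].event for i in idx]),
                X_all[idx],
            )
        )
    ll, _, _ = _pwp_loglik_grad_hess(
        strata, np.asarray(beta, float), ties, want_derivs=False
    )
    return ll


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------

def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelFit:
    """Binary logistic regression via iteratively reweighted least squares.

    Wald standard errors from the inverse observed information.  Raises
    :class:`SeparationError` on complete separation (diverging estimate
    with perfect classification).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and names is None:
        X = X.T
    y = np.asarray(y, float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept", *names]
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1 - mu)
        info = X.T @ (X * W[:, None])
        if np.max(np.abs(beta)) > 30:
            pred = (mu > 0.5).astype(float)
            if np.all(pred == y):
                raise SeparationError(
                    "complete separation: perfect classification with "
                    "diverging estimates"
                )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                "singular information in logistic fit (collinear design?)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -500, 500)
    mu = 1 / (1 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return ModelFit(
        kind="logistic",
        names=list(names),
        coef=beta,
        se=se,
        robust_se=None,
        loglik=ll,
        n_iter=it,
        converged=converged,
        n_events=int(y.sum()),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Rank tests (exact enumeration at small n, normal approximation beyond)
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped.  The p-value is computed by exact
    enumeration over all sign assignments when the number of non-zero
    pairs is <= 12, and by a normal approximation with continuity
    correction (and midrank tie handling) otherwise.  All differences
    zero gives the degenerate result (0, 1).
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 12:
        total = 0
        le = 0
        ge = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            total += 1
            le += w <= w_pos
            ge += w >= w_pos
        p = min(1.0, 2 * min(le / total, ge / total))
        return w_pos, p
    mean = n * (n + 1) / 4
    # variance with tie correction on midranks
    var = float(np.sum(ranks**2)) / 4
    if var == 0:
        return w_pos, 1.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    from scipy.stats import norm

    return w_pos, float(min(1.0, 2 * norm.sf(abs(z))))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration over all group assignments when n + m <= 12;
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n].sum())
    if n + m <= 12:
        idx = range(n + m)
        total = 0
        le = 0
        ge = 0
        for comb in itertools.combinations(idx, n):
            w = float(ranks[list(comb)].sum())
            total += 1
            le += w <= w_obs
            ge += w >= w_obs
        p = min(1.0, 2 * min(le / total, ge / total))
        return w_obs, p
    N = n + m
    mean = n * (N + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return w_obs, 1.0
    z = (w_obs - mean - 0.5 * np.sign(w_obs - mean)) / math.sqrt(var)
    from scipy.stats import norm

    return w_obs, float(min(1.0, 2 * norm.sf(abs(z))))


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return np.minimum(1.0, p * m)


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided Student's t-test for dependent (paired) samples."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    t = d.mean() / (sd / math.sqrt(n))
    from scipy.stats import t as tdist

    return float(t), float(2 * tdist.sf(abs(t), n - 1))


# ---------------------------------------------------------------------------
# Paired HR comparison via patient bootstrap
# ---------------------------------------------------------------------------

def compare_hr_dependent(
    patients,
    visits,
    attainment,
    target_a: str,
    target_b: str,
    event_type: str = "severe_flare",
    covariate: str = "in_target",
    B: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired t-test on bootstrap log-HR pairs for two target definitions.

    Patients are resampled with replacement B times; for each replicate
    both univariable PWP models (attainment covariate only) are refitted
    and the paired t-test is applied to the log-HR estimates.  Identical
    definitions on both sides give t = 0, p = 1 by construction.
    """
    import dataclasses as _dc

    from .features import gap_time_dataset_for_cohort

    if target_a == target_b:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    by_pid = {}
    for v in visits:
        by_pid.setdefault(v.patient_id, []).append(v)
    att_by_pid: dict[str, list] = {}
    for r in attainment:
        att_by_pid.setdefault(r.patient_id, []).append(r)
    pids = [p.patient_id for p in patients]
    pat_by_pid = {p.patient_id: p for p in patients}
    pairs = []
    for _ in range(B):
        chosen = rng.choice(pids, size=len(pids), replace=True)
        bp, bv, ba = [], [], []
        for j, pid in enumerate(chosen):
            new_id = f"b{j}"
            bp.append(_dc.replace(pat_by_pid[pid], patient_id=new_id))
            for v in by_pid[pid]:
                bv.append(_dc.replace(v, patient_id=new_id))
            for r in att_by_pid.get(pid, []):
                ba.append(_dc.replace(r, patient_id=new_id))
        try:
            logs = []
            for target in (target_a, target_b):
                rows = gap_time_dataset_for_cohort(
                    bp, bv, ba, target, event_type=event_type,
                    include_standard_covariates=False,
                )
                fit = fit_pwp_gap_time(rows, [covariate])
                logs.append(float(fit.coef[0]))
            pairs.append(logs)
        except (ValueError, SingularInformationError):
            continue
    if len(pairs) < 2:
        raise ConvergenceError("fewer than 2 successful bootstrap replicates")
    arr = np.array(pairs)
    return paired_t(arr[:, 0], arr[:, 1])


def hr_vs_cumulative_time(
    patients,
    visits,
    attainment,
    target: str,
    thresholds=range(10, 90, 10),
    event_type: str = "severe_flare",
) -> dict[int, ModelFit]:
    """Severe-flare HR as a function of cumulative time-in-target threshold.

    For each threshold X the univariable PWP model is fitted with the
    binary patient-level covariate "spent >= X% of follow-up in target"
    (X = 0 reduces to the ever-attained indicator).  Thresholds whose
    covariate does not vary are skipped.
    """
    from .cohort import visits_by_patient
    from .features import gap_time_dataset_for_cohort, time_in_target

    grouped = visits_by_patient(visits)
    att_for_target: dict[str, list] = {}
    for r in attainment:
        if r.target == target:
            att_for_target.setdefault(r.patient_id, []).append(r)
    percents = {
        pid: time_in_target(grouped[pid], att_for_target.get(pid, []))
        for pid in grouped
    }
    out: dict[int, ModelFit] = {}
    for x in thresholds:
        if x == 0:
            cov = {
                pid: float(t.time_to_first_attainment_months is not None)
                for pid, t in percents.items()
            }
        else:
            cov = {
                pid: float(t.percent_time_in_target >= x)
                for pid, t in percents.items()
            }
        if len(set(cov.values())) < 2:
            continue
        rows = gap_time_dataset_for_cohort(
            patients, visits, attainment, target,
            event_type=event_type,
            extra_patient_covariates={"time_in_target_ge_x": cov},
            include_standard_covariates=False,
        )
        # drop the per-visit state; keep only the threshold covariate
        try:
            out[int(x)] = fit_pwp_gap_time(rows, ["time_in_target_ge_x"])
        except (ValueError, SingularInformationError):
            continue
    return out
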
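"""Trial endpoint statistics: response rates, survival curves, comparisons.

Response rates come with exact (Clopper–Pearson) or Wald confidence
intervals.  Time-to-event endpoints use the Kaplan–Meier product-limit
estimator with Greenwood standard errors, the two-sample log-rank test
with hypergeometric variance, and univariate Cox proportional-hazards
regression for a single binary biomarker, maximising the Breslow partial
likelihood by Newton–Raphson.  The survival machinery is written out
explicitly rather than delegated, because the estimators themselves are
part of this package's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.stats.proportion import proportion_confint

from .io import PatientRecord

__all__ = [
    "ResponseSummary",
    "SurvivalEstimate",
    "CoxResult",
    "AdverseEvent",
    "response_rates",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_univariate",
    "safety_table",
]


@dataclass(frozen=True)
class ResponseSummary:
    """Best-response tabulation with CR-rate and ORR intervals."""

    n: int
    n_cr: int
    n_pr: int
    n_sd: int
    n_pd: int
    cr_rate: float
    orr: float
    cr_ci: tuple
    orr_ci: tuple
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_cr": self.n_cr,
            "n_pr": self.n_pr,
            "n_sd": self.n_sd,
            "n_pd": self.n_pd,
            "cr_rate": self.cr_rate,
            "orr": self.orr,
            "cr_ci": list(self.cr_ci),
            "orr_ci": list(self.orr_ci),
            "level": self.level,
        }


_CI_METHODS = {"clopper_pearson": "beta", "wald": "normal"}


def _proportion_ci(k: int, n: int, method: str, level: float) -> tuple:
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=_CI_METHODS[method])
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


def response_rates(
    records: Sequence[PatientRecord],
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> ResponseSummary:
    """CR rate and ORR over all evaluable records (intent-to-treat).

    Patients with a missing response assessment stay in the denominator;
    ORR counts CR plus PR.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    n = len(records)
    if n == 0:
        raise ValueError("cannot summarise an empty set of records")
    counts = {"CR": 0, "PR": 0, "SD": 0, "PD": 0}
    for r in records:
        if r.response is not None:
            counts[r.response] += 1
    n_cr = counts["CR"]
    n_resp = counts["CR"] + counts["PR"]
    return ResponseSummary(
        n=n,
        n_cr=n_cr,
        n_pr=counts["PR"],
        n_sd=counts["SD"],
        n_pd=counts["PD"],
        cr_rate=n_cr / n,
        orr=n_resp / n,
        cr_ci=_proportion_ci(n_cr, n, ci_method, level),
        orr_ci=_proportion_ci(n_resp, n, ci_method, level),
        level=level,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class SurvivalEstimate:
    """Product-limit curve: one step per distinct observed event time."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    return t, e


def km_estimate(times, events) -> SurvivalEstimate:
    """Kaplan–Meier estimator with Greenwood variance.

    At each distinct event time ``t_j`` with ``d_j`` events among ``n_j``
    at risk the curve multiplies by ``1 - d_j/n_j``; Greenwood's formula
    gives ``se(S)^2 = S^2 * sum d_j / (n_j (n_j - d_j))``.
    """
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    uniq, d_events = np.unique(t[e], return_counts=True)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    surv = np.cumprod(1.0 - d_events / at_risk)
    # Greenwood: se(S)^2 = S^2 * cumsum d / (n (n - d)); once the curve hits
    # zero the variance term degenerates and se is reported as 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            at_risk > d_events,
            d_events / (at_risk * (at_risk - d_events)),
            0.0,
        )
    se = np.where(surv > 0, surv * np.sqrt(np.cumsum(terms)), 0.0)
    return SurvivalEstimate(
        event_times=uniq,
        survival=surv,
        greenwood_se=se,
        n_at_risk=at_risk,
        n_events=d_events,
    )


def survival_at(estimate: SurvivalEstimate, t: float) -> float:
    """Right-continuous step value S(t)."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    idx = np.searchsorted(estimate.event_times, t, side="right")
    return 1.0 if idx == 0 else float(estimate.survival[idx - 1])


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(times_a, events_a, times_b, events_b) -> dict:
    """Two-sample log-rank test (1 df, hypergeometric variance).

    With zero events in the pooled data the statistic is 0 and p = 1 by
    convention.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    uniq = np.unique(t[e])
    if uniq.size == 0:
        return {"chi_square": 0.0, "p": 1.0}

    def _counts_at(values: np.ndarray) -> np.ndarray:
        u, c = np.unique(values, return_counts=True)
        out = np.zeros(uniq.size)
        out[np.searchsorted(uniq, u)] = c
        return out

    t_sorted = np.sort(t)
    tb_sorted = np.sort(tb)
    nj = t.size - np.searchsorted(t_sorted, uniq, side="left")
    n1j = tb.size - np.searchsorted(tb_sorted, uniq, side="left")
    dj = _counts_at(t[e])
    d1j = _counts_at(tb[eb])
    o_minus_e = float(np.sum(d1j - dj * n1j / nj))
    frac = n1j / nj
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            nj > 1, dj * frac * (1 - frac) * (nj - dj) / np.maximum(nj - 1, 1), 0.0
        )
    var = float(np.sum(terms))
    if var == 0.0:
        return {"chi_square": 0.0, "p": 1.0}
    stat = o_minus_e**2 / var
    return {"chi_square": float(stat), "p": float(chi2.sf(stat, df=1))}


# ---------------------------------------------------------------------------
# univariate Cox (binary covariate, Breslow ties)


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio with Wald inference for one binary covariate."""

    hr: float
    ci: tuple
    log_hr: float
    se_log_hr: float
    wald_p: float
    converged: bool = True


def cox_partial_loglik(beta: float, times, events, covariate) -> float:
    """Breslow partial log-likelihood for a single binary covariate.

    Exposed for oracle-style checks: small instances can be maximised by
    direct grid search over ``beta`` and compared with the Newton fit.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    ll = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        dead = e & (t == tj)
        dj = int(dead.sum())
        ll += beta * float(x[dead].sum())
        ll -= dj * np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


_BETA_BOUND = 15.0


def cox_univariate(
    times, events, covariate, ties: str = "breslow", level: float = 0.95
) -> CoxResult:
    """Fit ``h(t | x) = h0(t) exp(beta x)`` for a binary covariate.

    Newton–Raphson on the Breslow partial likelihood; convergence is
    declared when the score falls below 1e-8.  A monotone likelihood
    (all events on one arm of the covariate, so the MLE diverges) is
    detected by the estimate escaping ``|beta| > 15``; a bounded estimate
    is returned with ``converged=False`` and a warning.
    """
    if ties != "breslow":
        raise ValueError("only Breslow tie handling is implemented")
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate length mismatch")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant; hazard ratio is unidentifiable")
    if not e.any():
        raise ValueError("no events in the data")

    uniq = np.unique(t[e])
    # per event time: d_j, sum of x over events, risk-set masks
    masks = [t >= tj for tj in uniq]
    dead = [(e & (t == tj)) for tj in uniq]
    dj = np.array([d.sum() for d in dead], dtype=float)
    sx = np.array([x[d].sum() for d in dead])

    beta = 0.0
    converged = False
    for _ in range(50):
        score = 0.0
        info = 0.0
        for j, m in enumerate(masks):
            ex = np.exp(beta * x[m])
            s0 = ex.sum()
            s1 = float((x[m] * ex).sum())
            s2 = float((x[m] ** 2 * ex).sum())
            mean = s1 / s0
            score += sx[j] - dj[j] * mean
            info += dj[j] * (s2 / s0 - mean**2)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)  # damp early overshoot
        if abs(beta) > _BETA_BOUND:
            beta = np.sign(beta) * _BETA_BOUND
            warnings.warn(
                "monotone partial likelihood (complete separation of events); "
                "returning bounded estimate",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        if abs(score) < 1e-8:
            converged = True
            break

    # observed information at the solution for the Wald SE
    info = 0.0
    for j, m in enumerate(masks):
        ex = np.exp(beta * x[m])
        s0 = ex.sum()
        s1 = float((x[m] * ex).sum())
        s2 = float((x[m] ** 2 * ex).sum())
        info += dj[j] * (s2 / s0 - (s1 / s0) ** 2)
    se = float(np.sqrt(1.0 / info)) if info > 0 else float("inf")
    z = norm.ppf(0.5 + level / 2.0)
    wald = abs(beta) / se if np.isfinite(se) else 0.0
    with np.errstate(over="ignore"):
        ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci=ci,
        log_hr=float(beta),
        se_log_hr=se,
        wald_p=float(2.0 * norm.sf(wald)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# safety


@dataclass(frozen=True)
class AdverseEvent:
    """One adverse-event observation: patient, arm, event label, CTCAE grade."""

    sample_id: str
    arm: str
    event: str
    grade: int

    def __post_init__(self) -> None:
        if not 1 <= self.grade <= 5:
            raise ValueError(
                f"{self.sample_id}: CTCAE grade must be 1-5, got {self.grade}"
            )


def safety_table(
    events: Sequence[AdverseEvent], n_by_arm: Mapping[str, int]
) -> pd.DataFrame:
    """Any-grade and grade>=3 counts and rates per event label, per arm and overall.

    A patient counts once per (event, column) regardless of repeat
    observations; the grade>=3 column takes the patient's worst grade.
    Denominators are the per-arm enrolment counts in ``n_by_arm``.
    """
    for ev in events:
        if ev.arm not in n_by_arm:
            raise ValueError(f"event for unknown arm {ev.arm!r}")
    n_total = int(sum(n_by_arm.values()))
    worst: dict[tuple[str, str, str], int] = {}
    for ev in events:
        key = (ev.event, ev.arm, ev.sample_id)
        worst[key] = max(worst.get(key, 0), ev.grade)
    rows = []
    labels = sorted({ev.event for ev in events})
    arms = sorted(n_by_arm)
    for label in labels:
        for arm in arms + ["overall"]:
            if arm == "overall":
                grades = [g for (lab, _a, _s), g in worst.items() if lab == label]
                denom = n_total
            else:
                grades = [
                    g for (lab, a, _s), g in worst.items() if lab == label and a == arm
                ]
                denom = int(n_by_arm[arm])
            any_n = len(grades)
            g3_n = sum(1 for g in grades if g >= 3)
            rows.append(
                {
                    "event": label,
                    "arm": arm,
                    "n": denom,
                    "any_grade_n": any_n,
                    "any_grade_rate": any_n / denom if denom else 0.0,
                    "grade3plus_n": g3_n,
                    "grade3plus_rate": g3_n / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "arm", "n",
            "any_grade_n", "any_grade_rate",
            "grade3plus_n", "grade3plus_rate",
        ],
    )
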
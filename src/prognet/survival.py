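"""Survival statistics: meta-gene scoring, Kaplan-Meier, log-rank, binary Cox.

The log-rank statistic uses the usual observed-minus-expected sum with
hypergeometric variance over distinct event times. The one-sided p-value
tests the hypothesis that the signature-high group has *worse* survival
(more events than expected), matching the direction convention used for
poor-prognosis meta-gene stratification.

The Cox model here is the one-parameter binary-covariate special case,
fitted by Newton-Raphson on the Breslow partial likelihood. This is all
the stratified prognosis analysis needs, and the scalar case admits a
closed-form score/information pair, making convergence and monotone-
likelihood detection straightforward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, SurvivalRecord, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MetaGeneScore",
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "metagene_score",
    "stratify",
    "km_estimate",
    "logrank_test",
    "cox_hr_binary",
]

MetaGeneScore = dict  # sample_id -> float


def metagene_score(m: ExpressionMatrix, genes: Sequence[str]) -> dict[str, float]:
    """Per-sample meta-gene score: unweighted mean of the member genes' rows."""
    idx = m.feature_index()
    missing = [g for g in genes if g not in idx]
    if missing:
        raise KeyError(f"meta-gene members absent from matrix: {missing}")
    if len(genes) == 0:
        raise ValueError("empty gene set")
    rows = m.values[[idx[g] for g in genes]]
    scores = rows.mean(axis=0)
    return dict(zip(m.sample_ids, scores.tolist()))


def stratify(
    scores: Mapping[str, float],
    rule: str = "median",
    q: float | None = None,
) -> dict[str, str]:
    """Assign each sample 'high' or 'low' by its score.

    rule='median' splits at the median; rule='fraction' puts the top ``q``
    fraction in the high group. Ties go low: a sample is high only when its
    score is strictly above the cutoff.
    """
    ids = list(scores.keys())
    vals = np.array([scores[s] for s in ids], dtype=float)
    if rule == "median":
        cutoff = float(np.median(vals))
    elif rule == "fraction":
        if q is None or not (0 < q < 1):
            raise ValueError("fraction rule requires 0 < q < 1")
        cutoff = float(np.quantile(vals, 1.0 - q))
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    labels = {s: ("high" if v > cutoff else "low") for s, v in zip(ids, vals)}
    if all(lab == "low" for lab in labels.values()):
        warnings.warn("degenerate stratification: all samples in the low group")
    return labels


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) right-continuous, S(0)=1, non-increasing."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n at risk just before each event time
    n_events: np.ndarray       # events at each time

    def survival_at(self, t: float) -> float:
        """S(t) for arbitrary t (step function, right-continuous)."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def _times_events(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=bool)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    t, e = _times_events(records)
    if len(t) == 0:
        raise ValueError("no records")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & e))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
    )


def _risk_table(
    t: np.ndarray, e: np.ndarray, in_a: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Per distinct event time: (times, d, d_A, n at risk, n_A at risk)."""
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    a_sorted = in_a[order].astype(np.int64)
    n = len(t)
    # suffix counts: subjects (and group-A subjects) with time >= t_sorted[i]
    suffix_a = np.concatenate([np.cumsum(a_sorted[::-1])[::-1], [0]])

    event_times, d_i = np.unique(t[e], return_counts=True)
    da_times = t[e & in_a]
    d_ai = np.zeros(len(event_times), dtype=np.int64)
    if len(da_times):
        pos = np.searchsorted(event_times, da_times)
        np.add.at(d_ai, pos, 1)
    first = np.searchsorted(t_sorted, event_times, side="left")
    n_i = n - first
    n_ai = suffix_a[first]
    return event_times, d_i.astype(float), d_ai.astype(float), n_i.astype(float), n_ai.astype(float)


@dataclass
class LogrankResult:
    chi_square: float
    z: float
    p_two_sided: float
    p_one_sided: float
    direction: str  # 'a_worse' or 'b_worse'
    o_minus_e: float
    variance: float


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    sided: str = "two",
) -> LogrankResult:
    """Log-rank test between two groups.

    ``z = (O_A - E_A)/sqrt(V)``; the one-sided p-value tests "group A has
    worse survival" (``p = Phi(-z)`` is small when A has excess events).
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    a_t, a_e = _times_events(group_a)
    b_t, b_e = _times_events(group_b)
    if len(a_t) == 0 or len(b_t) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([a_t, b_t])
    e = np.concatenate([a_e, b_e])
    in_a = np.concatenate([np.ones(len(a_t), bool), np.zeros(len(b_t), bool)])

    event_times, d_i, d_ai, n_i, n_ai = _risk_table(t, e, in_a)
    o_minus_e = float(np.sum(d_ai - d_i * n_ai / n_i))
    ok = n_i > 1
    var = float(
        np.sum(
            d_i[ok]
            * (n_ai[ok] / n_i[ok])
            * (1.0 - n_ai[ok] / n_i[ok])
            * (n_i[ok] - d_i[ok])
            / (n_i[ok] - 1.0)
        )
    )
    if var <= 0:
        # no between-group information (e.g. no events): define a null result
        return LogrankResult(0.0, 0.0, 1.0, 0.5, "a_worse", o_minus_e, var)
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    p_two = float(stats.chi2.sf(chi2, df=1))
    p_one = float(stats.norm.sf(z))
    return LogrankResult(
        chi_square=float(chi2),
        z=float(z),
        p_two_sided=p_two,
        p_one_sided=p_one,
        direction="a_worse" if z > 0 else "b_worse",
        o_minus_e=float(o_minus_e),
        variance=float(var),
    )


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    ci95: tuple[float, float]
    p: float
    n_iter: int
    converged: bool
    separation_flag: bool


def cox_hr_binary(
    records: Sequence[SurvivalRecord],
    groups: Mapping[str, str] | Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Cox proportional-hazards HR for a binary covariate (Breslow ties).

    ``groups`` is either a sample_id -> {'high','low'} mapping or a 0/1
    sequence aligned with ``records`` (1 = high/exposed group). The
    hazard ratio is for group 1 relative to group 0.
    """
    recs = list(records)
    if isinstance(groups, Mapping):
        x = np.array(
            [1 if groups[r.sample_id] in ("high", 1, "1") else 0 for r in recs],
            dtype=float,
        )
    else:
        x = np.array(list(groups), dtype=float)
        if len(x) != len(recs):
            raise ValueError("group vector length mismatch")
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("covariate must be binary 0/1")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant; hazard ratio undefined")

    t, e = _times_events(recs)
    if not e.any():
        raise ValueError("no events; hazard ratio undefined")

    # Per distinct event time: events in group 1 (d1), total events (d),
    # risk-set counts per group (risk set for time et: t >= et).
    _, d, d1, n_total, n1 = _risk_table(t, e, x == 1.0)
    n0 = n_total - n1

    total_d1 = d1.sum()
    total_d = d.sum()
    separation = total_d1 == 0 or total_d1 == total_d

    beta = 0.0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        r = np.exp(beta)
        denom = n0 + n1 * r
        mu = n1 * r / denom              # expected fraction of events in group 1
        score = total_d1 - np.sum(d * mu)
        info = np.sum(d * mu * (1.0 - mu))
        if info <= 0:
            separation = True
            break
        step = score / info
        beta += step
        if abs(beta) > 20:               # likelihood is monotone
            separation = True
            break
        if abs(step) < tol:
            converged = True
            break

    if separation:
        logger.warning("monotone Cox partial likelihood (complete separation)")
        beta = float(np.clip(beta, -20, 20))
    r = np.exp(beta)
    denom = n0 + n1 * r
    mu = n1 * r / denom
    info = np.sum(d * mu * (1.0 - mu))
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    zstat = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    with np.errstate(over="ignore"):
        ci = (float(np.exp(lo)), float(np.exp(hi)))
    return CoxResult(
        log_hr=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        ci95=ci,
        p=p,
        n_iter=n_iter,
        converged=converged,
        separation_flag=bool(separation),
    )
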
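"""Standardized-mean-difference effect sizes and random-effects combination.

Per-dataset effects are bias-corrected standardized mean differences
(Hedges' g*): with group summaries (n1, x1, s1) and (n2, x2, s2),

    s*  = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))
    g   = (x1 - x2) / s*
    g*  = (1 - 3 / (4 (n1 + n2) - 9)) * g
    se  = sqrt((n1 + n2)/(n1 n2) + g*^2 / (2 (n1 + n2 - 3.94)))

Effects are combined with a DerSimonian-Laird random-effects model; the
combined estimate's p-value and 95% CI use the normal approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "EffectSize",
    "MetaResult",
    "hedges_g_star",
    "effect_from_values",
    "random_effects_combine",
    "run_grade_meta",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and (unbiased, n-1) standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("negative standard deviation")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class EffectSize:
    g: float
    g_star: float
    se: float
    n1: int
    n2: int
    label: Optional[str] = None


@dataclass(frozen=True)
class MetaResult:
    combined_smd: float
    se: float
    ci95: tuple[float, float]
    p: float
    tau2: float
    k: int


def hedges_g_star(a: GroupSummary, b: GroupSummary, label: Optional[str] = None) -> EffectSize:
    """Bias-corrected standardized mean difference of group a minus group b."""
    n1, n2 = a.n, b.n
    if n1 + n2 < 4:
        raise ValueError("need n1 + n2 >= 4 for the small-sample correction")
    pooled_var = ((n1 - 1) * a.sd**2 + (n2 - 1) * b.sd**2) / (n1 + n2 - 2)
    s_star = float(np.sqrt(pooled_var))
    if s_star == 0:
        raise ValueError("pooled standard deviation is zero (degenerate groups)")
    g = (a.mean - b.mean) / s_star
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g_star = correction * g
    se = float(
        np.sqrt((n1 + n2) / (n1 * n2) + g_star**2 / (2.0 * (n1 + n2 - 3.94)))
    )
    return EffectSize(g=float(g), g_star=float(g_star), se=se, n1=n1, n2=n2, label=label)


def effect_from_values(
    values_a: Sequence[float], values_b: Sequence[float], label: Optional[str] = None
) -> EffectSize:
    """Hedges' g* straight from the two groups' raw values."""
    return hedges_g_star(
        GroupSummary.from_values(values_a), GroupSummary.from_values(values_b), label
    )


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of between-study variance."""
    k = len(y)
    w = 1.0 / v
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0


def _tau2_reml(y: np.ndarray, v: np.ndarray, tol: float = 1e-10,
               max_iter: int = 200) -> float:
    """REML estimate of tau^2 by fixed-point iteration."""
    tau2 = _tau2_dl(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = float(
            np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        )
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def random_effects_combine(
    effects: Sequence[EffectSize], method: str = "dl"
) -> MetaResult:
    """Random-effects combination of per-dataset effects.

    ``method`` selects the between-study variance estimator:
    'dl' (DerSimonian-Laird moment estimator, default) or 'reml'.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("need at least two effects to combine")
    y = np.array([e.g_star for e in effects], dtype=float)
    v = np.array([e.se**2 for e in effects], dtype=float)
    if method == "dl":
        tau2 = _tau2_dl(y, v)
    elif method == "reml":
        tau2 = _tau2_reml(y, v)
    else:
        raise ValueError(f"unknown method {method!r} (use 'dl' or 'reml')")
    w_re = 1.0 / (v + tau2)
    combined = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(1.0 / np.sqrt(np.sum(w_re)))
    z = combined / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        combined_smd=combined,
        se=se,
        ci95=(combined - 1.96 * se, combined + 1.96 * se),
        p=p,
        tau2=float(tau2),
        k=k,
    )


def run_grade_meta(
    datasets: Sequence[dict],
    gene: Optional[str] = None,
    genes: Optional[Sequence[str]] = None,
    min_per_group: int = 10,
    method: str = "dl",
) -> tuple[MetaResult, list[EffectSize]]:
    """Per-dataset grade III vs I effect sizes and their combination.

    Each dataset is a dict with keys ``matrix`` (:class:`ExpressionMatrix`),
    ``grades`` (sample_id -> 'I'/'II'/'III'), optional ``patient_ids``
    (sample_id -> patient id, for deduplication) and optional ``label``.
    Either a single ``gene`` or a ``genes`` list (scored as a meta-gene,
    i.e. per-sample mean) selects the measured quantity. Datasets with
    fewer than ``min_per_group`` grade I or grade III tumors are excluded
    with a logged reason; duplicate patients keep their first sample.
    """
    if (gene is None) == (genes is None):
        raise ValueError("specify exactly one of gene / genes")
    members = [gene] if gene is not None else list(genes)  # type: ignore[arg-type]

    effects: list[EffectSize] = []
    for i, ds in enumerate(datasets):
        m: ExpressionMatrix = ds["matrix"]
        grades: dict[str, str] = ds["grades"]
        label = ds.get("label", f"dataset_{i + 1}")

        samples = [s for s in m.sample_ids if s in grades]
        if "patient_ids" in ds:
            seen: set[str] = set()
            deduped = []
            for s in samples:
                pid = ds["patient_ids"].get(s, s)
                if pid in seen:
                    continue
                seen.add(pid)
                deduped.append(s)
            samples = deduped

        g1 = [s for s in samples if grades[s] == "I"]
        g3 = [s for s in samples if grades[s] == "III"]
        if len(g1) < min_per_group or len(g3) < min_per_group:
            logger.info(
                "excluding %s: %d grade I / %d grade III tumors (need >= %d each)",
                label, len(g1), len(g3), min_per_group,
            )
            continue

        idx = m.feature_index()
        missing = [g for g in members if g not in idx]
        if missing:
            raise KeyError(f"{label}: genes absent from matrix: {missing}")
        rows = m.values[[idx[g] for g in members]]
        score = rows.mean(axis=0)
        sidx = {s: j for j, s in enumerate(m.sample_ids)}
        vals3 = score[[sidx[s] for s in g3]]
        vals1 = score[[sidx[s] for s in g1]]
        effects.append(effect_from_values(vals3, vals1, label=label))

    if not effects:
        raise ValueError("no eligible datasets (all failed the n >= 10/10 rule)")
    if len(effects) == 1:
        raise ValueError("only one eligible dataset; cannot combine")
    return random_effects_combine(effects, method=method), effects
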
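"""FPKM-scale differential expression and display summaries.

Genes pass a variation filter (fold change and absolute range across all
samples), are tested control-vs-knockdown with a two-sample t-test, and
corrected by the Benjamini-Hochberg step-up procedure. Helpers provide
row 0-1 scaling for heat maps, meta-gene group comparison, and Pearson
correlation of per-sample scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

__all__ = [
    "DEResult",
    "variation_filter",
    "ttest_bh",
    "row_scale_01",
    "metagene_group_compare",
    "pearson_correlation",
]

FOLD_EPS = 0.001  # pseudo-count guarding fold changes against zero FPKM


def variation_filter(
    m: ExpressionMatrix, min_fold: float = 1.5, min_abs: float = 1.0
) -> ExpressionMatrix:
    """Keep genes with (max+eps)/(min+eps) >= min_fold and max-min >= min_abs.

    Expects non-negative (FPKM-like) values.
    """
    if np.any(m.values < 0):
        raise ValueError("variation filter expects non-negative FPKM-scale values")
    mx = m.values.max(axis=1)
    mn = m.values.min(axis=1)
    keep = ((mx + FOLD_EPS) / (mn + FOLD_EPS) >= min_fold) & (mx - mn >= min_abs)
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return ExpressionMatrix(
        kept_ids, list(m.sample_ids), m.values[keep], m.feature_kind
    )


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns t, p, q, direction
    n_selected: int
    n_up: int
    n_down: int


def _split_labels(
    m: ExpressionMatrix, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = sorted(set(labels[s] for s in m.sample_ids))
    if len(groups) != 2:
        raise ValueError(f"need exactly two label groups, got {groups}")
    # convention: 'control' (or the alphabetically first) is the reference
    if "control" in groups:
        ref = "control"
        other = next(g for g in groups if g != "control")
    else:
        ref, other = groups
    mask_ref = np.array([labels[s] == ref for s in m.sample_ids])
    return m.values[:, mask_ref], m.values[:, ~mask_ref], ref, other


def ttest_bh(
    m: ExpressionMatrix,
    labels: Mapping[str, str],
    fdr: float = 0.1,
    equal_var: bool = True,
) -> DEResult:
    """Per-gene two-sample t-test (pooled variance by default) with BH q-values.

    Selection is q < fdr; direction is the sign of (knockdown - control)
    mean difference.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    ref_vals, kd_vals, _, _ = _split_labels(m, labels)
    if ref_vals.shape[1] < 2 or kd_vals.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    res = stats.ttest_ind(kd_vals, ref_vals, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance rows carry no evidence
    q = multipletests(p, method="fdr_bh")[1]
    diff = kd_vals.mean(axis=1) - ref_vals.mean(axis=1)
    direction = np.where(diff < 0, "down_in_kd", "up_in_kd")
    table = pd.DataFrame(
        {"t": t, "p": p, "q": q, "direction": direction}, index=m.feature_ids
    )
    sel = table["q"] < fdr
    return DEResult(
        table=table,
        n_selected=int(sel.sum()),
        n_up=int((sel & (table["direction"] == "up_in_kd")).sum()),
        n_down=int((sel & (table["direction"] == "down_in_kd")).sum()),
    )


def row_scale_01(m: ExpressionMatrix) -> ExpressionMatrix:
    """Affinely map each row to [0, 1]; constant rows become all 0.5."""
    mn = m.values.min(axis=1, keepdims=True)
    mx = m.values.max(axis=1, keepdims=True)
    rng = mx - mn
    constant = (rng == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant rows mapped to 0.5")
    safe = np.where(rng == 0, 1.0, rng)
    scaled = (m.values - mn) / safe
    scaled[constant] = 0.5
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), scaled, m.feature_kind
    )


def metagene_group_compare(
    m: ExpressionMatrix,
    genes: Sequence[str],
    labels: Mapping[str, str],
    equal_var: bool = True,
) -> tuple[dict[str, float], float]:
    """Per-sample meta-gene values plus a two-group t-test p-value."""
    idx = m.feature_index()
    missing = [g for g in genes if g not in idx]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    score = m.values[[idx[g] for g in genes]].mean(axis=0)
    values = dict(zip(m.sample_ids, score.tolist()))
    sub = ExpressionMatrix(["__meta__"], list(m.sample_ids), score[None, :], "gene")
    ref_vals, kd_vals, _, _ = _split_labels(sub, labels)
    p = float(
        stats.ttest_ind(kd_vals.ravel(), ref_vals.ravel(), equal_var=equal_var).pvalue
    )
    return values, p


def pearson_correlation(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson r and p over the samples shared by both score maps."""
    shared = [s for s in x if s in y]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    xv = np.array([x[s] for s in shared])
    yv = np.array([y[s] for s in shared])
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)
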
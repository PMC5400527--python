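"""Expression-matrix normalization and probe-to-gene collapsing.

Cross-dataset comparability is handled by per-gene median centering
within each dataset followed by quantile normalization across arrays.
Probe-level matrices are collapsed to one row per gene by keeping only
probes from the highest-priority id-suffix class present for that gene
and averaging the survivors.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import ExpressionMatrix, ProbeMap, ValidationError, probe_suffix_class

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "median_center_genes", "collapse_probes"]

# Probe-suffix preference when collapsing to one probe set per gene.
DEFAULT_SUFFIX_PRIORITY = ("_at", "_x_at", "_s_at")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common reference distribution.

    The reference is the across-column mean of the columns' sorted values;
    tied values within a column receive the mean of the reference values
    at the tied ranks, so the map is well defined under ties.
    """
    n_features, n_samples = m.shape
    if n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    values = m.values
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_features)
        assigned[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_features]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), out, m.feature_kind
    )


def median_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's (row's) median so every row has median 0."""
    medians = np.median(m.values, axis=1, keepdims=True)
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), m.values - medians, m.feature_kind
    )


def collapse_probes(
    m: ExpressionMatrix,
    probe_map: ProbeMap,
    suffix_priority: Sequence[str] = DEFAULT_SUFFIX_PRIORITY,
) -> ExpressionMatrix:
    """Collapse a target-probe matrix to one row per gene.

    For each gene, only probes of the best suffix class present in the
    matrix (by ``suffix_priority``, default '_at' > '_x_at' > '_s_at')
    are kept, and the surviving rows are averaged element-wise. Genes
    with no mapped probe present in ``m`` are dropped (count logged).
    Gene order follows first appearance in the probe map.
    """
    priority = {suf: rank for rank, suf in enumerate(suffix_priority)}
    if set(priority) != set(DEFAULT_SUFFIX_PRIORITY):
        raise ValueError(f"suffix_priority must be a permutation of {DEFAULT_SUFFIX_PRIORITY}")
    idx = m.feature_index()

    gene_order: list[str] = []
    probes_by_gene: dict[str, list[str]] = {}
    for _, gene, tgt in probe_map.rows:
        if gene not in probes_by_gene:
            gene_order.append(gene)
            probes_by_gene[gene] = []
        if tgt in idx and tgt not in probes_by_gene[gene]:
            probes_by_gene[gene].append(tgt)

    out_genes: list[str] = []
    out_rows: list[np.ndarray] = []
    n_dropped = 0
    for gene in gene_order:
        probes = probes_by_gene[gene]
        if not probes:
            n_dropped += 1
            continue
        best = min(priority[probe_suffix_class(p)] for p in probes)
        kept = [p for p in probes if priority[probe_suffix_class(p)] == best]
        rows = m.values[[idx[p] for p in kept]]
        out_genes.append(gene)
        out_rows.append(rows.mean(axis=0))
    if n_dropped:
        logger.info("collapse_probes: dropped %d genes with no probe in matrix", n_dropped)
    return ExpressionMatrix(
        out_genes, list(m.sample_ids), np.array(out_rows), feature_kind="gene"
    )
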
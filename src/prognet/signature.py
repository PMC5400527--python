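"""Derivation funnel for a knockdown-dependent poor-prognosis gene signature.

Stages, in order:

1. **Differential probes** — probes significantly changed by *both*
   independent shRNAs versus control (Welch t-test, p < alpha for each,
   with agreeing direction), separately in two cell lines.
2. **Probe-to-gene mapping** — differential source probes are mapped to
   target-platform probes/genes; one target probe is chosen per gene by
   id-suffix priority.
3. **Prognostic screen** — each gene's target probe is tested on a
   survival training cohort: median-split log-rank, keep p < threshold.
4. **Two-cell-line intersection + direction** — genes prognostic in both
   cell lines and down-regulated by both shRNAs in both lines.
5. **Poor-prognosis expression filter** — keep genes whose median
   expression is above the cohort median among poor-prognosis patients
   (event before the horizon) and below it among good-prognosis patients
   (event-free with follow-up past the horizon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, ProbeMap, SurvivalRecord, probe_suffix_class
from .preprocess import DEFAULT_SUFFIX_PRIORITY, collapse_probes
from .survival import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionalFeatureSet",
    "GeneSignature",
    "differential_probes",
    "map_probes_to_genes",
    "prognostic_probe_filter",
    "intersect_and_direction",
    "poor_prognosis_expression_filter",
    "derive_signature",
]

DOWN = "down_in_kd"
UP = "up_in_kd"


@dataclass
class DirectionalFeatureSet:
    """Features passing a dual-shRNA differential test, with directions.

    ``entries`` maps feature_id -> (direction, p_kd1, p_kd2).
    """

    entries: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def direction(self, feature_id: str) -> str:
        return self.entries[feature_id][0]

    def feature_ids(self) -> list[str]:
        return list(self.entries)


@dataclass
class GeneSignature:
    """Final signature with per-gene direction and filtering provenance."""

    gene_ids: list[str]
    directions: dict[str, str]
    provenance: pd.DataFrame  # index: candidate gene; bool flag columns

    def __len__(self) -> int:
        return len(self.gene_ids)


def differential_probes(
    control: ExpressionMatrix,
    kd1: ExpressionMatrix,
    kd2: ExpressionMatrix,
    alpha: float = 1e-6,
) -> DirectionalFeatureSet:
    """Probes changed by both shRNAs (Welch t-test p < alpha, agreeing sign)."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if control.feature_ids != kd1.feature_ids or control.feature_ids != kd2.feature_ids:
        raise ValueError("the three matrices must share an identical feature space")
    for m in (control, kd1, kd2):
        if m.shape[1] < 2:
            raise ValueError("need at least 2 replicates per arm")

    p1 = stats.ttest_ind(kd1.values, control.values, axis=1, equal_var=False).pvalue
    p2 = stats.ttest_ind(kd2.values, control.values, axis=1, equal_var=False).pvalue
    d1 = kd1.values.mean(axis=1) - control.values.mean(axis=1)
    d2 = kd2.values.mean(axis=1) - control.values.mean(axis=1)

    keep = (p1 < alpha) & (p2 < alpha) & (np.sign(d1) == np.sign(d2)) & (d1 != 0)
    entries = {
        control.feature_ids[i]: (DOWN if d1[i] < 0 else UP, float(p1[i]), float(p2[i]))
        for i in np.flatnonzero(keep)
    }
    return DirectionalFeatureSet(entries)


def map_probes_to_genes(
    dfs: DirectionalFeatureSet,
    probe_map: ProbeMap,
    suffix_priority: Sequence[str] = DEFAULT_SUFFIX_PRIORITY,
) -> dict[str, tuple[str, str]]:
    """Map differential source probes to genes with one target probe each.

    Returns gene_id -> (direction, target_probe_id). When several source
    probes of one gene pass, the target probe is chosen by suffix
    priority (then lexicographically); genes whose passing probes
    disagree in direction are dropped with a log message.
    """
    priority = {suf: rank for rank, suf in enumerate(suffix_priority)}
    by_source = probe_map.targets_of_source()
    gene_of_target = probe_map.gene_of_target()

    candidates: dict[str, list[tuple[str, str]]] = {}  # gene -> [(direction, target)]
    for probe, (direction, _, _) in dfs.entries.items():
        for tgt in by_source.get(probe, []):
            gene = gene_of_target[tgt]
            candidates.setdefault(gene, []).append((direction, tgt))

    out: dict[str, tuple[str, str]] = {}
    n_conflict = 0
    for gene, cands in candidates.items():
        directions = {d for d, _ in cands}
        if len(directions) > 1:
            n_conflict += 1
            continue
        tgt = min(
            (t for _, t in cands),
            key=lambda t: (priority[probe_suffix_class(t)], t),
        )
        out[gene] = (next(iter(directions)), tgt)
    if n_conflict:
        logger.info("dropped %d genes with conflicting probe directions", n_conflict)
    return out


def prognostic_probe_filter(
    cohort: ExpressionMatrix,
    clinical: Sequence[SurvivalRecord],
    p_threshold: float = 0.1,
    features: Optional[Sequence[str]] = None,
    split: str = "median",
    quantile: float = 0.5,
) -> dict[str, float]:
    """Per-feature survival screen: split at the feature's median (or a
    quantile), two-sided log-rank, keep features with p < threshold.

    Ties at the cutoff go to the low group (high requires value strictly
    above it). Features with fewer than 2 samples on either side are
    skipped with a warning. Returns feature_id -> p for the keepers.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    by_id = {r.sample_id: r for r in clinical}
    missing = [s for s in cohort.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"cohort samples without clinical records: {missing[:10]}")
    records = [by_id[s] for s in cohort.sample_ids]

    idx = cohort.feature_index()
    if features is None:
        features = list(cohort.feature_ids)
    kept: dict[str, float] = {}
    for fid in features:
        row = cohort.values[idx[fid]]
        if split == "median":
            cutoff = float(np.median(row))
        elif split == "quantile":
            cutoff = float(np.quantile(row, quantile))
        else:
            raise ValueError(f"unknown split rule {split!r}")
        high_mask = row > cutoff
        if high_mask.sum() < 2 or (~high_mask).sum() < 2:
            logger.warning("skipping feature %s: degenerate split", fid)
            continue
        high = [r for r, h in zip(records, high_mask) if h]
        low = [r for r, h in zip(records, high_mask) if not h]
        res = logrank_test(high, low, sided="two")
        if res.p_two_sided < p_threshold:
            kept[fid] = res.p_two_sided
    return kept


def intersect_and_direction(
    genes_a: Mapping[str, tuple[str, str]],
    genes_b: Mapping[str, tuple[str, str]],
) -> set[str]:
    """Genes present in both cell lines and down-regulated in both."""
    common = set(genes_a) & set(genes_b)
    return {g for g in common if genes_a[g][0] == DOWN and genes_b[g][0] == DOWN}


def poor_prognosis_expression_filter(
    genes: Sequence[str],
    cohort: ExpressionMatrix,
    clinical: Sequence[SurvivalRecord],
    horizon_months: float = 60.0,
) -> GeneSignature:
    """Keep genes over-expressed in poor-prognosis and under-expressed in
    good-prognosis patients.

    Poor = event before the horizon; good = event-free with follow-up of
    at least the horizon; other patients are excluded. A gene passes when
    its median within the poor group exceeds its overall cohort median
    *and* its median within the good group is below the overall median.
    """
    if cohort.feature_kind != "gene":
        raise ValueError("poor-prognosis filter requires a gene-level cohort")
    by_id = {r.sample_id: r for r in clinical}
    records = [by_id[s] for s in cohort.sample_ids]
    poor = np.array([r.event and r.time < horizon_months for r in records])
    good = np.array([r.time >= horizon_months for r in records])
    if poor.sum() == 0 or good.sum() == 0:
        raise ValueError(
            f"empty prognosis group at horizon {horizon_months} months "
            f"(poor={int(poor.sum())}, good={int(good.sum())})"
        )

    idx = cohort.feature_index()
    kept: list[str] = []
    flags = {}
    for g in genes:
        row = cohort.values[idx[g]]
        overall = np.median(row)
        ok = np.median(row[poor]) > overall and np.median(row[good]) < overall
        flags[g] = ok
        if ok:
            kept.append(g)
    prov = pd.DataFrame({"passed_poor_prognosis": pd.Series(flags)})
    return GeneSignature(
        gene_ids=kept, directions={g: DOWN for g in kept}, provenance=prov
    )


def derive_signature(
    kd_a: Mapping[str, ExpressionMatrix],
    kd_b: Mapping[str, ExpressionMatrix],
    probe_map: ProbeMap,
    cohort: ExpressionMatrix,
    clinical: Sequence[SurvivalRecord],
    alpha: float = 1e-6,
    logrank_p: float = 0.1,
    horizon_months: float = 60.0,
    suffix_priority: Sequence[str] = DEFAULT_SUFFIX_PRIORITY,
) -> tuple[GeneSignature, pd.DataFrame]:
    """Run the full funnel and return (signature, stage-count report).

    ``kd_a``/``kd_b`` are dicts with keys 'control', 'kd1', 'kd2' holding
    source-probe matrices for the two cell lines; ``cohort`` is a
    target-probe-level training cohort with matching ``clinical`` records.
    """
    stages: list[tuple[str, int]] = []

    dfs_a = differential_probes(kd_a["control"], kd_a["kd1"], kd_a["kd2"], alpha)
    dfs_b = differential_probes(kd_b["control"], kd_b["kd1"], kd_b["kd2"], alpha)
    stages += [("differential_probes_A", len(dfs_a)),
               ("differential_probes_B", len(dfs_b))]

    genes_a = map_probes_to_genes(dfs_a, probe_map, suffix_priority)
    genes_b = map_probes_to_genes(dfs_b, probe_map, suffix_priority)
    stages += [("mapped_genes_A", len(genes_a)), ("mapped_genes_B", len(genes_b))]

    cohort_feats = set(cohort.feature_ids)
    prog_a = prognostic_probe_filter(
        cohort, clinical, logrank_p,
        features=[t for _, t in genes_a.values() if t in cohort_feats],
    )
    prog_b = prognostic_probe_filter(
        cohort, clinical, logrank_p,
        features=[t for _, t in genes_b.values() if t in cohort_feats],
    )
    genes_a = {g: v for g, v in genes_a.items() if v[1] in prog_a}
    genes_b = {g: v for g, v in genes_b.items() if v[1] in prog_b}
    stages += [("prognostic_A", len(genes_a)), ("prognostic_B", len(genes_b))]

    common = set(genes_a) & set(genes_b)
    down_both = intersect_and_direction(genes_a, genes_b)
    stages += [("common_genes", len(common)), ("down_in_both", len(down_both))]

    gene_cohort = collapse_probes(cohort, probe_map, suffix_priority)
    signature = poor_prognosis_expression_filter(
        sorted(down_both), gene_cohort, clinical, horizon_months
    )
    stages.append(("poor_prognosis_signature", len(signature)))

    prov = pd.DataFrame(index=sorted(common))
    prov["passed_prognostic"] = True  # by construction at this stage
    prov["passed_direction"] = [g in down_both for g in prov.index]
    prov["passed_poor_prognosis"] = [
        bool(signature.provenance["passed_poor_prognosis"].get(g, False))
        for g in prov.index
    ]
    signature.provenance = prov

    report = pd.DataFrame(stages, columns=["stage", "n_features"])
    return signature, report
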